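"""Probe-exclusion rules applied before differential testing.

Three rules, mirroring standard 450k practice for this kind of screen:

1. detection failure — drop a probe whose detection p-value exceeds
   ``p_max`` (default 0.01) in more than a tolerated fraction of samples
   (default 0: any failing sample drops the probe);
2. missing signal — drop a probe lacking a beta value in one or more
   samples;
3. sex chromosomes — drop chrX probes (chrY optionally) before the
   genome-wide screen, since X inactivation confounds partial methylation.

The rules are independent per probe, so they commute.
"""

from __future__ import annotations

import logging
from typing import AbstractSet, Iterable, Optional

import numpy as np
import pandas as pd

from .datatypes import DataError, FilterReport, MethylationDataset

logger = logging.getLogger(__name__)


def filter_detection(
    dataset: MethylationDataset,
    p_max: float = 0.01,
    max_fail_fraction: float = 0.0,
) -> tuple[MethylationDataset, FilterReport]:
    """Drop probes with unreliable signal.

    A probe is removed iff its detection p-value exceeds ``p_max`` in a
    fraction of samples strictly greater than ``max_fail_fraction`` (default
    0, i.e. a single failing sample suffices).  When the dataset carries no
    detection matrix the operation is the identity, with a warning.
    """
    if not (0 < p_max <= 1):
        raise DataError(f"p_max must lie in (0, 1], got {p_max}")
    n = dataset.n_probes
    if dataset.detection_p is None:
        logger.warning("filter_detection: no detection p-values; skipping")
        return dataset, FilterReport("detection", n, 0)
    fail = (dataset.detection_p.to_numpy(dtype=float) > p_max)
    frac = fail.mean(axis=1)
    drop = frac > max_fail_fraction
    out = dataset.subset_probes(dataset.beta.index[~drop])
    report = FilterReport("detection", n, int(drop.sum()))
    logger.info("filter_detection: removed %d/%d probes", report.n_removed, n)
    return out, report


def filter_missing(dataset: MethylationDataset) -> tuple[MethylationDataset, FilterReport]:
    """Drop probes that lack a signal value in one or more samples."""
    n = dataset.n_probes
    drop = dataset.beta.isna().any(axis=1).to_numpy()
    out = dataset.subset_probes(dataset.beta.index[~drop])
    report = FilterReport("missing", n, int(drop.sum()))
    logger.info("filter_missing: removed %d/%d probes", report.n_removed, n)
    return out, report


def exclude_sex_chromosomes(
    dataset: MethylationDataset,
    chroms: AbstractSet[str] = frozenset({"chrX"}),
) -> tuple[MethylationDataset, FilterReport]:
    """Drop probes on the listed chromosomes (default chrX only)."""
    n = dataset.n_probes
    drop = dataset.annotation["chrom"].isin(set(chroms)).to_numpy()
    out = dataset.subset_probes(dataset.beta.index[~drop])
    report = FilterReport("sex_chromosome", n, int(drop.sum()))
    logger.info("exclude_sex_chromosomes: removed %d/%d probes", report.n_removed, n)
    return out, report


def apply_qc(
    dataset: MethylationDataset,
    p_max: float = 0.01,
    max_fail_fraction: float = 0.0,
    sex_chroms: AbstractSet[str] = frozenset({"chrX"}),
    blocklist: Optional[Iterable[str]] = None,
) -> tuple[MethylationDataset, list[FilterReport]]:
    """Apply the full exclusion cascade: detection, missing, sex chromosomes,
    then an optional user-supplied probe blocklist.

    Each probe is counted once, under the first rule that removes it.
    """
    reports: list[FilterReport] = []
    ds, rep = filter_detection(dataset, p_max=p_max, max_fail_fraction=max_fail_fraction)
    reports.append(rep)
    ds, rep = filter_missing(ds)
    reports.append(rep)
    ds, rep = exclude_sex_chromosomes(ds, chroms=sex_chroms)
    reports.append(rep)
    if blocklist is not None:
        n = ds.n_probes
        block = set(blocklist)
        keep = [p for p in ds.beta.index if p not in block]
        ds = ds.subset_probes(keep)
        reports.append(FilterReport("blocklist", n, n - len(keep)))
    return ds, reports


def qc_summary(reports: list[FilterReport]) -> dict:
    """Serialisable summary of an exclusion cascade."""
    out = {"n_input": reports[0].n_input if reports else 0}
    for r in reports:
        out[f"n_fail_{r.rule}"] = r.n_removed
    out["n_retained"] = reports[-1].n_retained if reports else 0
    return out
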