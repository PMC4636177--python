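"""Run-based candidate-DMR detection over positionally sorted probe
statistics.

A candidate region is a maximal run of "qualifying" probes on one
chromosome — each with p-value below ``p_max`` and a non-zero effect —
where consecutive run members share the sign of their effect and lie
strictly less than ``max_gap_bp`` apart.  A run is emitted iff it contains
at least ``min_probes`` probes and the absolute *average* effect over its
probes exceeds ``min_mean_abs_delta``.  The average rule means individual
probes inside a region may fall below the effect threshold.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import DataError, KnownDMR, RegionCall

logger = logging.getLogger(__name__)


def _sorted_chrom_table(stats: pd.DataFrame) -> Iterable[tuple[str, pd.DataFrame]]:
    """Yield per-chromosome tables sorted by (pos, probe_id).

    Duplicate positions are ordered lexically by probe id — a deterministic
    tie-break, logged when it fires.
    """
    required = {"chrom", "pos", "delta_beta", "p_value"}
    missing = required - set(stats.columns)
    if missing:
        raise DataError(f"stats table missing columns: {sorted(missing)}")
    for chrom in sorted(stats["chrom"].unique()):
        sub = stats[stats["chrom"] == chrom]
        if sub["pos"].duplicated().any():
            logger.info("chromosome %s: duplicate probe positions; "
                        "tie-broken by probe id", chrom)
        order = sorted(range(len(sub)), key=lambda i: (sub["pos"].iloc[i], sub.index[i]))
        yield chrom, sub.iloc[order]


def call_regions(
    stats: pd.DataFrame,
    min_probes: int = 3,
    max_gap_bp: int = 500,
    p_max: float = 0.01,
    min_mean_abs_delta: float = 0.2,
) -> list[RegionCall]:
    """Scan sorted probe statistics for maximal qualifying runs.

    Parameters
    ----------
    stats : DataFrame
        Indexed by probe id with columns ``chrom``, ``pos``, ``delta_beta``,
        ``p_value`` — restricted to QC-retained probes ("consecutive" means
        adjacent among retained probes on a chromosome).

    Run rules: a probe qualifies iff ``p_value < p_max`` and
    ``delta_beta != 0``; a run extends while the next probe qualifies, has
    the run's sign, and lies ``< max_gap_bp`` from the previous member.  A
    sign flip terminates the run and seeds a new one at the flipping probe.
    Emitted regions never overlap and are returned sorted by
    (chromosome, start).
    """
    if min_probes < 1:
        raise DataError("min_probes must be >= 1")
    regions: list[RegionCall] = []
    for chrom, sub in _sorted_chrom_table(stats):
        pos = sub["pos"].to_numpy()
        delta = sub["delta_beta"].to_numpy(dtype=float)
        pval = sub["p_value"].to_numpy(dtype=float)
        qualifies = (pval < p_max) & (delta != 0)

        run: list[int] = []

        def flush() -> None:
            if len(run) >= min_probes:
                d = delta[run]
                mean_d = float(d.mean())
                if abs(mean_d) > min_mean_abs_delta:
                    gaps = np.diff(pos[run])
                    regions.append(RegionCall(
                        chrom=chrom,
                        start=int(pos[run[0]]),
                        end=int(pos[run[-1]]),
                        probe_ids=tuple(sub.index[run]),
                        direction="gain" if mean_d > 0 else "loss",
                        mean_delta_beta=mean_d,
                        max_gap=int(gaps.max()) if len(gaps) else 0,
                    ))
            run.clear()

        for i in range(len(sub)):
            if not qualifies[i]:
                flush()
                continue
            if run:
                same_sign = np.sign(delta[i]) == np.sign(delta[run[-1]])
                close = (pos[i] - pos[run[-1]]) < max_gap_bp
                if same_sign and close:
                    run.append(i)
                    continue
                flush()
            run.append(i)
        flush()
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def annotate_regions(
    regions: Sequence[RegionCall],
    annotation: pd.DataFrame,
    dmrs: Sequence[KnownDMR] = (),
) -> list[RegionCall]:
    """Attach CpG-island, promoter and known-DMR-overlap flags.

    A region is a CpG island iff at least half its probes carry the island
    flag; it is a promoter region iff any probe is annotated as promoter.
    Known-DMR overlap is interval intersection of the region span with the
    DMR span (both 1-based inclusive).
    """
    out = []
    for r in regions:
        ann = annotation.loc[list(r.probe_ids)]
        cgi = bool(ann["cgi"].mean() >= 0.5)
        promoter = bool((ann["feature"] == "promoter").any())
        overlap = tuple(
            d.name for d in dmrs
            if d.chrom == r.chrom and d.start <= r.end and r.start <= d.end
        )
        out.append(r.with_flags(cgi=cgi, promoter=promoter, known_dmr_overlap=overlap))
    return out


def screen_report(regions: Sequence[RegionCall]) -> dict:
    """Headline counts for a set of annotated regions."""
    n = len(regions)
    n_cgi = sum(1 for r in regions if r.cgi)
    n_promoter = sum(1 for r in regions if r.promoter)
    return {
        "n_regions": n,
        "n_cgi": n_cgi,
        "cgi_fraction": (n_cgi / n) if n else 0.0,
        "promoter_fraction": (n_promoter / n) if n else 0.0,
        "n_gain": sum(1 for r in regions if r.direction == "gain"),
        "n_loss": sum(1 for r in regions if r.direction == "loss"),
        "n_known_dmr_overlap": sum(1 for r in regions if r.known_dmr_overlap),
    }
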