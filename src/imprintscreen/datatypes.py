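"""Core domain types shared across the screen.

The pipeline's universal carrier is :class:`MethylationDataset`: a probe
manifest aligned row-for-row with a beta-value matrix (probes x samples),
an optional detection p-value matrix of the same shape, and a sample sheet
assigning each array column to a biological group (androgenetic mole,
NLRP7-mutated mole, normal placenta, somatic tissue, sperm, blood).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Recognised sample groups.
ANDRO_CHM = "ANDRO_CHM"
NLRP7_RHM = "NLRP7_RHM"
PLACENTA_FIRST = "PLACENTA_FIRST"
PLACENTA_TERM = "PLACENTA_TERM"
SOMATIC = "SOMATIC"
SPERM = "SPERM"
BLOOD = "BLOOD"

VALID_GROUPS = (
    ANDRO_CHM,
    NLRP7_RHM,
    PLACENTA_FIRST,
    PLACENTA_TERM,
    SOMATIC,
    SPERM,
    BLOOD,
)

#: Gene-feature annotation of a probe.
VALID_FEATURES = ("promoter", "gene_body", "intergenic")

#: Parental origin of a germline DMR.
VALID_ORIGINS = ("maternal", "paternal")

#: Known-DMR category.
VALID_CATEGORIES = ("ubiquitous", "placenta_specific")

ANNOTATION_COLUMNS = ("chrom", "pos", "cgi", "feature")


class DataError(ValueError):
    """Raised when an input violates a dataset invariant."""


@dataclass(frozen=True)
class KnownDMR:
    """A previously characterised imprinted DMR interval (1-based, inclusive)."""

    name: str
    chrom: str
    start: int
    end: int
    origin: str  # maternal | paternal
    category: str  # ubiquitous | placenta_specific

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"DMR {self.name}: start {self.start} > end {self.end}")
        if self.origin not in VALID_ORIGINS:
            raise DataError(f"DMR {self.name}: unknown origin {self.origin!r}")
        if self.category not in VALID_CATEGORIES:
            raise DataError(f"DMR {self.name}: unknown category {self.category!r}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class RegionCall:
    """A maximal run of qualifying probes — the screen's unit of discovery.

    Coordinates are the positions of the first and last probe in the run
    (1-based, inclusive).  ``direction`` is ``gain`` for case-hypermethylated
    runs and ``loss`` for case-hypomethylated ones.
    """

    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    direction: str  # gain | loss
    mean_delta_beta: float
    max_gap: int
    cgi: Optional[bool] = None
    promoter: Optional[bool] = None
    known_dmr_overlap: tuple[str, ...] = ()
    label: Optional[str] = None

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise DataError("region with no probes")
        if self.direction not in ("gain", "loss"):
            raise DataError(f"unknown direction {self.direction!r}")
        if self.mean_delta_beta != 0 and (
            (self.mean_delta_beta > 0) != (self.direction == "gain")
        ):
            raise DataError(
                f"direction {self.direction} inconsistent with "
                f"mean_delta_beta {self.mean_delta_beta}"
            )

    def with_flags(self, **kwargs) -> "RegionCall":
        return replace(self, **kwargs)


@dataclass
class MethylationDataset:
    """Aligned probe annotation, beta matrix, detection p-values, sample sheet.

    Parameters
    ----------
    annotation : pd.DataFrame
        Indexed by probe id with columns ``chrom`` (str), ``pos`` (int,
        1-based), ``cgi`` (bool), ``feature`` (str).
    beta : pd.DataFrame
        Probes x samples, values in [0, 1] (NaN marks a missing signal).
    samples : pd.DataFrame
        Indexed by sample id with a ``group`` column.
    detection_p : pd.DataFrame, optional
        Same shape/index/columns as ``beta``.
    """

    annotation: pd.DataFrame
    beta: pd.DataFrame
    samples: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        ann, beta = self.annotation, self.beta
        if not ann.index.is_unique:
            dup = ann.index[ann.index.duplicated()][0]
            raise DataError(f"duplicate probe id in manifest: {dup}")
        if not ann.index.equals(beta.index):
            raise DataError("annotation and beta matrix rows are not aligned")
        missing_cols = set(ANNOTATION_COLUMNS) - set(ann.columns)
        if missing_cols:
            raise DataError(f"manifest missing columns: {sorted(missing_cols)}")
        vals = beta.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"beta value {vals[i, j]} outside [0, 1] at probe "
                f"{beta.index[i]!r}, sample {beta.columns[j]!r}"
            )
        if not self.samples.index.is_unique:
            raise DataError("duplicate sample id in sample sheet")
        unknown = set(self.samples["group"]) - set(VALID_GROUPS)
        if unknown:
            raise DataError(f"unknown sample group(s): {sorted(unknown)}")
        missing = set(beta.columns) - set(self.samples.index)
        if missing:
            raise DataError(f"matrix sample(s) absent from sample sheet: {sorted(missing)}")
        if self.detection_p is not None:
            if self.detection_p.shape != beta.shape:
                raise DataError("detection_p shape differs from beta")
            if not self.detection_p.index.equals(beta.index):
                raise DataError("detection_p rows not aligned with beta")

    # -- convenience ------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def groups_present(self) -> list[str]:
        present = set(self.samples.loc[self.beta.columns, "group"])
        return [g for g in VALID_GROUPS if g in present]

    def samples_in_group(self, *groups: str) -> list[str]:
        wanted = set(groups)
        grp = self.samples.loc[self.beta.columns, "group"]
        return [s for s, g in grp.items() if g in wanted]

    def subset_probes(self, probe_ids: Sequence[str] | pd.Index | np.ndarray) -> "MethylationDataset":
        """Return a new dataset restricted to ``probe_ids`` (order preserved)."""
        idx = pd.Index(probe_ids)
        return MethylationDataset(
            annotation=self.annotation.loc[idx],
            beta=self.beta.loc[idx],
            samples=self.samples,
            detection_p=None if self.detection_p is None else self.detection_p.loc[idx],
        )


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for one probe-exclusion step."""

    rule: str
    n_input: int
    n_removed: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


@dataclass(frozen=True)
class EBayesParams:
    """Scaled inverse-chi-square prior fitted to the per-probe variances.

    ``d0`` is the prior degrees of freedom (``inf`` when the variances carry
    no excess spread beyond sampling noise) and ``s0_sq`` the prior variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise DataError(f"prior df must be positive, got {self.d0}")
        if not (np.isfinite(self.s0_sq) and self.s0_sq > 0):
            raise DataError(f"prior variance must be finite positive, got {self.s0_sq}")


@dataclass(frozen=True)
class EpigenotypeProfile:
    """Per-group and per-sample mean beta over a region's probes."""

    region_id: str
    group_means: Mapping[str, float]
    per_sample_means: Mapping[str, float]
    n_probes: int = 0


@dataclass(frozen=True)
class EpigenotypeCall:
    region_id: str
    label: str
    retained_in: tuple[str, ...] = ()
    reason: str = ""


# Epigenotype labels
MATERNAL_GDMR_UBIQUITOUS = "MATERNAL_GDMR_UBIQUITOUS"
MATERNAL_GDMR_PLACENTA_SPECIFIC = "MATERNAL_GDMR_PLACENTA_SPECIFIC"
PATERNAL_GDMR = "PATERNAL_GDMR"
SECONDARY_DMR = "SECONDARY_DMR"
NOT_IMPRINTED_UNMETH = "NOT_IMPRINTED_UNMETH"
NOT_IMPRINTED_METH = "NOT_IMPRINTED_METH"
AMBIGUOUS = "AMBIGUOUS"

EPIGENOTYPE_LABELS = (
    MATERNAL_GDMR_UBIQUITOUS,
    MATERNAL_GDMR_PLACENTA_SPECIFIC,
    PATERNAL_GDMR,
    SECONDARY_DMR,
    NOT_IMPRINTED_UNMETH,
    NOT_IMPRINTED_METH,
    AMBIGUOUS,
)
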