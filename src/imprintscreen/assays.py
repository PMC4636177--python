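"""Interpreters and simulators for the orthogonal validation assays.

Array-level candidate DMRs are validated three ways:

* **bisulfite clone panels** — individual cloned DNA strands scored per
  CpG; allelic methylation shows as a bimodal clone population whose
  methylated clones share a SNP allele;
* **methylation-sensitive HpaII genotyping** — HpaII cuts unmethylated
  CCGG sites, so after digestion only methylated alleles amplify; a
  heterozygous SNP reduced to homozygosity proves single-allele
  methylation and the surviving allele names the methylated chromosome;
* **pyrosequencing outlier summaries** — a case value against the
  5th-95th percentile band of a control-placenta panel;
* **generic allelic-signal calls** — numeric allele fractions standing in
  for electropherogram peak reading of allele-specific RT-PCR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .datatypes import DataError

# ---------------------------------------------------------------------------
# Bisulfite clones
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BisulfiteClone:
    """One sequenced DNA strand: per-CpG methylation states and, when the
    amplicon spans a heterozygous SNP, the allele it came from."""

    clone_id: str
    cpg_states: tuple[bool, ...]
    allele: str = "unknown"  # A | B | unknown

    def __post_init__(self) -> None:
        if len(self.cpg_states) < 1:
            raise DataError(f"clone {self.clone_id}: no CpG states")
        if self.allele not in ("A", "B", "unknown"):
            raise DataError(f"clone {self.clone_id}: bad allele {self.allele!r}")

    @property
    def meth_fraction(self) -> float:
        return sum(self.cpg_states) / len(self.cpg_states)


@dataclass(frozen=True)
class BisulfiteCloneSet:
    region_id: str
    clones: tuple[BisulfiteClone, ...]
    conversion_error: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.conversion_error < 1):
            raise DataError("conversion_error must lie in [0, 1)")


@dataclass(frozen=True)
class CloneCall:
    call: str  # allelic | methylated | unmethylated | strand_mixture | inconclusive
    methylated_allele: Optional[str] = None
    fraction_hi: float = 0.0
    fraction_lo: float = 0.0
    per_allele_meth: Mapping[str, float] = field(default_factory=dict)


def call_clone_methylation(
    cloneset: BisulfiteCloneSet,
    clone_meth_hi: float = 0.7,
    clone_meth_lo: float = 0.3,
    min_fraction: float = 0.25,
    allele_purity: float = 0.8,
) -> CloneCall:
    """Classify a clone panel's methylation pattern.

    Each clone is classed by its CpG methylation fraction: hi
    (> ``clone_meth_hi``), lo (< ``clone_meth_lo``) or mixed.  The panel is

    * ``allelic`` iff hi and lo classes each hold >= ``min_fraction`` of
      clones and allele labels anchor them: hi clones concentrate
      (>= ``allele_purity``) on one allele, which differs from the lo
      clones' majority allele;
    * ``strand_mixture`` iff bimodal in the same sense but the allele
      anchoring is absent or fails;
    * ``methylated`` / ``unmethylated`` iff >= 75% of clones fall in one
      extreme class;
    * ``inconclusive`` otherwise, or with fewer than 4 clones.
    """
    clones = cloneset.clones
    n = len(clones)
    if n < 4:
        return CloneCall("inconclusive")
    fracs = np.array([c.meth_fraction for c in clones])
    hi = fracs > clone_meth_hi
    lo = fracs < clone_meth_lo
    f_hi = hi.mean()
    f_lo = lo.mean()

    per_allele: dict[str, float] = {}
    for al in ("A", "B"):
        sub = [c.meth_fraction for c in clones if c.allele == al]
        if sub:
            per_allele[al] = float(np.mean(sub))

    if f_hi >= min_fraction and f_lo >= min_fraction:
        hi_alleles = [c.allele for c, h in zip(clones, hi) if h and c.allele != "unknown"]
        lo_alleles = [c.allele for c, l in zip(clones, lo) if l and c.allele != "unknown"]
        if hi_alleles and lo_alleles:
            counts = {al: hi_alleles.count(al) for al in set(hi_alleles)}
            top = max(counts, key=counts.get)
            purity = counts[top] / len(hi_alleles)
            lo_counts = {al: lo_alleles.count(al) for al in set(lo_alleles)}
            lo_top = max(lo_counts, key=lo_counts.get)
            if purity >= allele_purity and top != lo_top:
                return CloneCall("allelic", methylated_allele=top,
                                 fraction_hi=f_hi, fraction_lo=f_lo,
                                 per_allele_meth=per_allele)
        return CloneCall("strand_mixture", fraction_hi=f_hi, fraction_lo=f_lo,
                         per_allele_meth=per_allele)
    if f_hi >= 0.75:
        return CloneCall("methylated", fraction_hi=f_hi, fraction_lo=f_lo,
                         per_allele_meth=per_allele)
    if f_lo >= 0.75:
        return CloneCall("unmethylated", fraction_hi=f_hi, fraction_lo=f_lo,
                         per_allele_meth=per_allele)
    return CloneCall("inconclusive", fraction_hi=f_hi, fraction_lo=f_lo,
                     per_allele_meth=per_allele)


# ---------------------------------------------------------------------------
# HpaII methylation-sensitive genotyping
# ---------------------------------------------------------------------------


def _norm_pair(pair) -> Optional[tuple[str, str]]:
    if pair is None:
        return None
    a, b = pair
    return tuple(sorted((str(a), str(b))))


@dataclass(frozen=True)
class HpaIIAssay:
    """Genotype calls at one SNP before and after HpaII digestion."""

    snp_id: str
    genotype_undigested: tuple[str, str]
    genotype_digested: Optional[tuple[str, str]] = None  # None = no product
    maternal_genotype: Optional[tuple[str, str]] = None
    paternal_genotype: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        und = set(self.genotype_undigested)
        if self.genotype_digested is not None:
            if not set(self.genotype_digested) <= und:
                raise DataError(
                    f"{self.snp_id}: digested allele(s) "
                    f"{set(self.genotype_digested) - und} absent from "
                    f"undigested genotype"
                )


@dataclass(frozen=True)
class HpaIICall:
    call: str  # allelic_methylation | both_methylated | unmethylated | uninformative
    methylated_allele: Optional[str] = None
    parental_origin: Optional[str] = None  # maternal | paternal
    flag: str = ""


def call_hpa2(assay: HpaIIAssay) -> HpaIICall:
    """Interpret a before/after-digestion genotype pair.

    Reduction to homozygosity (het before, hom after) proves allelic
    methylation; the surviving allele is the methylated chromosome.  A
    heterozygous digested call means both alleles carried methylation (or
    digestion was incomplete — flagged, indistinguishable at the genotype
    level).  No product after digestion means neither allele was protected.
    A homozygous input SNP is uninformative.  When parental genotypes are
    supplied and exactly one parent could have transmitted the surviving
    allele, the parental origin of the methylation is assigned.
    """
    und = _norm_pair(assay.genotype_undigested)
    dig = _norm_pair(assay.genotype_digested)
    if und[0] == und[1]:
        return HpaIICall("uninformative")
    if dig is None:
        return HpaIICall("unmethylated")
    if dig[0] == dig[1]:
        allele = dig[0]
        origin = None
        mat, pat = _norm_pair(assay.maternal_genotype), _norm_pair(assay.paternal_genotype)
        if mat is not None and pat is not None:
            could_mat = allele in mat
            could_pat = allele in pat
            if could_mat and not could_pat:
                origin = "maternal"
            elif could_pat and not could_mat:
                origin = "paternal"
        return HpaIICall("allelic_methylation", methylated_allele=allele,
                         parental_origin=origin)
    return HpaIICall("both_methylated",
                     flag="heterozygous after digestion: both alleles "
                          "methylated or digestion incomplete")


def simulate_hpa2(
    alleles: tuple[str, str],
    methylated: Mapping[str, bool],
    digestion_efficiency: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    snp_id: str = "snp",
    maternal_genotype: Optional[tuple[str, str]] = None,
    paternal_genotype: Optional[tuple[str, str]] = None,
) -> HpaIIAssay:
    """Simulate one digestion/amplification round.

    A methylated allele always survives digestion; an unmethylated allele
    escapes with probability ``1 - digestion_efficiency``.  Surviving
    alleles form the digested genotype (homozygous call when only one
    survives, no product when none does).
    """
    if not (0 <= digestion_efficiency <= 1):
        raise DataError("digestion_efficiency must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    survivors = []
    for al in alleles:
        if methylated.get(al, False) or rng.random() >= digestion_efficiency:
            survivors.append(al)
    if not survivors:
        digested = None
    elif len(set(survivors)) == 1:
        digested = (survivors[0], survivors[0])
    else:
        digested = tuple(sorted(set(survivors))[:2])
    return HpaIIAssay(
        snp_id=snp_id,
        genotype_undigested=tuple(sorted(alleles)),
        genotype_digested=digested,
        maternal_genotype=maternal_genotype,
        paternal_genotype=paternal_genotype,
    )


# ---------------------------------------------------------------------------
# Pyrosequencing summaries and generic allelic-signal calls
# ---------------------------------------------------------------------------


def pyro_summary(control_values: Sequence[float], case_value: float) -> dict:
    """Case value against the control panel's median and 5-95% band.

    Percentiles are empirical with linear interpolation; the case is an
    outlier iff it falls outside [p5, p95].
    """
    controls = np.asarray(control_values, dtype=float)
    if controls.size < 5:
        raise DataError(f"need >= 5 control values, got {controls.size}")
    p5, med, p95 = np.percentile(controls, [5, 50, 95])
    return {
        "median": float(med),
        "p5": float(p5),
        "p95": float(p95),
        "case": float(case_value),
        "outlier": bool(case_value < p5 or case_value > p95),
    }


def call_allelic_signal(
    allele_fractions: tuple[float, float],
    mono_threshold: float = 0.9,
) -> str:
    """Monoallelic vs biallelic call from two allele signal fractions.

    ``monoallelic`` iff the larger fraction is >= ``mono_threshold`` of the
    total; ``biallelic`` iff both are >= 25% of the total; ``inconclusive``
    otherwise (including zero total signal).
    """
    a, b = allele_fractions
    if a < 0 or b < 0:
        raise DataError("allele fractions must be non-negative")
    total = a + b
    if total == 0:
        return "inconclusive"
    fa, fb = a / total, b / total
    if max(fa, fb) >= mono_threshold:
        return "monoallelic"
    if fa >= 0.25 and fb >= 0.25:
        return "biallelic"
    return "inconclusive"
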