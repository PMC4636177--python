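"""Classification of a region's germline epigenotype from its beta profile
across sample groups.

The biology behind the decision table: a germline DMR carries methylation
on exactly one parental allele, so normal placenta (biparental) sits near
beta = 0.5.  An androgenetic mole has two paternal genomes: maternally
methylated DMRs lose all methylation there while paternally methylated
DMRs become fully methylated.  NLRP7-mutated biparental moles fail to
acquire maternal (oocyte) methylation only, so maternal DMRs show
lack-of-methylation (LOM) while paternal DMRs keep their partial state.
Sperm is unmethylated at maternal DMRs.  Somatic tissue distinguishes
ubiquitous maternal DMRs (partial) from placenta-specific ones (LOM).
Secondary DMRs — allelic methylation acquired post-fertilisation on the
paternal allele under control of a maternal germline DMR — appear fully
methylated in both mole types.

Thresholds are interpretive dials, not measurements: ``lo``/``hi`` bound
the unmethylated/methylated states and ``part_lo``/``part_hi`` the partial
(allelic) band, with wide margins between the idealised states (LOM ~ 0,
partial ~ 0.5, full ~ 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AMBIGUOUS,
    ANDRO_CHM,
    EpigenotypeCall,
    EpigenotypeProfile,
    MATERNAL_GDMR_PLACENTA_SPECIFIC,
    MATERNAL_GDMR_UBIQUITOUS,
    MethylationDataset,
    NLRP7_RHM,
    NOT_IMPRINTED_METH,
    NOT_IMPRINTED_UNMETH,
    PATERNAL_GDMR,
    PLACENTA_FIRST,
    PLACENTA_TERM,
    SECONDARY_DMR,
    SOMATIC,
    SPERM,
)


@dataclass(frozen=True)
class EpigenotypeThresholds:
    lo: float = 0.15
    part_lo: float = 0.30
    part_hi: float = 0.70
    hi: float = 0.85

    def partial(self, x: float) -> bool:
        return self.part_lo <= x <= self.part_hi


def profile_region(
    dataset: MethylationDataset,
    probe_ids: Sequence[str],
    region_id: str,
) -> Optional[EpigenotypeProfile]:
    """Unweighted mean beta over (region probes x group samples).

    Returns None (callers skip with a warning) when no region probe
    survived QC.
    """
    present = [p for p in probe_ids if p in dataset.beta.index]
    if not present:
        return None
    block = dataset.beta.loc[present]
    per_sample = {s: float(block[s].mean()) for s in block.columns}
    groups = dataset.samples.loc[block.columns, "group"]
    group_means = {
        g: float(block[[s for s in block.columns if groups[s] == g]].to_numpy().mean())
        for g in sorted(set(groups))
    }
    return EpigenotypeProfile(
        region_id=region_id,
        group_means=group_means,
        per_sample_means=per_sample,
        n_probes=len(present),
    )


def _pooled_placenta(means: Mapping[str, float]) -> Optional[float]:
    vals = [means[g] for g in (PLACENTA_FIRST, PLACENTA_TERM) if g in means]
    return float(np.mean(vals)) if vals else None


def classify_epigenotype(
    profile: EpigenotypeProfile,
    thresholds: EpigenotypeThresholds = EpigenotypeThresholds(),
    sample_groups: Optional[Mapping[str, str]] = None,
) -> EpigenotypeCall:
    """Map a beta profile to a germline epigenotype label.

    Decision table (placenta = pooled first-trimester + term mean), first
    match wins:

    * not imprinted: every available group below ``lo`` (UNMETH) or above
      ``hi`` (METH) — checked first so a uniformly methylated promoter is
      never mistaken for a secondary DMR;
    * maternal germline DMR: placenta partial, both mole types LOM (and
      sperm LOM when present); placenta-specific iff somatic is also LOM,
      ubiquitous iff somatic is partial;
    * paternal germline DMR (H19-type): placenta partial, androgenetic
      mole fully methylated, RHM partial (paternal imprint intact);
    * secondary DMR (ZDBF2/ZNF597-type): fully methylated in both mole
      types while placenta is partial or methylated;
    * anything else: AMBIGUOUS.

    The maternal-LOM test is robust to mosaic imprint retention: when
    ``sample_groups`` (sample id -> group) is supplied, mole samples whose
    per-sample mean sits in the partial band are excluded from their
    group's mean — provided they are a minority (at most half the group) —
    and reported in ``retained_in`` when the maternal call stands.
    Without ``sample_groups`` plain group means are used.
    """
    th = thresholds
    m = profile.group_means
    placenta = _pooled_placenta(m)
    andro = m.get(ANDRO_CHM)
    rhm = m.get(NLRP7_RHM)
    sperm = m.get(SPERM)
    somatic = m.get(SOMATIC)

    if placenta is None or (andro is None and rhm is None):
        return EpigenotypeCall(profile.region_id, AMBIGUOUS,
                               reason="missing required group")

    available = [v for v in (placenta, andro, rhm, sperm, somatic) if v is not None]

    # Mosaic imprint retention: a minority of mole samples may keep the
    # partial state at a bona fide maternal DMR (FAM50B-type inter-mole
    # variation).  For the LOM test only, exclude partial-band samples when
    # they are at most half of their group; they are reported in
    # ``retained_in`` if the maternal call stands.
    retained_candidates: list[str] = []
    andro_adj, rhm_adj = andro, rhm
    if sample_groups is not None:
        for grp in (ANDRO_CHM, NLRP7_RHM):
            members = [s for s, g in sample_groups.items()
                       if g == grp and s in profile.per_sample_means]
            partial = [s for s in members
                       if th.partial(profile.per_sample_means[s])]
            if partial and len(partial) * 2 <= len(members):
                rest = [profile.per_sample_means[s] for s in members
                        if s not in partial]
                adj = float(np.mean(rest))
                if grp == ANDRO_CHM:
                    andro_adj = adj
                else:
                    rhm_adj = adj
                retained_candidates.extend(partial)

    label = AMBIGUOUS
    reason = ""
    expects_mole_lom = False

    mole_lom = ((andro_adj is None or andro_adj < th.lo)
                and (rhm_adj is None or rhm_adj < th.lo)
                and not (andro_adj is None and rhm_adj is None))
    if all(v < th.lo for v in available):
        label = NOT_IMPRINTED_UNMETH
    elif all(v > th.hi for v in available):
        label = NOT_IMPRINTED_METH
    elif th.partial(placenta) and mole_lom and (sperm is None or sperm < th.lo):
        expects_mole_lom = True
        if somatic is not None and somatic < th.lo:
            label = MATERNAL_GDMR_PLACENTA_SPECIFIC
        elif somatic is None or th.partial(somatic):
            label = MATERNAL_GDMR_UBIQUITOUS
        else:
            label = AMBIGUOUS
            reason = "somatic level fits neither LOM nor partial"
    elif (th.partial(placenta) and andro is not None and andro > th.hi
          and rhm is not None and th.partial(rhm)):
        label = PATERNAL_GDMR
    elif (andro is not None and andro > th.hi and rhm is not None and rhm > th.hi
          and (placenta > th.hi or th.partial(placenta))):
        label = SECONDARY_DMR

    retained: tuple[str, ...] = ()
    if expects_mole_lom:
        retained = tuple(retained_candidates)
    return EpigenotypeCall(profile.region_id, label, retained_in=retained,
                           reason=reason)


def profile_and_classify(
    dataset: MethylationDataset,
    regions: Mapping[str, Sequence[str]],
    thresholds: EpigenotypeThresholds = EpigenotypeThresholds(),
) -> tuple[list[EpigenotypeProfile], list[EpigenotypeCall]]:
    """Profile and classify every region in ``regions`` (id -> probe ids).

    Regions with zero retained probes are skipped.
    """
    sample_groups = dict(dataset.samples.loc[dataset.beta.columns, "group"])
    profiles: list[EpigenotypeProfile] = []
    calls: list[EpigenotypeCall] = []
    for rid, probes in regions.items():
        prof = profile_region(dataset, probes, rid)
        if prof is None:
            continue
        profiles.append(prof)
        calls.append(classify_epigenotype(prof, thresholds, sample_groups))
    return profiles, calls


def heatmap_matrix(
    dataset: MethylationDataset,
    regions: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Regions x samples matrix of mean beta, for external heatmap plotting."""
    rows = {}
    for rid, probes in regions.items():
        present = [p for p in probes if p in dataset.beta.index]
        if present:
            rows[rid] = dataset.beta.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T
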