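"""Seeded generator of complete synthetic fixtures with the statistical
structure the screen assumes.

The generator lays out CpG islands (tight probe clusters, 20-200 bp
spacing) separated by gaps wider than the region caller's 500 bp rule, so
no called region can span two islands and ground-truth matching is
unambiguous.  Each island is assigned an epigenotype class whose idealised
beta targets per sample group follow the imprinting biology: partial
(~0.5) methylation at imprinted DMRs in biparental placenta, lack of
methylation (~0.03) at maternal DMRs in androgenetic moles, NLRP7-mutated
moles and sperm, full methylation (~0.97) at paternal DMRs in androgenetic
moles, and somatic-tissue LOM at placenta-specific DMRs.  Per-sample
imprint retention (a mole sample keeping the partial state at a maternal
DMR) models the inter-mole variation seen in consecutive moles from one
patient.

Everything is reproducible from a single integer seed via an
integer-state PCG64 generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as isio
from .datatypes import (
    ANDRO_CHM,
    BLOOD,
    DataError,
    KnownDMR,
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
from .assays import BisulfiteClone, BisulfiteCloneSet

# Idealised beta states.
LOM = 0.03
PARTIAL = 0.50
FULL = 0.97

#: Island classes and their per-group beta targets.
CLASS_TARGETS: dict[str, dict[str, float]] = {
    "maternal_ubiquitous": {
        PLACENTA_FIRST: PARTIAL, PLACENTA_TERM: PARTIAL, ANDRO_CHM: LOM,
        NLRP7_RHM: LOM, SPERM: LOM, SOMATIC: PARTIAL, BLOOD: PARTIAL,
    },
    "maternal_placenta_specific": {
        PLACENTA_FIRST: PARTIAL, PLACENTA_TERM: PARTIAL, ANDRO_CHM: LOM,
        NLRP7_RHM: LOM, SPERM: LOM, SOMATIC: LOM, BLOOD: LOM,
    },
    "paternal": {
        PLACENTA_FIRST: PARTIAL, PLACENTA_TERM: PARTIAL, ANDRO_CHM: FULL,
        NLRP7_RHM: PARTIAL, SPERM: FULL, SOMATIC: PARTIAL, BLOOD: PARTIAL,
    },
    "secondary": {
        PLACENTA_FIRST: PARTIAL, PLACENTA_TERM: PARTIAL, ANDRO_CHM: FULL,
        NLRP7_RHM: FULL, SPERM: LOM, SOMATIC: PARTIAL, BLOOD: PARTIAL,
    },
    "not_imprinted_unmeth": {
        PLACENTA_FIRST: LOM, PLACENTA_TERM: LOM, ANDRO_CHM: LOM,
        NLRP7_RHM: LOM, SPERM: LOM, SOMATIC: LOM, BLOOD: LOM,
    },
    "not_imprinted_meth": {
        PLACENTA_FIRST: FULL, PLACENTA_TERM: FULL, ANDRO_CHM: FULL,
        NLRP7_RHM: FULL, SPERM: FULL, SOMATIC: FULL, BLOOD: FULL,
    },
}

#: Expected classifier label per island class.
CLASS_LABELS = {
    "maternal_ubiquitous": MATERNAL_GDMR_UBIQUITOUS,
    "maternal_placenta_specific": MATERNAL_GDMR_PLACENTA_SPECIFIC,
    "paternal": PATERNAL_GDMR,
    "secondary": SECONDARY_DMR,
    "not_imprinted_unmeth": NOT_IMPRINTED_UNMETH,
    "not_imprinted_meth": NOT_IMPRINTED_METH,
}

MATERNAL_CLASSES = ("maternal_ubiquitous", "maternal_placenta_specific")

#: Classes differential in the screen's case/control contrast
#: (NLRP7_RHM vs pooled placenta).
DIFFERENTIAL_CLASSES = ("maternal_ubiquitous", "maternal_placenta_specific",
                        "secondary")


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic run.

    Group sizes default to the study design: 4 androgenetic moles,
    5 NLRP7-mutated moles, 3 first-trimester + 4 term placentas, somatic
    tissues and a sperm sample.
    """

    seed: int = 0
    n_islands: int = 200
    probes_per_island: tuple[int, int] = (3, 8)
    intra_island_spacing: tuple[int, int] = (20, 200)
    inter_island_gap: int = 600
    class_proportions: dict[str, float] = field(default_factory=lambda: {
        "maternal_ubiquitous": 0.10,
        "maternal_placenta_specific": 0.15,
        "paternal": 0.05,
        "secondary": 0.10,
        "not_imprinted_unmeth": 0.35,
        "not_imprinted_meth": 0.25,
    })
    beta_noise_sd: float = 0.05
    noise_model: str = "truncnorm"  # truncnorm | beta
    group_sizes: dict[str, int] = field(default_factory=lambda: {
        ANDRO_CHM: 4, NLRP7_RHM: 5, PLACENTA_FIRST: 3, PLACENTA_TERM: 4,
        SOMATIC: 4, SPERM: 1,
    })
    detection_fail_rate: float = 0.001
    retention_rate: float = 0.05
    promoter_fraction: float = 0.8
    n_chromosomes: int = 4
    clones_per_set: int = 12
    cpgs_per_clone: int = 10
    conversion_error: float = 0.02

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"class proportions sum to {total}, expected 1")
        unknown = set(self.class_proportions) - set(CLASS_TARGETS)
        if unknown:
            raise DataError(f"unknown island class(es): {sorted(unknown)}")
        if self.probes_per_island[0] < 1 or self.intra_island_spacing[0] < 1:
            raise DataError("probe counts and spacings must be positive")
        if self.inter_island_gap <= self.intra_island_spacing[1]:
            raise DataError("inter-island gap must exceed intra-island spacing")


@dataclass
class IslandTruth:
    island_id: str
    class_label: str
    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    promoter: bool
    retained_samples: tuple[str, ...] = ()

    @property
    def expected_label(self) -> str:
        return CLASS_LABELS[self.class_label]

    @property
    def differential(self) -> bool:
        return self.class_label in DIFFERENTIAL_CLASSES


@dataclass
class GroundTruth:
    islands: list[IslandTruth]

    def differential_islands(self) -> list[IslandTruth]:
        return [i for i in self.islands if i.differential]

    def by_id(self) -> dict[str, IslandTruth]:
        return {i.island_id: i for i in self.islands}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            [asdict(i) for i in self.islands], indent=1, default=list))


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Deterministic class counts from the proportions, order shuffled."""
    names = sorted(config.class_proportions)
    counts = {c: int(np.floor(config.class_proportions[c] * config.n_islands))
              for c in names}
    short = config.n_islands - sum(counts.values())
    # distribute the rounding remainder to the largest fractional parts
    fracs = sorted(names, key=lambda c: -(config.class_proportions[c]
                                          * config.n_islands
                                          - counts[c]))
    for c in fracs[:short]:
        counts[c] += 1
    labels = [c for c in names for _ in range(counts[c])]
    return [labels[i] for i in rng.permutation(len(labels))]


def generate_manifest(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Lay out islands of clustered probes and assign each a class.

    Islands are separated by at least ``inter_island_gap`` bp (default 600,
    above the caller's 500 bp rule).  Island probes carry the CpG-island
    flag; a ``promoter_fraction`` share of islands is annotated as
    promoter.
    """
    rng = rng or np.random.default_rng(config.seed)
    classes = _assign_classes(config, rng)
    rows = []
    islands: list[IslandTruth] = []
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: 10_000 for c in chroms}
    lo_n, hi_n = config.probes_per_island
    lo_s, hi_s = config.intra_island_spacing
    for k, cls in enumerate(classes):
        chrom = chroms[k % len(chroms)]
        n_probes = int(rng.integers(lo_n, hi_n + 1))
        pos = cursors[chrom]
        positions = [pos]
        for _ in range(n_probes - 1):
            pos += int(rng.integers(lo_s, hi_s + 1))
            positions.append(pos)
        promoter = bool(rng.random() < config.promoter_fraction)
        pids = tuple(f"cg{k:05d}_{j:02d}" for j in range(n_probes))
        for pid, p in zip(pids, positions):
            rows.append({"probe_id": pid, "chrom": chrom, "pos": p,
                         "cgi": True,
                         "feature": "promoter" if promoter else "gene_body"})
        islands.append(IslandTruth(
            island_id=f"island{k:05d}", class_label=cls, chrom=chrom,
            start=positions[0], end=positions[-1], probe_ids=pids,
            promoter=promoter,
        ))
        cursors[chrom] = positions[-1] + config.inter_island_gap + int(rng.integers(0, 500))
    ann = pd.DataFrame(rows).set_index("probe_id")
    return ann, GroundTruth(islands)


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for group in sorted(config.group_sizes):
        for i in range(config.group_sizes[group]):
            rows.append({"sample_id": f"{group}_{i + 1}", "group": group})
    return pd.DataFrame(rows).set_index("sample_id")


def _noise(rng: np.random.Generator, target: float, sd: float, size: int,
           model: str) -> np.ndarray:
    if sd == 0:
        return np.full(size, target)
    if model == "truncnorm":
        return np.clip(target + rng.normal(0.0, sd, size=size), 0.0, 1.0)
    if model == "beta":
        # moment-matched beta draw; variance capped by the mean constraint
        var = min(sd ** 2, target * (1 - target) * 0.99)
        k = target * (1 - target) / var - 1
        return rng.beta(target * k, (1 - target) * k, size=size)
    raise DataError(f"unknown noise model {model!r}")


def generate_betas(
    annotation: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> MethylationDataset:
    """Draw the beta and detection-p matrices for a manifest + truth pair.

    With probability ``retention_rate`` a (mole sample x maternal island)
    pair keeps the partial target instead of LOM; retained pairs are
    recorded in the truth.  Detection p-values sit near zero except for a
    ``detection_fail_rate`` share of cells pushed above 0.01.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    samples = _sample_sheet(config)
    sample_ids = list(samples.index)
    groups = samples["group"]
    mole_samples = [s for s in sample_ids if groups[s] in (ANDRO_CHM, NLRP7_RHM)]

    row_of = {pid: i for i, pid in enumerate(annotation.index)}
    arr = np.empty((len(annotation), len(sample_ids)), dtype=float)
    for isl in truth.islands:
        targets = CLASS_TARGETS[isl.class_label]
        retained = []
        if isl.class_label in MATERNAL_CLASSES and config.retention_rate > 0:
            retained = [s for s in mole_samples
                        if rng.random() < config.retention_rate]
        isl.retained_samples = tuple(retained)
        rows_idx = np.array([row_of[p] for p in isl.probe_ids])
        n = len(rows_idx)
        for j, s in enumerate(sample_ids):
            target = targets[groups[s]]
            if s in retained:
                target = PARTIAL
            arr[rows_idx, j] = _noise(
                rng, target, config.beta_noise_sd, n, config.noise_model)
    beta = pd.DataFrame(arr, index=annotation.index, columns=sample_ids)

    det = pd.DataFrame(
        rng.uniform(0.0, 0.005, size=beta.shape),
        index=beta.index, columns=beta.columns,
    )
    if config.detection_fail_rate > 0:
        fail = rng.random(beta.shape) < config.detection_fail_rate
        det = det.where(~fail, rng.uniform(0.011, 0.5, size=beta.shape))
    return MethylationDataset(annotation=annotation, beta=beta,
                              samples=samples, detection_p=det)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[MethylationDataset, GroundTruth]:
    """Manifest + betas in one call, reproducible from ``config.seed``."""
    seq = np.random.SeedSequence(config.seed)
    rng_manifest, rng_beta = [np.random.default_rng(s) for s in seq.spawn(2)]
    ann, truth = generate_manifest(config, rng_manifest)
    ds = generate_betas(ann, truth, config, rng_beta)
    return ds, truth


def known_dmrs_from_truth(truth: GroundTruth, pad: int = 10) -> list[KnownDMR]:
    """Known-DMR list covering the planted germline-DMR islands."""
    out = []
    for isl in truth.islands:
        if isl.class_label == "maternal_ubiquitous":
            origin, category = "maternal", "ubiquitous"
        elif isl.class_label == "maternal_placenta_specific":
            origin, category = "maternal", "placenta_specific"
        elif isl.class_label == "paternal":
            origin, category = "paternal", "ubiquitous"
        else:
            continue
        out.append(KnownDMR(name=isl.island_id, chrom=isl.chrom,
                            start=max(1, isl.start - pad), end=isl.end + pad,
                            origin=origin, category=category))
    return out


def generate_clonesets(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[BisulfiteCloneSet]:
    """Bisulfite clone panels for the planted maternal-DMR islands.

    Half the clones come from the methylated maternal allele (A), half
    from the unmethylated paternal allele (B); each CpG state flips with
    probability ``conversion_error`` (incomplete conversion or sequencing
    error).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    out = []
    for isl in truth.islands:
        if isl.class_label not in MATERNAL_CLASSES:
            continue
        clones = []
        n = config.clones_per_set
        for j in range(n):
            maternal = j < n // 2
            base = maternal  # maternal allele methylated
            states = tuple(
                bool(base ^ (rng.random() < config.conversion_error))
                for _ in range(config.cpgs_per_clone)
            )
            clones.append(BisulfiteClone(
                clone_id=f"{isl.island_id}_c{j:02d}",
                cpg_states=states,
                allele="A" if maternal else "B",
            ))
        out.append(BisulfiteCloneSet(region_id=isl.island_id,
                                     clones=tuple(clones),
                                     conversion_error=config.conversion_error))
    return out


def evaluate_screen(regions, truth: GroundTruth) -> dict:
    """Sensitivity / false-discovery proportion of region calls vs truth.

    A called region is a true positive iff it overlaps a planted island of
    a differential class (differential in the RHM vs placenta contrast); a
    differential island is recovered iff at least one region overlaps it.
    """
    diff = truth.differential_islands()
    def overlaps(region, isl) -> bool:
        return (region.chrom == isl.chrom and region.start <= isl.end
                and isl.start <= region.end)
    n_true = sum(1 for isl in diff if any(overlaps(r, isl) for r in regions))
    n_fp = sum(1 for r in regions if not any(overlaps(r, isl) for isl in diff))
    return {
        "n_differential": len(diff),
        "n_recovered": n_true,
        "sensitivity": n_true / len(diff) if diff else float("nan"),
        "n_regions": len(regions),
        "n_false": n_fp,
        "fdp": n_fp / len(regions) if regions else 0.0,
    }


def evaluate_epigenotype(calls_by_island: dict[str, str],
                         truth: GroundTruth) -> dict:
    """Label accuracy of epigenotype calls made on the planted islands."""
    islands = truth.by_id()
    n = n_correct = 0
    maternal_total = maternal_subtype_correct = 0
    for rid, label in calls_by_island.items():
        isl = islands[rid]
        n += 1
        if label == isl.expected_label:
            n_correct += 1
        if (isl.class_label in MATERNAL_CLASSES
                and label in (MATERNAL_GDMR_UBIQUITOUS,
                              MATERNAL_GDMR_PLACENTA_SPECIFIC)):
            maternal_total += 1
            if label == isl.expected_label:
                maternal_subtype_correct += 1
    return {
        "n": n,
        "accuracy": n_correct / n if n else float("nan"),
        "maternal_called": maternal_total,
        "maternal_subtype_accuracy": (maternal_subtype_correct / maternal_total
                                      if maternal_total else float("nan")),
    }


def write_workspace(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Emit a complete demo workspace in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds, truth = simulate_dataset(config)
    paths = isio.write_dataset(ds, outdir)
    dmrs = known_dmrs_from_truth(truth)
    dmr_path = outdir / "known_dmrs.tsv"
    pd.DataFrame([{
        "name": d.name, "chrom": d.chrom, "start": d.start, "end": d.end,
        "origin": d.origin, "category": d.category,
    } for d in dmrs]).to_csv(dmr_path, sep="\t", index=False)
    paths["known_dmrs"] = dmr_path
    truth_path = outdir / "ground_truth.json"
    truth.to_json(truth_path)
    paths["ground_truth"] = truth_path

    clone_path = outdir / "clones.tsv"
    rows = []
    for cs in generate_clonesets(truth, config):
        for c in cs.clones:
            rows.append({
                "region_id": cs.region_id, "clone_id": c.clone_id,
                "allele": c.allele,
                "cpg_states": "".join("1" if s else "0" for s in c.cpg_states),
            })
    pd.DataFrame(rows).to_csv(clone_path, sep="\t", index=False)
    paths["clones"] = clone_path
    return paths
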