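"""Model/results interface to the screen.

:class:`ImprintingScreen` bundles a dataset with the screen's parameters;
``fit()`` runs QC -> differential testing -> region calling -> annotation
-> epigenotyping and returns a :class:`ScreenResults` holding every stage
output, with ``summary()`` for a human-readable digest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as isio
from . import qc as isqc
from .datatypes import (
    EBayesParams,
    EpigenotypeCall,
    EpigenotypeProfile,
    FilterReport,
    KnownDMR,
    MethylationDataset,
    NLRP7_RHM,
    PLACENTA_FIRST,
    PLACENTA_TERM,
    RegionCall,
)
from .diffmeth import run_diffmeth
from .epigenotype import (
    EpigenotypeThresholds,
    heatmap_matrix,
    profile_and_classify,
)
from .regions import annotate_regions, call_regions, screen_report

SCHEMA_VERSION = 1


@dataclass
class ScreenParams:
    """All tunable screen parameters with their defaults."""

    case_group: str = NLRP7_RHM
    control_groups: tuple[str, ...] = (PLACENTA_FIRST, PLACENTA_TERM)
    detection_p_max: float = 0.01
    detection_max_fail_fraction: float = 0.0
    sex_chroms: tuple[str, ...] = ("chrX",)
    min_probes: int = 3
    max_gap_bp: int = 500
    p_max: float = 0.01
    min_mean_abs_delta: float = 0.2
    epigenotype_thresholds: EpigenotypeThresholds = field(
        default_factory=EpigenotypeThresholds)


class ImprintingScreen:
    """The genome-wide imprinting-defect screen as a fittable model.

    Parameters
    ----------
    dataset : MethylationDataset
        Probe manifest, beta matrix, optional detection p-values, sample
        sheet.
    known_dmrs : sequence of KnownDMR, optional
        Reference imprinted DMRs for overlap annotation and tallies.
    params : ScreenParams, optional
        Screen thresholds; keyword arguments override individual fields.
    """

    def __init__(
        self,
        dataset: MethylationDataset,
        known_dmrs: Sequence[KnownDMR] = (),
        params: Optional[ScreenParams] = None,
        **overrides,
    ) -> None:
        self.dataset = dataset
        self.known_dmrs = list(known_dmrs)
        p = params or ScreenParams()
        for k, v in overrides.items():
            if not hasattr(p, k):
                raise TypeError(f"unknown screen parameter {k!r}")
            setattr(p, k, v)
        self.params = p

    @classmethod
    def from_files(
        cls,
        manifest_path,
        beta_path,
        samplesheet_path,
        detection_path=None,
        known_dmrs_path=None,
        **kwargs,
    ) -> "ImprintingScreen":
        dataset = isio.read_dataset(manifest_path, beta_path, samplesheet_path,
                                    detection_path)
        dmrs = isio.read_known_dmrs(known_dmrs_path) if known_dmrs_path else ()
        return cls(dataset, known_dmrs=dmrs, **kwargs)

    # -- fitting ----------------------------------------------------------
    def fit(self) -> "ScreenResults":
        p = self.params
        ds_qc, reports = isqc.apply_qc(
            self.dataset,
            p_max=p.detection_p_max,
            max_fail_fraction=p.detection_max_fail_fraction,
            sex_chroms=set(p.sex_chroms),
        )
        if ds_qc.n_probes == 0:
            raise isqc.DataError("no probes retained after QC")
        prior, stats = run_diffmeth(ds_qc, p.case_group, p.control_groups)
        regions = call_regions(
            stats,
            min_probes=p.min_probes,
            max_gap_bp=p.max_gap_bp,
            p_max=p.p_max,
            min_mean_abs_delta=p.min_mean_abs_delta,
        )
        regions = annotate_regions(regions, ds_qc.annotation, self.known_dmrs)
        region_probes = {r.region_id: list(r.probe_ids) for r in regions}
        profiles, calls = profile_and_classify(
            ds_qc, region_probes, p.epigenotype_thresholds)
        label_by_region = {c.region_id: c.label for c in calls}
        regions = [r.with_flags(label=label_by_region.get(r.region_id))
                   for r in regions]
        dmr_probe_map = isio.map_probes_to_known_dmrs(ds_qc, self.known_dmrs)
        return ScreenResults(
            model=self,
            dataset_qc=ds_qc,
            filter_reports=reports,
            prior=prior,
            probe_stats=stats,
            regions=regions,
            profiles=profiles,
            calls=calls,
            known_dmr_probe_map=dmr_probe_map,
        )


@dataclass
class ScreenResults:
    """Everything the fitted screen produced."""

    model: ImprintingScreen
    dataset_qc: MethylationDataset
    filter_reports: list[FilterReport]
    prior: EBayesParams
    probe_stats: pd.DataFrame
    regions: list[RegionCall]
    profiles: list[EpigenotypeProfile]
    calls: list[EpigenotypeCall]
    known_dmr_probe_map: dict[str, list[str]]

    # -- digests ----------------------------------------------------------
    @property
    def report(self) -> dict:
        rep = screen_report(self.regions)
        label_counts: dict[str, int] = {}
        for c in self.calls:
            label_counts[c.label] = label_counts.get(c.label, 0) + 1
        by_cat: dict[str, int] = {}
        cat_of = {d.name: d.category for d in self.model.known_dmrs}
        for name, probes in self.known_dmr_probe_map.items():
            cat = cat_of.get(name, "unknown")
            by_cat[cat] = by_cat.get(cat, 0) + len(probes)
        return {
            "schema_version": SCHEMA_VERSION,
            "qc": isqc.qc_summary(self.filter_reports),
            "ebayes": {"d0": None if np.isinf(self.prior.d0) else self.prior.d0,
                       "s0_sq": self.prior.s0_sq},
            "screen": rep,
            "epigenotype_label_counts": label_counts,
            "known_dmr_probe_counts": by_cat,
            "n_known_dmrs": len(self.model.known_dmrs),
        }

    def region_table(self) -> pd.DataFrame:
        return isio.regions_to_frame(self.regions)

    def summary(self) -> str:
        rep = self.report
        qc = rep["qc"]
        lines = [
            "Imprinting-defect methylation screen",
            "=" * 42,
            f"probes in / retained:     {qc.get('n_input', 0)} / {qc.get('n_retained', 0)}",
            f"case group:               {self.model.params.case_group} "
            f"(n={int(self.probe_stats['n_case'].iloc[0]) if len(self.probe_stats) else 0})",
            f"control groups:           {'+'.join(self.model.params.control_groups)} "
            f"(n={int(self.probe_stats['n_control'].iloc[0]) if len(self.probe_stats) else 0})",
            f"eBayes prior:             d0={self.prior.d0:.3g}, "
            f"s0^2={self.prior.s0_sq:.3g}",
            f"candidate regions:        {rep['screen']['n_regions']} "
            f"(gain {rep['screen']['n_gain']}, loss {rep['screen']['n_loss']})",
            f"CpG-island regions:       {rep['screen']['n_cgi']} "
            f"({100 * rep['screen']['cgi_fraction']:.1f}%)",
            f"promoter regions:         {100 * rep['screen']['promoter_fraction']:.1f}%",
        ]
        if rep["epigenotype_label_counts"]:
            lines.append("epigenotype labels:")
            for label, n in sorted(rep["epigenotype_label_counts"].items()):
                lines.append(f"  {label:32s} {n}")
        if rep["known_dmr_probe_counts"]:
            lines.append("known-DMR probe tallies:")
            for cat, n in sorted(rep["known_dmr_probe_counts"].items()):
                lines.append(f"  {cat:32s} {n}")
        return "\n".join(lines)

    # -- exports ----------------------------------------------------------
    def save(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["probe_stats"] = outdir / "probe_stats.tsv"
        cols = ["chrom", "pos", "delta_beta", "s_sq", "s_sq_post", "t_mod", "p_value"]
        self.probe_stats[cols].to_csv(paths["probe_stats"], sep="\t",
                                      float_format="%.6g")
        paths["regions_bed"] = outdir / "regions.bed"
        isio.write_regions_bed(self.regions, paths["regions_bed"])
        paths["regions_tsv"] = outdir / "regions.tsv"
        self.region_table().to_csv(paths["regions_tsv"], sep="\t", index=False,
                                   float_format="%.6g")
        paths["calls"] = outdir / "epigenotype_calls.tsv"
        pd.DataFrame([{
            "region_id": c.region_id, "label": c.label,
            "retained_in": ",".join(c.retained_in), "reason": c.reason,
        } for c in self.calls]).to_csv(paths["calls"], sep="\t", index=False)
        paths["heatmap"] = outdir / "region_heatmap.tsv"
        hm = heatmap_matrix(self.dataset_qc,
                            {r.region_id: list(r.probe_ids) for r in self.regions})
        hm.to_csv(paths["heatmap"], sep="\t", float_format="%.6f")
        paths["summary"] = outdir / "summary.json"
        paths["summary"].write_text(json.dumps(self.report, indent=1, sort_keys=True))
        return paths
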