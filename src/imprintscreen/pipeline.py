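"""Orchestration: read -> QC -> differential -> regions -> epigenotype ->
report, plus the known-DMR profiling run.

Both entry points are pure functions of (inputs, config): rerunning the
same config yields byte-identical JSON summaries.  The resolved config is
written next to the outputs of every run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as isio
from . import qc as isqc
from .datatypes import DataError, MethylationDataset
from .epigenotype import EpigenotypeThresholds, heatmap_matrix, profile_and_classify
from .model import ImprintingScreen, ScreenParams, ScreenResults

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths plus every screen parameter; serialisable to YAML."""

    manifest: str = ""
    beta: str = ""
    samplesheet: str = ""
    detection: Optional[str] = None
    known_dmrs: Optional[str] = None
    outdir: str = "screen_out"
    seed: int = 0
    params: ScreenParams = field(default_factory=ScreenParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        pd_ = d.pop("params", {}) or {}
        th = pd_.pop("epigenotype_thresholds", None)
        params = ScreenParams(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in pd_.items()})
        if th:
            params.epigenotype_thresholds = EpigenotypeThresholds(**th)
        return cls(params=params, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def write_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _load_model(config: PipelineConfig) -> ImprintingScreen:
    for name in ("manifest", "beta", "samplesheet"):
        if not getattr(config, name):
            raise DataError(f"pipeline config missing input path: {name}")
    return ImprintingScreen.from_files(
        config.manifest, config.beta, config.samplesheet,
        detection_path=config.detection,
        known_dmrs_path=config.known_dmrs,
        params=config.params,
    )


def run_screen(config: PipelineConfig) -> ScreenResults:
    """Run the full screen and write all stage outputs to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write_yaml(outdir / "config.yaml")
    try:
        model = _load_model(config)
    except Exception as exc:
        raise DataError(f"stage 'read': {exc}") from exc
    try:
        results = model.fit()
    except Exception as exc:
        raise DataError(f"stage 'fit': {exc}") from exc
    results.save(outdir)
    logger.info("screen finished: %d regions", len(results.regions))
    return results


def run_known_dmr_profile(config: PipelineConfig) -> pd.DataFrame:
    """Profile and classify every known DMR; write table + heatmap matrix.

    Unlike the genome-wide screen, known-DMR profiling keeps sex-chromosome
    probes: the reference list is trusted, only unreliable and missing
    signals are excluded.
    """
    if not config.known_dmrs:
        raise DataError("known-DMR profiling requires a known_dmrs path")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write_yaml(outdir / "config.yaml")
    model = _load_model(config)
    ds, _ = isqc.filter_detection(model.dataset,
                                  p_max=config.params.detection_p_max,
                                  max_fail_fraction=config.params.detection_max_fail_fraction)
    ds, _ = isqc.filter_missing(ds)
    dmr_map = isio.map_probes_to_known_dmrs(ds, model.known_dmrs)
    profiles, calls = profile_and_classify(
        ds, {k: v for k, v in dmr_map.items() if v},
        config.params.epigenotype_thresholds)
    call_by_id = {c.region_id: c for c in calls}
    prof_by_id = {p.region_id: p for p in profiles}
    rows = []
    for dmr in model.known_dmrs:
        probes = dmr_map[dmr.name]
        row = {
            "name": dmr.name, "chrom": dmr.chrom, "start": dmr.start,
            "end": dmr.end, "origin": dmr.origin, "category": dmr.category,
            "n_probes": len(probes), "label": None, "retained_in": "",
        }
        prof = prof_by_id.get(dmr.name)
        if prof is not None:
            for g, m in prof.group_means.items():
                row[f"mean_{g}"] = m
            call = call_by_id[dmr.name]
            row["label"] = call.label
            row["retained_in"] = ",".join(call.retained_in)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "known_dmr_profile.tsv", sep="\t", index=False,
                 float_format="%.6g")
    hm = heatmap_matrix(ds, {k: v for k, v in dmr_map.items() if v})
    hm.to_csv(outdir / "known_dmr_heatmap.tsv", sep="\t", float_format="%.6f")
    summary = {
        "schema_version": 1,
        "n_dmrs": len(model.known_dmrs),
        "probe_counts_by_category": {
            cat: int(sum(len(dmr_map[d.name]) for d in model.known_dmrs
                         if d.category == cat))
            for cat in sorted({d.category for d in model.known_dmrs})
        },
        "label_counts": {
            lab: int(sum(1 for c in calls if c.label == lab))
            for lab in sorted({c.label for c in calls})
        },
    }
    (outdir / "known_dmr_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))
    return table
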