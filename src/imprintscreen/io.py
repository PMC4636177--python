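"""Readers and writers for manifests, beta matrices, sample sheets and
known-DMR lists, plus probe-to-region mapping and BED export.

Coordinate conventions: manifests and known-DMR lists are 1-based inclusive;
BED output is 0-based half-open.  Beta/detection matrices are plain TSV with
the probe id in the first column; comment lines starting with ``!`` (GEO
series-matrix style) are skipped.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ANNOTATION_COLUMNS,
    DataError,
    KnownDMR,
    MethylationDataset,
    RegionCall,
    VALID_CATEGORIES,
    VALID_FEATURES,
    VALID_ORIGINS,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("probe_id", "chrom", "pos", "cgi", "feature")

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "t": True, "f": False, "yes": True, "no": False,
}


def _parse_bool(series: pd.Series) -> pd.Series:
    def conv(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s not in _BOOL_MAP:
            raise DataError(f"cannot parse boolean value {v!r}")
        return _BOOL_MAP[s]

    return series.map(conv)


def read_manifest(path) -> pd.DataFrame:
    """Read a probe manifest TSV (probe_id, chrom, pos, cgi, feature).

    Probes lacking a chromosome or position are dropped with a logged count:
    the screen is positional and cannot use them.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str}, comment="!")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"manifest {path}: missing columns {sorted(missing)}")
    n0 = len(df)
    df = df.dropna(subset=["chrom", "pos"])
    df = df[df["chrom"].astype(str).str.len() > 0]
    if len(df) < n0:
        logger.info("manifest: dropped %d probes lacking coordinates", n0 - len(df))
    df["pos"] = df["pos"].astype(np.int64)
    if (df["pos"] < 1).any():
        bad = df.loc[df["pos"] < 1, "probe_id"].iloc[0]
        raise DataError(f"manifest: non-positive position at probe {bad}")
    df["cgi"] = _parse_bool(df["cgi"])
    unknown = set(df["feature"]) - set(VALID_FEATURES)
    if unknown:
        raise DataError(f"manifest: unknown feature value(s) {sorted(unknown)}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise DataError(f"manifest: duplicate probe id {dup}")
    return df.set_index("probe_id")[list(ANNOTATION_COLUMNS)]


def read_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix with probe ids in the first column.

    Lines starting with ``!`` (GEO series-matrix metadata) are skipped.
    Empty cells become NaN.
    """
    df = pd.read_csv(path, sep="\t", comment="!", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "probe_id"
    return df.astype(float)


def read_samplesheet(path) -> pd.DataFrame:
    """Read a CSV sample sheet (sample_id, group)."""
    df = pd.read_csv(path, dtype=str)
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise DataError(f"sample sheet {path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise DataError(f"sample sheet {path}: duplicate sample id")
    return df.set_index("sample_id")[["group"]]


def read_known_dmrs(path) -> list[KnownDMR]:
    """Read a known-DMR TSV (name, chrom, start, end, origin, category)."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str})
    missing = {"name", "chrom", "start", "end", "origin", "category"} - set(df.columns)
    if missing:
        raise DataError(f"known-DMR list {path}: missing columns {sorted(missing)}")
    return [
        KnownDMR(
            name=r.name, chrom=r.chrom, start=int(r.start), end=int(r.end),
            origin=r.origin, category=r.category,
        )
        for r in df.itertuples(index=False)
    ]


def read_dataset(
    manifest_path,
    beta_path,
    samplesheet_path,
    detection_path=None,
) -> MethylationDataset:
    """Assemble a :class:`MethylationDataset` from its on-disk parts.

    Probes present in both the manifest and the beta matrix are retained in
    manifest order; probes absent from the matrix are dropped with a logged
    count.  Beta values outside [0, 1] are rejected (not clipped) naming the
    offending probe.
    """
    ann = read_manifest(manifest_path)
    beta = read_matrix(beta_path)
    samples = read_samplesheet(samplesheet_path)

    keep = ann.index.intersection(beta.index)
    n_dropped = len(ann) - len(keep)
    if n_dropped:
        logger.info("read_dataset: dropped %d manifest probes absent from matrix", n_dropped)
    ann = ann.loc[[p for p in ann.index if p in set(keep)]]
    beta = beta.loc[ann.index]

    extra = set(beta.columns) - set(samples.index)
    if extra:
        raise DataError(f"beta matrix samples not in sample sheet: {sorted(extra)}")

    detection = None
    if detection_path is not None:
        detection = read_matrix(detection_path)
        if set(detection.columns) != set(beta.columns):
            raise DataError("detection matrix samples differ from beta matrix")
        detection = detection.loc[ann.index, beta.columns]

    return MethylationDataset(annotation=ann, beta=beta, samples=samples,
                              detection_p=detection)


def write_dataset(dataset: MethylationDataset, outdir, precision: int = 6) -> dict[str, Path]:
    """Write a dataset back to TSV/CSV parts; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": outdir / "manifest.tsv",
        "beta": outdir / "beta.tsv",
        "samplesheet": outdir / "samples.csv",
    }
    ann = dataset.annotation.reset_index()
    ann.to_csv(paths["manifest"], sep="\t", index=False)
    dataset.beta.to_csv(paths["beta"], sep="\t", float_format=f"%.{precision}f")
    dataset.samples.reset_index().to_csv(paths["samplesheet"], index=False)
    if dataset.detection_p is not None:
        paths["detection"] = outdir / "detection_p.tsv"
        dataset.detection_p.to_csv(paths["detection"], sep="\t",
                                   float_format=f"%.{precision}g")
    return paths


def map_probes_to_known_dmrs(
    dataset: MethylationDataset, dmrs: Sequence[KnownDMR]
) -> dict[str, list[str]]:
    """Map each known DMR to the ordered probe ids it contains.

    A probe maps to a DMR iff ``start <= pos <= end`` (inclusive both ends);
    a probe may appear under several overlapping DMRs.  Every DMR gets an
    entry, possibly empty.
    """
    ann = dataset.annotation
    by_chrom: dict[str, pd.DataFrame] = {}
    for chrom, sub in ann.groupby("chrom", sort=False):
        by_chrom[chrom] = sub.sort_values("pos", kind="mergesort")
    out: dict[str, list[str]] = {}
    for dmr in dmrs:
        sub = by_chrom.get(dmr.chrom)
        if sub is None:
            out[dmr.name] = []
            continue
        pos = sub["pos"].to_numpy()
        lo = int(np.searchsorted(pos, dmr.start, side="left"))
        hi = int(np.searchsorted(pos, dmr.end, side="right"))
        out[dmr.name] = list(sub.index[lo:hi])
    return out


def write_regions_bed(regions: Iterable[RegionCall], path) -> None:
    """Write region calls as BED (0-based half-open).

    name = ``direction:n_probes``; score = round(1000 * |mean dbeta|), capped
    at 1000.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# candidate DMRs: chrom start end direction:n_probes score\n")
        for r in regions:
            score = min(1000, round(1000 * abs(r.mean_delta_beta)))
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t"
                f"{r.direction}:{r.n_probes}\t{score}\n"
            )


def regions_to_frame(regions: Sequence[RegionCall]) -> pd.DataFrame:
    """Tabulate region calls (one row per region) for TSV export."""
    rows = []
    for r in regions:
        rows.append({
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "n_probes": r.n_probes,
            "direction": r.direction,
            "mean_delta_beta": r.mean_delta_beta,
            "max_gap": r.max_gap,
            "cgi": r.cgi,
            "promoter": r.promoter,
            "known_dmr_overlap": ",".join(r.known_dmr_overlap),
            "label": r.label,
            "probe_ids": ",".join(r.probe_ids),
        })
    cols = ["chrom", "start", "end", "n_probes", "direction", "mean_delta_beta",
            "max_gap", "cgi", "promoter", "known_dmr_overlap", "label", "probe_ids"]
    return pd.DataFrame(rows, columns=cols)
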