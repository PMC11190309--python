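"""Tabular readers/writers: sample sheets, truth/call BED, count matrices.

All outputs are plain text (TSV, BED, JSON).  Files carry a comment header
recording the seed and configuration digest of the run that produced them,
so re-runs can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .detection import CnvCall
from .genome import GenomeModel
from .simulate import CnvTruth, SampleRecord


def file_digest(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _header(seed: int | None, config_digest: str | None) -> str:
    parts = ["# niptcnv"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_digest is not None:
        parts.append(f"config={config_digest}")
    return " ".join(parts) + "\n"


def _write_df(df: pd.DataFrame, path: Path | str, seed=None, config_digest=None,
              index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed, config_digest))
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def _read_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- genome -----------------------------------------------------------------

def write_genome_tables(genome: GenomeModel, chrom_path, bins_path,
                        seed=None, config_digest=None) -> None:
    chrom = pd.DataFrame({"chrom": genome.chrom_names,
                          "length": genome.chrom_lengths})
    _write_df(chrom, chrom_path, seed, config_digest)
    bins = pd.DataFrame({
        "chrom": [genome.chrom_names[c] for c in genome.bin_chrom],
        "start": genome.bin_start,
        "end": genome.bin_start + genome.bin_size,
        "gc": np.round(genome.gc, 5),
        "mappability": np.round(genome.mappability, 5),
    })
    _write_df(bins, bins_path, seed, config_digest)


# -- sample sheet -----------------------------------------------------------

def sample_sheet(cohort: Sequence[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": s.sample_id, "era": s.era,
        "fetal_fraction": round(s.fetal_fraction, 6),
        "total_reads": s.total_reads,
        "mean_read_length": round(s.mean_read_length, 2),
        "q20": round(s.q20, 4), "gc_fraction": round(s.gc_fraction, 4),
        "fetal_sex": s.fetal_sex,
        "n_truth_cnvs": len(s.truth),
    } for s in cohort])


def write_sample_sheet(cohort: Sequence[SampleRecord], path,
                       seed=None, config_digest=None,
                       extra: pd.DataFrame | None = None) -> None:
    df = sample_sheet(cohort)
    if extra is not None:
        df = df.merge(extra, on="sample_id", how="left")
    _write_df(df, path, seed, config_digest)


def read_sample_sheet(path) -> pd.DataFrame:
    return _read_tsv(path)


# -- truth and calls (BED) --------------------------------------------------

def write_truth_bed(cohort: Sequence[SampleRecord], path,
                    seed=None, config_digest=None) -> None:
    """Ground-truth CNVs as BED: name column is kind:origin, extra column
    carries the sample id."""
    rows = []
    for s in cohort:
        for t in s.truth:
            rows.append((t.chrom, t.start, t.end, f"{t.kind}:{t.origin}",
                         s.sample_id))
    with open(path, "w") as fh:
        fh.write(_header(seed, config_digest))
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def read_truth_bed(path) -> list[tuple[str, CnvTruth]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, sample = line.rstrip("\n").split("\t")
            kind, origin = name.split(":")
            out.append((sample, CnvTruth(chrom, int(start), int(end),
                                         kind, origin)))
    return out


def write_calls_bed(calls: Sequence[CnvCall], path,
                    seed=None, config_digest=None) -> None:
    """CNV calls as BED6+: score is |regional Z| capped at 1000; extra
    columns size_mb, n_bins, stratum, sample_id."""
    with open(path, "w") as fh:
        fh.write(_header(seed, config_digest))
        for c in calls:
            score = min(abs(c.stouffer_z), 1000.0)
            fh.write("\t".join(map(str, (
                c.chrom, c.start, c.end, c.kind, round(score, 2), ".",
                c.size_mb, c.n_bins, c.stratum, c.sample_id))) + "\n")


def read_calls_bed(path) -> list[CnvCall]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            (chrom, start, end, kind, score, _strand, size_mb, n_bins,
             stratum, sample) = line.rstrip("\n").split("\t")
            sign = 1.0 if kind == "duplication" else -1.0
            out.append(CnvCall(chrom, int(start), int(end), kind,
                               float(size_mb), sign * float(score),
                               sign * float(score), int(n_bins), stratum,
                               sample))
    return out


# -- count matrices ---------------------------------------------------------

def write_counts_matrix(cohort: Sequence[SampleRecord], genome: GenomeModel,
                        path, seed=None, config_digest=None) -> None:
    """Dense bin-by-sample count matrix as TSV (chrom/start index columns)."""
    data = {"chrom": [genome.chrom_names[c] for c in genome.bin_chrom],
            "start": genome.bin_start}
    for s in cohort:
        if s.counts is None:
            raise ValueError(f"sample {s.sample_id} has no counts")
        data[s.sample_id] = s.counts
    _write_df(pd.DataFrame(data), path, seed, config_digest)


def read_counts_matrix(path) -> tuple[pd.DataFrame, np.ndarray]:
    """Returns (bin index frame with chrom/start, counts matrix bins x samples)."""
    df = _read_tsv(path)
    idx = df[["chrom", "start"]]
    counts = df.drop(columns=["chrom", "start"])
    return idx, counts.to_numpy(dtype=np.int64)


# -- misc -------------------------------------------------------------------

def write_json(obj, path, seed=None, config_digest=None) -> None:
    payload = dict(obj)
    meta = {}
    if seed is not None:
        meta["seed"] = seed
    if config_digest is not None:
        meta["config"] = config_digest
    if meta:
        payload["_meta"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_z_profiles(chrom_z: pd.DataFrame, path, seed=None,
                     config_digest=None) -> None:
    """Per-sample chromosome-level Z scores, one row per sample."""
    _write_df(chrom_z, path, seed, config_digest)
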