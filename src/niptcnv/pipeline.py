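"""Pipeline orchestration: simulate -> enrich -> qc -> panel -> detect -> evaluate.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so any contiguous subset of stages can be re-run.  One global
seed fans out into per-stage, per-sample substreams; re-running with the
same configuration and seed reproduces every tabular output byte for byte.
A manifest recording input/output digests is written even when a stage
fails.

The simulate stage emits metadata and truth only; binned counts are
generated in the enrich stage, after post-improvement samples' fetal
fractions have been updated — the dosage signal in the counts depends on
the enriched fetal fraction.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .config import RunConfig
from .detection import build_panel, call_cnv, compute_chr_ratio, zscore, ReferencePanel
from .performance import pearson_chi2, positive_rate, ppv, stratify_calls
from .qc import evaluate_sample, failure_rate, run_retest_policy
from .simulate import (SampleRecord, expected_bin_intensity,
                       simulate_bin_counts, simulate_cohort, simulate_sample)
from .size_selection import enrich_fetal_fraction

STAGES = ("simulate", "enrich", "qc", "panel", "detect", "evaluate")

_STAGE_INPUTS: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "enrich": ("samples.tsv", "truth.bed"),
    "qc": ("samples_enriched.tsv", "counts.tsv", "truth.bed"),
    "panel": ("samples_qc.tsv", "counts_qc.tsv", "truth.bed"),
    "detect": ("panel.json", "samples_qc.tsv", "counts_qc.tsv"),
    "evaluate": ("calls.bed", "truth.bed", "samples_qc.tsv"),
}


class MissingInputError(FileNotFoundError):
    """A stage was requested but a required input file does not exist."""


@dataclass
class StageResult:
    name: str
    status: str
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    elapsed_s: float = 0.0
    error: str | None = None


@dataclass
class RunManifest:
    seed: int
    config_digest: str
    stages: list[StageResult] = field(default_factory=list)

    def to_json(self, path: Path) -> None:
        payload = {
            "seed": self.seed, "config": self.config_digest,
            "stages": [{
                "name": s.name, "status": s.status, "inputs": s.inputs,
                "outputs": s.outputs, "elapsed_s": round(s.elapsed_s, 3),
                "error": s.error,
            } for s in self.stages],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def _sample_rng(seed: int, stage: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage, index]))


def _load_cohort(outdir: Path, sheet_name: str, counts_name: str | None,
                 genome) -> list[SampleRecord]:
    sheet = nio.read_sample_sheet(outdir / sheet_name)
    truth_by_sample: dict[str, list] = {}
    for sample, t in nio.read_truth_bed(outdir / "truth.bed"):
        truth_by_sample.setdefault(sample, []).append(t)
    counts = None
    if counts_name is not None:
        _, counts = nio.read_counts_matrix(outdir / counts_name)
        ids = list(nio._read_tsv(outdir / counts_name).columns[2:])
        col = {sid: k for k, sid in enumerate(ids)}
    records = []
    for _, row in sheet.iterrows():
        c = counts[:, col[row.sample_id]] if counts is not None else None
        ff_col = "ff_post" if "ff_post" in sheet.columns else "fetal_fraction"
        records.append(SampleRecord(
            row.sample_id, row.era, float(row[ff_col]),
            int(c.sum()) if c is not None else int(row.total_reads),
            float(row.mean_read_length), float(row.q20),
            float(row.gc_fraction), c,
            tuple(truth_by_sample.get(row.sample_id, ())), row.fetal_sex))
    return records


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    genome = cfg.genome.build()
    spec = cfg.cohort.spec(cfg.seed)
    cohort = simulate_cohort(spec, genome, with_counts=False)
    dg = cfg.digest()
    nio.write_genome_tables(genome, outdir / "genome.tsv", outdir / "bins.tsv",
                            cfg.seed, dg)
    nio.write_sample_sheet(cohort, outdir / "samples.tsv", cfg.seed, dg)
    nio.write_truth_bed(cohort, outdir / "truth.bed", cfg.seed, dg)
    return [outdir / p for p in
            ("genome.tsv", "bins.tsv", "samples.tsv", "truth.bed")]


def _materialize_counts(rec: SampleRecord, genome, cfg: RunConfig,
                        rng: np.random.Generator) -> SampleRecord:
    intensity = expected_bin_intensity(genome, rec.truth, rec.fetal_fraction,
                                       rec.fetal_sex,
                                       cfg.cohort.gc_bias_amplitude)
    counts = simulate_bin_counts(intensity, rec.total_reads, rng)
    return replace(rec, counts=counts, total_reads=int(counts.sum()))


def _stage_enrich(cfg: RunConfig, outdir: Path) -> list[Path]:
    genome = cfg.genome.build()
    cohort = _load_cohort(outdir, "samples.tsv", None, genome)
    model = cfg.enrichment.model()
    dg = cfg.digest()
    enriched, rows = [], []
    for i, rec in enumerate(cohort):
        ff_pre = rec.fetal_fraction
        if rec.era == "post_improvement":
            res = enrich_fetal_fraction(ff_pre, model,
                                        cfg.enrichment.threshold_bp,
                                        cfg.enrichment.logistic_width)
            rec = replace(rec, fetal_fraction=res.output_ff)
        rows.append({"sample_id": rec.sample_id,
                     "ff_pre": round(ff_pre, 6),
                     "ff_post": round(rec.fetal_fraction, 6)})
        enriched.append(_materialize_counts(rec, genome, cfg,
                                            _sample_rng(cfg.seed, 1, i)))
    nio.write_sample_sheet(enriched, outdir / "samples_enriched.tsv", cfg.seed,
                           dg, extra=pd.DataFrame(rows))
    nio.write_counts_matrix(enriched, genome, outdir / "counts.tsv", cfg.seed, dg)
    return [outdir / "samples_enriched.tsv", outdir / "counts.tsv"]


def _stage_qc(cfg: RunConfig, outdir: Path) -> list[Path]:
    genome = cfg.genome.build()
    cohort = _load_cohort(outdir, "samples_enriched.tsv", "counts.tsv", genome)
    qc_cfg = cfg.qc.qc_config()
    spec = cfg.cohort.spec(cfg.seed)
    model = cfg.enrichment.model()
    dg = cfg.digest()

    attempts_log, accepted, verdicts = [], [], []
    for i, rec in enumerate(cohort):
        def redraw(prev: SampleRecord, attempt: int,
                   _i=i, _era=rec.era, _truth=rec.truth) -> SampleRecord:
            rng = _sample_rng(cfg.seed, 2 + attempt, _i)
            fresh = simulate_sample(spec, genome, prev.sample_id, _era, rng,
                                    with_counts=False, truth=_truth)
            if _era == "post_improvement":
                res = enrich_fetal_fraction(fresh.fetal_fraction, model,
                                            cfg.enrichment.threshold_bp,
                                            cfg.enrichment.logistic_width)
                fresh = replace(fresh, fetal_fraction=res.output_ff)
            return _materialize_counts(fresh, genome, cfg, rng)

        verdict, final = run_retest_policy(rec, qc_cfg, redraw)
        verdicts.append(verdict)
        for att in range(1, verdict.attempt + 1):
            attempts_log.append({"sample_id": rec.sample_id, "attempt": att,
                                 "final_status": verdict.status,
                                 "failed": ";".join(verdict.failed_criteria)
                                 if att == verdict.attempt else ""})
        if verdict.status == "accepted":
            accepted.append(final)

    pd_log = pd.DataFrame(attempts_log)
    nio._write_df(pd_log, outdir / "qc_report.tsv", cfg.seed, dg)
    nio.write_json({"failure_rate_pct": failure_rate(verdicts),
                    "n_total": len(cohort), "n_accepted": len(accepted)},
                   outdir / "qc_summary.json", cfg.seed, dg)
    nio.write_sample_sheet(accepted, outdir / "samples_qc.tsv", cfg.seed, dg)
    nio.write_counts_matrix(accepted, genome, outdir / "counts_qc.tsv",
                            cfg.seed, dg)
    return [outdir / p for p in ("qc_report.tsv", "qc_summary.json",
                                 "samples_qc.tsv", "counts_qc.tsv")]


def _stage_panel(cfg: RunConfig, outdir: Path) -> list[Path]:
    genome = cfg.genome.build()
    cohort = _load_cohort(outdir, "samples_qc.tsv", "counts_qc.tsv", genome)
    # simulation mode knows the truth; a clinical deployment would use a
    # verified euploid reference set here
    euploid = [s for s in cohort if not s.truth][:cfg.evaluation.panel_size]
    panel = build_panel(euploid, genome)
    panel.to_json(outdir / "panel.json")
    return [outdir / "panel.json"]


def _stage_detect(cfg: RunConfig, outdir: Path) -> list[Path]:
    genome = cfg.genome.build()
    cohort = _load_cohort(outdir, "samples_qc.tsv", "counts_qc.tsv", genome)
    panel = ReferencePanel.from_json(outdir / "panel.json")
    params = cfg.caller.params()
    dg = cfg.digest()
    calls, zrows = [], []
    for rec in cohort:
        profile = compute_chr_ratio(rec.counts, genome, rec.sample_id)
        zp = zscore(profile, panel, genome)
        calls.extend(call_cnv(zp, genome, params))
        zrows.append({"sample_id": rec.sample_id,
                      **{f"z_{k}": round(v, 4) for k, v in zp.chrom_z.items()}})
    nio.write_calls_bed(calls, outdir / "calls.bed", cfg.seed, dg)
    nio.write_z_profiles(pd.DataFrame(zrows), outdir / "chrom_z.tsv",
                         cfg.seed, dg)
    return [outdir / "calls.bed", outdir / "chrom_z.tsv"]


def _match_call(call, truths) -> bool:
    """A call is a true positive when it overlaps a same-type event that the
    fetus actually carries."""
    return any(t.chrom == call.chrom and t.kind == call.kind
               and t.fetal_affected
               and t.start < call.end and call.start < t.end
               for t in truths)


def _stage_evaluate(cfg: RunConfig, outdir: Path) -> list[Path]:
    sheet = nio.read_sample_sheet(outdir / "samples_qc.tsv")
    truth_by_sample: dict[str, list] = {}
    for sample, t in nio.read_truth_bed(outdir / "truth.bed"):
        truth_by_sample.setdefault(sample, []).append(t)
    calls = nio.read_calls_bed(outdir / "calls.bed")
    accepted_ids = set(sheet.sample_id)
    calls = [c for c in calls if c.sample_id in accepted_ids]
    dg = cfg.digest()

    rows = [{"size_mb": c.size_mb, "kind": c.kind, "stratum": c.stratum,
             "true_positive": _match_call(c, truth_by_sample.get(c.sample_id, ()))}
            for c in calls]
    strata = stratify_calls(rows) if rows else stratify_calls(
        pd.DataFrame(columns=["size_mb", "kind", "true_positive"]))
    nio._write_df(strata.reset_index(), outdir / "strata.tsv", cfg.seed, dg)

    perf: dict = {"n_accepted": len(sheet), "n_calls": len(calls)}
    tp = sum(r["true_positive"] for r in rows)
    if rows:
        perf["ppv_pct"] = ppv(tp=tp, fp=len(rows) - tp)
    lo, hi = cfg.evaluation.around_1mb_lo, cfg.evaluation.around_1mb_hi
    near = [r for r in rows if lo <= r["size_mb"] <= hi]
    if near:
        near_tp = sum(r["true_positive"] for r in near)
        perf["ppv_around_1mb_pct"] = ppv(tp=near_tp, fp=len(near) - near_tp)

    pos_ids = {c.sample_id for c in calls}
    perf["positive_rate_pct"] = positive_rate(len(pos_ids), len(sheet))
    era_counts = {}
    for era in ("pre_improvement", "post_improvement"):
        ids = set(sheet[sheet.era == era].sample_id)
        era_counts[era] = (len(ids & pos_ids), len(ids))
        if len(ids):
            perf[f"positive_rate_{era}_pct"] = positive_rate(
                len(ids & pos_ids), len(ids))
    try:
        (p1, n1), (p2, n2) = era_counts.values()
        stat, df_, pval = pearson_chi2([[p1, n1 - p1], [p2, n2 - p2]])
        perf["chi2_pr_era"] = {"statistic": stat, "df": df_, "p": pval}
    except ValueError:
        perf["chi2_pr_era"] = None

    # simulation mode: truth is known, so sensitivity/specificity exist
    fetal_events = [(sid, t) for sid, ts in truth_by_sample.items()
                    if sid in accepted_ids for t in ts if t.fetal_affected]
    if fetal_events:
        hit = sum(any(c.sample_id == sid and _match_call(c, [t])
                      for c in calls) for sid, t in fetal_events)
        perf["sensitivity_pct"] = round(100.0 * hit / len(fetal_events), 2)
    unaffected = [sid for sid in accepted_ids
                  if not any(t.fetal_affected
                             for t in truth_by_sample.get(sid, ()))]
    if unaffected:
        clean = sum(sid not in pos_ids for sid in unaffected)
        perf["specificity_pct"] = round(100.0 * clean / len(unaffected), 2)

    nio.write_json(perf, outdir / "performance.json", cfg.seed, dg)
    return [outdir / "strata.tsv", outdir / "performance.json"]


_STAGE_FN = {
    "simulate": _stage_simulate, "enrich": _stage_enrich, "qc": _stage_qc,
    "panel": _stage_panel, "detect": _stage_detect, "evaluate": _stage_evaluate,
}


def run_pipeline(cfg: RunConfig, outdir: Path | str,
                 stages: tuple[str, ...] | list[str] | None = None
                 ) -> RunManifest:
    """Run the requested stages in dependency order.

    Raises :class:`MissingInputError` if a requested stage's inputs are
    absent and the producing stage is not part of this run.  The manifest is
    written to ``<outdir>/manifest.json`` in all cases.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = [s for s in STAGES if s in (stages or STAGES)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest = RunManifest(cfg.seed, cfg.digest())
    try:
        for name in requested:
            res = StageResult(name, "running")
            manifest.stages.append(res)
            t0 = time.perf_counter()
            try:
                for req in _STAGE_INPUTS[name]:
                    path = outdir / req
                    if not path.exists():
                        raise MissingInputError(
                            f"stage {name!r} requires missing input {req!r}; "
                            f"run the producing stage first")
                    res.inputs[req] = nio.file_digest(path)
                outputs = _STAGE_FN[name](cfg, outdir)
                res.outputs = {p.name: nio.file_digest(p) for p in outputs}
                res.status = "ok"
            except Exception as exc:
                res.status = "failed"
                res.error = f"{type(exc).__name__}: {exc}"
                res.elapsed_s = time.perf_counter() - t0
                raise
            res.elapsed_s = time.perf_counter() - t0
    finally:
        manifest.to_json(outdir / "manifest.json")
    return manifest
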