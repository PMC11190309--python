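"""Calibration, recovery and power experiments for the screening statistic.

These are the package's standard validation experiments, each run at desk
scale on synthetic cohorts:

* leave-one-out null calibration of the per-chromosome Z,
* segment recovery of a 10 Mb fetal deletion with boundary accuracy,
* paired detection-power contrast for a ~1 Mb deletion at two fetal
  fractions,
* simulation-mode PPV as a function of the placental-discordance rate.

Depth conventions.  The clinical assay spreads its 3.5 M unique-read floor
over the full autosomal bin grid (~1.44e5 20 kb bins), i.e. ~24.3 reads per
bin; experiments probing *power* reproduce that per-bin depth on the desk
genome.  The boundary-recovery experiment instead keeps the full 3.5 M
reads on a compact 2 x 40 Mb genome: boundary localisation is information-
limited by the per-bin Z shift, and the concentrated depth provides the
shift at which +/-3-bin accuracy is statistically attainable.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .detection import (CallerParams, ReferencePanel, build_panel, call_cnv,
                        compute_chr_ratio, loo_zscores, zscore)
from .genome import (GenomeModel, HG19_CHROM_LENGTHS, RECOVERY_GENOME_LENGTHS,
                     SEX_CHROMOSOMES, build_genome, mini_genome)
from .simulate import (CnvTruth, CohortSpec, euploid_spec,
                       expected_bin_intensity, simulate_bin_counts,
                       simulate_cohort, simulate_sample)

#: clinical genome-wide depth: the 3.5 M unique-read floor over the
#: hg19-like autosomal 20 kb bin grid
_HG19_AUTO_BINS = sum(v // 20_000 for k, v in HG19_CHROM_LENGTHS.items()
                      if k not in SEX_CHROMOSOMES)
CLINICAL_BIN_DEPTH = 3.5e6 / _HG19_AUTO_BINS  # ~24.3 reads per 20 kb bin


def clinical_depth_reads(genome: GenomeModel, intensity: np.ndarray) -> int:
    """Total reads that put the mean autosomal bin count at clinical depth."""
    auto = genome.autosome_bin_mask
    return int(round(CLINICAL_BIN_DEPTH * intensity.sum()
                     / intensity[auto].mean()))


def _counts_at_depth(genome: GenomeModel, truth: Sequence[CnvTruth], ff: float,
                     sex: str, rng: np.random.Generator,
                     total_reads: int | None = None) -> np.ndarray:
    intensity = expected_bin_intensity(genome, truth, ff, sex)
    if total_reads is None:
        total_reads = clinical_depth_reads(genome, intensity)
    return simulate_bin_counts(intensity, total_reads, rng)


def build_euploid_panel(genome: GenomeModel, n: int, seed: int,
                        clinical_depth: bool = False,
                        total_reads: float = 3.5e6) -> ReferencePanel:
    """Reference panel from ``n`` euploid samples at the requested depth."""
    spec = euploid_spec(n, seed=seed, reads_mean=total_reads, reads_sd=0.0)
    if not clinical_depth:
        return build_panel(simulate_cohort(spec, genome), genome)
    samples = []
    for i, s in enumerate(simulate_cohort(spec, genome, with_counts=False)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 900, i]))
        counts = _counts_at_depth(genome, (), s.fetal_fraction, s.fetal_sex, rng)
        samples.append(replace(s, counts=counts, total_reads=int(counts.sum())))
    return build_panel(samples, genome)


# ---------------------------------------------------------------------------

def loo_null_calibration(n_samples: int = 2000, seed: int = 0,
                         genome: GenomeModel | None = None,
                         threshold: float = 3.0) -> tuple[int, int]:
    """Leave-one-out per-chromosome |Z| > threshold tally on euploid samples.

    Returns (exceedances, trials); under a calibrated statistic the rate is
    the two-sided normal tail, ~0.27% at threshold 3.
    """
    genome = genome if genome is not None else mini_genome()
    cohort = simulate_cohort(euploid_spec(n_samples, seed=seed), genome)
    pct = np.array([[compute_chr_ratio(s.counts, genome).chrom_pct[c]
                     for c in genome.autosome_names] for s in cohort])
    z = loo_zscores(pct)
    return int((np.abs(z) > threshold).sum()), int(z.size)


def recovery_experiment(n_reps: int = 100, seed: int = 0, ff: float = 0.18,
                        total_reads: int = 3_500_000, panel_size: int = 100,
                        tol_bins: int = 3,
                        params: CallerParams = CallerParams(),
                        ) -> tuple[int, int]:
    """Recover a 10 Mb fetal deletion with type and boundary accuracy.

    Returns (replicates called with correct type and both boundaries within
    ``tol_bins`` bins, total replicates).
    """
    genome = build_genome(RECOVERY_GENOME_LENGTHS, seed=0)
    panel = build_euploid_panel(genome, panel_size, seed=seed + 1,
                                total_reads=total_reads)
    truth = CnvTruth("1", 10_000_000, 20_000_000, "deletion", "fetal")
    tol = tol_bins * genome.bin_size
    hits = 0
    for ss in np.random.SeedSequence([seed, 41]).spawn(n_reps):
        rng = np.random.default_rng(ss)
        counts = _counts_at_depth(genome, [truth], ff, "female", rng,
                                  total_reads)
        zp = zscore(compute_chr_ratio(counts, genome), panel, genome)
        calls = [c for c in call_cnv(zp, genome, params)
                 if c.chrom == truth.chrom and c.kind == truth.kind]
        hits += any(abs(c.start - truth.start) <= tol
                    and abs(c.end - truth.end) <= tol for c in calls)
    return hits, n_reps


def power_contrast(n_reps: int = 500, seed: int = 0,
                   ffs: tuple[float, float] = (0.18, 0.10),
                   size_mb: float = 1.0, panel_size: int = 100,
                   genome: GenomeModel | None = None,
                   panel: ReferencePanel | None = None,
                   params: CallerParams = CallerParams(),
                   ) -> dict[float, int]:
    """Paired detection power for a small fetal deletion at two fetal
    fractions, at clinical per-bin depth.

    Each replicate draws both conditions from sibling RNG streams; detection
    means a deletion call overlapping the simulated event.  Returns
    detections per fetal fraction.
    """
    genome = genome if genome is not None else mini_genome()
    if panel is None:
        panel = build_euploid_panel(genome, panel_size, seed=seed + 2,
                                    clinical_depth=True)
    start = 20_000_000
    truth = CnvTruth("2", start, start + int(size_mb * 1e6), "deletion", "fetal")
    det = {ff: 0 for ff in ffs}
    for ss in np.random.SeedSequence([seed, 43]).spawn(n_reps):
        for ff, css in zip(ffs, ss.spawn(len(ffs))):
            rng = np.random.default_rng(css)
            counts = _counts_at_depth(genome, [truth], ff, "female", rng)
            zp = zscore(compute_chr_ratio(counts, genome), panel, genome)
            calls = [c for c in call_cnv(zp, genome, params,
                                         chromosomes=[truth.chrom])
                     if c.kind == "deletion" and c.start < truth.end
                     and truth.start < c.end]
            det[ff] += bool(calls)
    return det


def _is_true_positive(call, truth: Sequence[CnvTruth]) -> bool:
    return any(t.chrom == call.chrom and t.kind == call.kind
               and t.fetal_affected and t.start < call.end
               and call.start < t.end for t in truth)


def ppv_vs_discordance(grid: Sequence[float] = (0.0, 0.4, 0.8),
                       n_per_point: int = 200, seed: int = 0,
                       panel_size: int = 100,
                       genome: GenomeModel | None = None,
                       panel: ReferencePanel | None = None,
                       params: CallerParams = CallerParams(),
                       ) -> dict[float, dict]:
    """Simulation-mode PPV across a grid of placental-discordance rates.

    Every sample carries one CNV; placental-only (and maternal-origin)
    events produce plasma signal without an affected fetus, so their calls
    are false positives and PPV falls as the discordance rate rises.
    """
    genome = genome if genome is not None else mini_genome()
    if panel is None:
        panel = build_euploid_panel(genome, panel_size, seed=seed + 3,
                                    clinical_depth=True)
    out: dict[float, dict] = {}
    for d in grid:
        spec = CohortSpec(n_samples=n_per_point, seed=seed,
                          cnv_prevalence=1.0, placental_discordance=d,
                          maternal_origin=0.025, reads_mean=3.5e6,
                          reads_sd=0.0)
        tp = fp = 0
        root = np.random.SeedSequence([seed, 47, int(round(d * 100))])
        for i, ss in enumerate(root.spawn(n_per_point)):
            rng = np.random.default_rng(ss)
            s = simulate_sample(spec, genome, f"P{i:04d}", "post_improvement",
                                rng, with_counts=False)
            counts = _counts_at_depth(genome, s.truth, s.fetal_fraction,
                                      s.fetal_sex, rng)
            zp = zscore(compute_chr_ratio(counts, genome), panel, genome)
            for c in call_cnv(zp, genome, params):
                if _is_true_positive(c, s.truth):
                    tp += 1
                else:
                    fp += 1
        out[d] = {"tp": tp, "fp": fp,
                  "ppv_pct": round(100.0 * tp / (tp + fp), 2)
                  if tp + fp else float("nan")}
    return out


def false_call_rate(n_samples: int = 200, seed: int = 0,
                    panel_size: int = 100,
                    params: CallerParams = CallerParams()) -> tuple[int, int]:
    """Family-wise false-call tally: euploid samples with >= 1 CNV call."""
    genome = mini_genome()
    panel = build_euploid_panel(genome, panel_size, seed=seed + 4)
    cohort = simulate_cohort(euploid_spec(n_samples, seed=seed + 5), genome)
    fw = sum(bool(call_cnv(zscore(compute_chr_ratio(s.counts, genome,
                                                    s.sample_id),
                                  panel, genome), genome, params))
             for s in cohort)
    return fw, n_samples
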