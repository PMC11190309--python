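"""Synthetic maternal-plasma cfDNA cohorts with known CNV truth.

Generates the statistical structure the screening analysis assumes: each
pregnancy contributes a fetal fraction drawn from an era-specific
distribution, QC metadata, an optional ground-truth CNV of fetal, maternal
or placental-only origin, and genome-wide binned unique-read counts whose
expected depth encodes the copy-number dosage signal.

Dosage model (diploid baseline, cfDNA is a two-genome mixture):
a CNV changing the affected genome by ``d = copy_state - 2`` copies scales
the regional read intensity by ``1 + (d/2) * ff`` when the fetal (placental)
genome carries it and ``1 + (d/2) * (1 - ff)`` when the maternal genome
does.  A heterozygous fetal deletion at ff = 0.20 therefore drops regional
coverage by 10%.  ``placental_only`` events behave like fetal events in the
plasma signal but leave the fetus unaffected — the biological source of
screening false positives (confined placental mosaicism).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .genome import GenomeModel, SEX_CHROMOSOMES

CnvKind = Literal["deletion", "duplication"]
CnvOrigin = Literal["fetal", "maternal", "placental_only"]
Era = Literal["pre_improvement", "post_improvement"]

#: CNV size strata (Mb ranges) and their default sampling weights, taken
#: from the composition of 161 diagnosed screen positives (34 near 1 Mb,
#: then 50 / 40 / 17 / 20 across 0-5 / 5-10 / 10-20 / >=20 Mb).
DEFAULT_SIZE_STRATA: dict[str, tuple[float, float]] = {
    "~1": (0.5, 1.5),
    "0-5": (1.5, 5.0),
    "5-10": (5.0, 10.0),
    "10-20": (10.0, 20.0),
    ">=20": (20.0, 40.0),
}
DEFAULT_SIZE_WEIGHTS: dict[str, float] = {
    "~1": 34 / 161, "0-5": 50 / 161, "5-10": 40 / 161,
    "10-20": 17 / 161, ">=20": 20 / 161,
}


@dataclass(frozen=True)
class CnvTruth:
    """A ground-truth copy-number event (0-based, half-open bp coordinates)."""

    chrom: str
    start: int
    end: int
    kind: CnvKind
    origin: CnvOrigin = "fetal"
    copy_state: int = 0  # copies carried by the affected genome; 0 -> default het

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"CNV end must exceed start: {self.start}-{self.end}")
        if self.kind not in ("deletion", "duplication"):
            raise ValueError(f"unknown CNV kind {self.kind!r}")
        if self.origin not in ("fetal", "maternal", "placental_only"):
            raise ValueError(f"unknown CNV origin {self.origin!r}")
        if self.copy_state == 0:  # default: heterozygous 1 (del) or 3 (dup)
            object.__setattr__(self, "copy_state",
                               1 if self.kind == "deletion" else 3)
        if self.kind == "deletion" and self.copy_state >= 2:
            raise ValueError("deletion requires copy_state < 2")
        if self.kind == "duplication" and self.copy_state <= 2:
            raise ValueError("duplication requires copy_state > 2")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def size_mb(self) -> float:
        return self.size / 1e6

    @property
    def fetal_affected(self) -> bool:
        """True when the fetus itself carries the event (screening TP)."""
        return self.origin == "fetal"


@dataclass(frozen=True)
class SampleRecord:
    """One pregnancy: QC metadata, fetal fraction, truth and binned counts."""

    sample_id: str
    era: Era
    fetal_fraction: float
    total_reads: int
    mean_read_length: float
    q20: float
    gc_fraction: float
    counts: np.ndarray | None
    truth: tuple[CnvTruth, ...] = ()
    fetal_sex: Literal["male", "female"] = "female"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fetal_fraction <= 1.0:
            raise ValueError("fetal_fraction must lie in [0, 1]")
        if self.counts is not None:
            if np.any(self.counts < 0):
                raise ValueError("bin counts must be non-negative")
            if int(self.counts.sum()) != self.total_reads:
                raise ValueError("counts must sum to the recorded total reads")

    @property
    def is_euploid(self) -> bool:
        return not any(t.fetal_affected for t in self.truth)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated screening cohort.

    Era-level fetal-fraction parameters reproduce the cohort means observed
    before (13.76% +/- 5.68%) and after (18.44% +/- 5.80%) the
    size-selection library improvement.  ``ff_mode`` selects whether each
    era's ff is drawn directly from its own distribution ("per_era") or all
    samples get pre-era ("raw") draws for later explicit enrichment.
    """

    n_samples: int = 200
    seed: int = 0
    era_pre_fraction: float = 12_885 / 68_588
    ff_params: dict = field(default_factory=lambda: {
        "pre_improvement": (0.1376, 0.0568),
        "post_improvement": (0.1844, 0.0580),
    })
    ff_mode: Literal["per_era", "raw"] = "per_era"
    cnv_prevalence: float = 0.005
    size_weights: dict = field(default_factory=lambda: dict(DEFAULT_SIZE_WEIGHTS))
    size_strata: dict = field(default_factory=lambda: dict(DEFAULT_SIZE_STRATA))
    deletion_fraction: float = 193 / 281
    placental_discordance: float = 0.40
    maternal_origin: float = 0.025
    reads_mean: float = 3.9e6
    reads_sd: float = 2.5e5
    reads_min: float = 3.5e6
    read_length_mean: float = 135.0
    read_length_sd: float = 8.0
    q20_mean: float = 0.92
    q20_sd: float = 0.02
    gc_mean: float = 0.415
    gc_sd: float = 0.012
    male_fraction: float = 0.5
    gc_bias_amplitude: float = 0.05
    nb_dispersion: float | None = None  # optional negative-binomial overdispersion

    def __post_init__(self) -> None:
        for name in ("era_pre_fraction", "cnv_prevalence", "deletion_fraction",
                     "placental_discordance", "maternal_origin", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.placental_discordance + self.maternal_origin > 1.0:
            raise ValueError("origin probabilities exceed 1")
        w = sum(self.size_weights.values())
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError(f"size-stratum weights must sum to 1, got {w}")
        if set(self.size_weights) - set(self.size_strata):
            raise ValueError("size_weights refer to unknown strata")


# ---------------------------------------------------------------------------
# intensity model

def gc_bias_factor(gc: np.ndarray, amplitude: float = 0.05,
                   center: float = 0.415, span: float = 0.045) -> np.ndarray:
    """Multiplicative smooth GC bias: +/- ``amplitude`` across the GC range."""
    return 1.0 + amplitude * np.clip((np.asarray(gc) - center) / span, -1.0, 1.0)


def expected_bin_intensity(genome: GenomeModel,
                           truth: Sequence[CnvTruth],
                           fetal_fraction: float,
                           fetal_sex: str = "female",
                           gc_bias_amplitude: float = 0.05,
                           y_background: float = 0.0) -> np.ndarray:
    """Per-bin expected relative coverage for one sample.

    Baseline is mappability x GC bias.  Sex chromosomes scale with the
    mixture: X carries (1-ff) maternal diploid mass plus ff fetal mass at
    copy 2 (female fetus) or 1 (male); Y carries ff/2 for a male fetus plus
    an optional mismapping background.  CNV segments multiply the dosage
    factor described in the module docstring, prorated on partially
    overlapped bins; overlapping segments multiply.
    """
    ff = float(fetal_fraction)
    if not 0.0 <= ff <= 1.0:
        raise ValueError("fetal_fraction must lie in [0, 1]")
    intensity = genome.mappability * gc_bias_factor(genome.gc, gc_bias_amplitude)
    intensity = intensity.astype(float).copy()

    for ci, name in enumerate(genome.chrom_names):
        if name not in SEX_CHROMOSOMES:
            continue
        sl = genome.chrom_slice(name)
        if name.lstrip("chr") == "X":
            fetal_x = 1.0 if fetal_sex == "female" else 0.5
            intensity[sl] *= (1.0 - ff) + ff * fetal_x
        else:  # Y
            male_y = ff / 2.0 if fetal_sex == "male" else 0.0
            intensity[sl] = intensity[sl] * male_y + y_background

    for seg in truth:
        dose = (seg.copy_state - 2) / 2.0
        mix = ff if seg.origin in ("fetal", "placental_only") else 1.0 - ff
        sl, frac = genome.overlap_fractions(seg.chrom, seg.start, seg.end)
        intensity[sl] *= 1.0 + dose * mix * frac
    return intensity


def simulate_bin_counts(intensity: np.ndarray, total_reads: int,
                        rng: np.random.Generator | int,
                        nb_dispersion: float | None = None) -> np.ndarray:
    """Draw per-bin counts: independent Poisson with mean proportional to
    ``intensity``, normalised so the expected total equals ``total_reads``.

    With ``nb_dispersion`` alpha > 0, counts are negative-binomial with
    variance ``mu + alpha * mu**2`` instead (overdispersion switch).
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    intensity = np.asarray(intensity, dtype=float)
    total = intensity.sum()
    if not np.all(intensity >= 0):
        raise ValueError("intensity must be non-negative")
    if total <= 0:
        raise ValueError("intensity must not be identically zero")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    lam = intensity / total * float(total_reads)
    if nb_dispersion:
        alpha = float(nb_dispersion)
        n_param = 1.0 / alpha
        with np.errstate(divide="ignore", invalid="ignore"):
            p_param = n_param / (n_param + lam)
        out = np.zeros(lam.size, dtype=np.int64)
        pos = lam > 0
        out[pos] = rng.negative_binomial(n_param, p_param[pos])
        return out
    return rng.poisson(lam).astype(np.int64)


# ---------------------------------------------------------------------------
# cohort generation

def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_cnv(spec: CohortSpec, genome: GenomeModel,
              rng: np.random.Generator) -> CnvTruth:
    strata = sorted(spec.size_weights)
    weights = np.array([spec.size_weights[s] for s in strata])
    stratum = strata[rng.choice(len(strata), p=weights / weights.sum())]
    lo, hi = spec.size_strata[stratum]
    size = int(round(np.exp(rng.uniform(np.log(lo * 1e6), np.log(hi * 1e6)))))

    kind: CnvKind = "deletion" if rng.random() < spec.deletion_fraction else "duplication"
    u = rng.random()
    if u < spec.placental_discordance:
        origin: CnvOrigin = "placental_only"
    elif u < spec.placental_discordance + spec.maternal_origin:
        origin = "maternal"
    else:
        origin = "fetal"

    pad = genome.bin_size  # keep one bin clear of each chromosome end
    feasible = [n for n in genome.autosome_names
                if genome.n_bins_of(n) * genome.bin_size - 2 * pad > size]
    if not feasible:
        longest = max(genome.autosome_names, key=genome.n_bins_of)
        feasible = [longest]
        size = genome.n_bins_of(longest) * genome.bin_size - 2 * pad - genome.bin_size
    lens = np.array([genome.n_bins_of(n) * genome.bin_size for n in feasible], float)
    chrom = feasible[rng.choice(len(feasible), p=lens / lens.sum())]
    max_start = genome.n_bins_of(chrom) * genome.bin_size - pad - size
    start = int(rng.integers(pad, max_start + 1))
    return CnvTruth(chrom, start, start + size, kind, origin)


def simulate_sample(spec: CohortSpec, genome: GenomeModel,
                    sample_id: str, era: Era,
                    rng: np.random.Generator,
                    with_counts: bool = True,
                    fetal_fraction: float | None = None,
                    truth: tuple[CnvTruth, ...] | None = None) -> SampleRecord:
    """Draw one pregnancy under the spec's study conditions."""
    ff_era = "pre_improvement" if spec.ff_mode == "raw" else era
    if fetal_fraction is None:
        m, s = spec.ff_params[ff_era]
        fetal_fraction = _truncnorm(rng, m, s, 0.0, 1.0)
    if truth is None:
        truth = ((_draw_cnv(spec, genome, rng),)
                 if rng.random() < spec.cnv_prevalence else ())
    sex = "male" if rng.random() < spec.male_fraction else "female"
    target_reads = int(_truncnorm(rng, spec.reads_mean, spec.reads_sd,
                                  spec.reads_min, np.inf))
    read_len = _truncnorm(rng, spec.read_length_mean, spec.read_length_sd, 50.0, 400.0)
    q20 = _truncnorm(rng, spec.q20_mean, spec.q20_sd, 0.0, 1.0)
    gc = _truncnorm(rng, spec.gc_mean, spec.gc_sd, 0.0, 1.0)

    counts = None
    total = target_reads
    if with_counts:
        intensity = expected_bin_intensity(
            genome, truth, fetal_fraction, sex, spec.gc_bias_amplitude)
        counts = simulate_bin_counts(intensity, target_reads, rng,
                                     spec.nb_dispersion)
        total = int(counts.sum())
    return SampleRecord(sample_id, era, fetal_fraction, total, read_len,
                        q20, gc, counts, truth, sex)


def simulate_cohort(spec: CohortSpec, genome: GenomeModel,
                    with_counts: bool = True) -> list[SampleRecord]:
    """Simulate a full cohort; bit-identical under identical spec + seed.

    Per-sample RNG substreams are spawned from ``spec.seed`` so cohorts are
    reproducible independently of iteration details.
    """
    root = np.random.SeedSequence(spec.seed)
    records: list[SampleRecord] = []
    for i, ss in enumerate(root.spawn(spec.n_samples)):
        rng = np.random.default_rng(ss)
        era: Era = ("pre_improvement" if rng.random() < spec.era_pre_fraction
                    else "post_improvement")
        records.append(simulate_sample(spec, genome, f"S{i:05d}", era, rng,
                                       with_counts=with_counts))
    return records


def euploid_spec(n_samples: int, seed: int, **overrides) -> CohortSpec:
    """A CohortSpec with CNV prevalence zero (reference-panel conditions)."""
    return replace(CohortSpec(n_samples=n_samples, seed=seed, cnv_prevalence=0.0),
                   **overrides)
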