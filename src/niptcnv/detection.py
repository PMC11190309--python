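"""Reference-panel Z-score statistic and CNV segment calling.

The screening statistic is a read-ratio Z-score.  For each sample,

    %chrN = unique reads on chromosome N / unique reads on all autosomes x 100

and Z = (%chrN - panel mean) / panel SD against a euploid reference panel.
A chromosome with |Z| > 3 (strictly) is marked as a whole-chromosome
aneuploidy.  Subchromosomal deletions/duplications are called from the
analogous per-bin ratios: bin ratios are GC-corrected against a panel-fitted
curve, standardised per bin, and scanned for the contiguous segment
maximising the combined (Stouffer) Z, ``sum(z)/sqrt(n)``.  Segments whose
combined |Z| clears a null-calibrated threshold are reported, boundaries are
refined by a change-point likelihood step, and the scan recurses on the
flanks so multiple events per chromosome can be recovered.

The regional threshold default (5.0) is deliberately higher than the
per-chromosome cut of 3: the scan maximises over every contiguous segment of
every autosome, and the null distribution of that maximum (simulated on the
desk-scale genome) has its 95th percentile near 4.7.  Threshold 5 keeps the
family-wise false-call rate per euploid sample at the percent level.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import GenomeModel, SEX_CHROMOSOMES
from .simulate import SampleRecord

Z_THRESHOLD_CHROM = 3.0

#: Size strata (Mb) used in the screening-performance tables.
SIZE_STRATA_MB: tuple[tuple[str, float, float], ...] = (
    ("0-5", 0.0, 5.0),
    ("5-10", 5.0, 10.0),
    ("10-20", 10.0, 20.0),
    (">=20", 20.0, math.inf),
)


def size_stratum(size_mb: float) -> str:
    if size_mb < 0:
        raise ValueError("CNV size must be non-negative")
    for label, lo, hi in SIZE_STRATA_MB:
        if lo <= size_mb < hi:
            return label
    return SIZE_STRATA_MB[-1][0]


# ---------------------------------------------------------------------------
# ratio profiles

@dataclass(frozen=True)
class RatioProfile:
    """Per-chromosome %chrN (percent) and per-bin read ratios for one sample."""

    sample_id: str
    chrom_pct: dict[str, float]
    bin_ratio: np.ndarray  # percent of autosomal reads per bin


def compute_chr_ratio(counts: np.ndarray, genome: GenomeModel,
                      sample_id: str = "sample") -> RatioProfile:
    """Exact read-ratio statistic: every chromosome (X and Y included) is
    expressed as a percentage of the *autosomal* unique-read total."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    auto_total = counts[genome.autosome_bin_mask].sum()
    if auto_total <= 0:
        raise ValueError("autosomal read total is zero; cannot form ratios")
    chrom_pct = {
        name: float(counts[genome.chrom_slice(name)].sum()) / auto_total * 100.0
        for name in genome.chrom_names
    }
    return RatioProfile(sample_id, chrom_pct, counts / auto_total * 100.0)


# ---------------------------------------------------------------------------
# GC correction

@dataclass(frozen=True)
class GcCurve:
    """Panel-fitted expected-ratio-vs-GC curve, normalised to median 1."""

    gc_grid: np.ndarray
    factor: np.ndarray
    gc_min: float
    gc_max: float

    def predict(self, gc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Correction factor at each GC; second output flags bins outside the
        fitted GC range (nearest-endpoint extrapolation is used there)."""
        gc = np.asarray(gc, dtype=float)
        out_of_range = (gc < self.gc_min) | (gc > self.gc_max)
        return np.interp(gc, self.gc_grid, self.factor), out_of_range


def fit_gc_curve(mean_ratio: np.ndarray, gc: np.ndarray,
                 frac: float = 0.3) -> GcCurve:
    """Fit the smooth expected bin ratio as a function of GC (LOWESS)."""
    gc = np.asarray(gc, float)
    mean_ratio = np.asarray(mean_ratio, float)
    fitted = lowess(mean_ratio, gc, frac=frac, return_sorted=True)
    grid, vals = fitted[:, 0], fitted[:, 1]
    grid, uniq = np.unique(grid, return_index=True)
    vals = vals[uniq]
    med = np.median(np.interp(gc, grid, vals))
    factor = vals / med if med > 0 else np.ones_like(vals)
    return GcCurve(grid, factor, float(grid[0]), float(grid[-1]))


def gc_correct(bin_ratio: np.ndarray, gc: np.ndarray,
               curve: GcCurve) -> tuple[np.ndarray, np.ndarray]:
    """Divide each bin ratio by the curve's relative factor at its GC.

    Returns the corrected ratios and a boolean flag array marking bins whose
    GC fell outside the fitted range.  Degenerate single-bin input is
    returned unchanged with a warning.
    """
    bin_ratio = np.asarray(bin_ratio, dtype=float)
    if bin_ratio.size <= 1:
        warnings.warn("single-bin input: GC correction skipped", stacklevel=2)
        return bin_ratio.copy(), np.zeros(bin_ratio.size, dtype=bool)
    factor, flagged = curve.predict(gc)
    return bin_ratio / factor, flagged


# ---------------------------------------------------------------------------
# reference panel

@dataclass(frozen=True)
class ReferencePanel:
    """Euploid-panel means and SDs for the chromosome and bin statistics."""

    chrom_names: tuple[str, ...]
    chrom_mean: np.ndarray
    chrom_sd: np.ndarray
    bin_mean: np.ndarray       # GC-corrected bin ratio means (NaN off-autosome)
    bin_sd: np.ndarray
    gc_curve: GcCurve
    n_samples: int
    bin_size: int

    def chrom_stats(self, name: str) -> tuple[float, float]:
        try:
            i = self.chrom_names.index(name)
        except ValueError:
            raise KeyError(f"chromosome {name!r} not in panel") from None
        return float(self.chrom_mean[i]), float(self.chrom_sd[i])

    def to_json(self, path) -> None:
        payload = {
            "n_samples": self.n_samples,
            "bin_size": self.bin_size,
            "chrom_names": list(self.chrom_names),
            "chrom_mean": self.chrom_mean.tolist(),
            "chrom_sd": self.chrom_sd.tolist(),
            "bin_mean": self.bin_mean.tolist(),
            "bin_sd": self.bin_sd.tolist(),
            "gc_curve": {
                "gc_grid": self.gc_curve.gc_grid.tolist(),
                "factor": self.gc_curve.factor.tolist(),
                "gc_min": self.gc_curve.gc_min,
                "gc_max": self.gc_curve.gc_max,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ReferencePanel":
        with open(path) as fh:
            d = json.load(fh)
        curve = GcCurve(np.asarray(d["gc_curve"]["gc_grid"]),
                        np.asarray(d["gc_curve"]["factor"]),
                        d["gc_curve"]["gc_min"], d["gc_curve"]["gc_max"])
        return cls(tuple(d["chrom_names"]), np.asarray(d["chrom_mean"]),
                   np.asarray(d["chrom_sd"]), np.asarray(d["bin_mean"]),
                   np.asarray(d["bin_sd"]), curve, d["n_samples"], d["bin_size"])


def build_panel(samples: Sequence[SampleRecord], genome: GenomeModel,
                sd_floor_frac: float | None = 0.1,
                lowess_frac: float = 0.3) -> ReferencePanel:
    """Build per-chromosome and per-bin reference statistics from euploid samples.

    SDs are floored at ``sd_floor_frac`` times the Poisson-expected SD of the
    corresponding ratio (computed at the panel's median autosomal depth) so a
    finite panel can never hand the Z-statistic a near-zero denominator.
    Pass ``sd_floor_frac=None`` to disable the floor, in which case any unit
    with zero variance raises.
    """
    if len(samples) < 2:
        raise ValueError("a reference panel needs at least 2 samples")
    profiles = [compute_chr_ratio(s.counts, genome, s.sample_id) for s in samples]

    auto = genome.autosome_bin_mask
    ratios = np.vstack([p.bin_ratio for p in profiles])
    mean_raw = ratios[:, auto].mean(axis=0)
    curve = fit_gc_curve(mean_raw, genome.gc[auto], frac=lowess_frac)
    corrected = np.stack([gc_correct(r[auto], genome.gc[auto], curve)[0]
                          for r in ratios])

    bin_mean = np.full(genome.n_bins, np.nan)
    bin_sd = np.full(genome.n_bins, np.nan)
    bin_mean[auto] = corrected.mean(axis=0)
    bin_sd[auto] = corrected.std(axis=0, ddof=1)

    chrom_pct = np.array([[p.chrom_pct[n] for n in genome.chrom_names]
                          for p in profiles])
    chrom_mean = chrom_pct.mean(axis=0)
    chrom_sd = chrom_pct.std(axis=0, ddof=1)

    median_total = float(np.median([s.counts[auto].sum() for s in samples]))
    # Poisson SD of a ratio r = 100 c / T is sqrt(100 r / T)
    pois_bin = np.sqrt(100.0 * np.clip(bin_mean[auto], 0.0, None) / median_total)
    pois_chrom = np.sqrt(100.0 * np.clip(chrom_mean, 0.0, None) / median_total)
    if sd_floor_frac is not None:
        bin_sd[auto] = np.maximum(bin_sd[auto], sd_floor_frac * pois_bin)
        chrom_sd = np.maximum(chrom_sd, sd_floor_frac * pois_chrom)
    elif np.any(bin_sd[auto] == 0) or np.any(chrom_sd == 0):
        raise ValueError("zero-variance unit in panel and SD floor disabled")

    return ReferencePanel(genome.chrom_names, chrom_mean, chrom_sd,
                          bin_mean, bin_sd, curve, len(samples),
                          genome.bin_size)


# ---------------------------------------------------------------------------
# Z profiles

@dataclass(frozen=True)
class ZProfile:
    sample_id: str
    chrom_z: dict[str, float]
    bin_z: np.ndarray  # NaN outside the panel's tested (autosomal) bins
    threshold: float = Z_THRESHOLD_CHROM


def zscore(profile: RatioProfile, panel: ReferencePanel,
           genome: GenomeModel, center_bins: bool = True) -> ZProfile:
    """Standardise a sample's ratios against the panel (exact Z equation).

    Ratios are compositional: a real CNV shifts the autosomal denominator
    and drags every other bin's ratio slightly off the panel mean, which a
    genome-wide segment scan would pick up as a spurious diffuse event.
    ``center_bins`` (default) therefore recentres the per-bin Z profile by
    its autosomal median — robust to the CNV itself, which occupies a small
    minority of bins.  Chromosome-level Z is never recentred.
    """
    chrom_z = {}
    for name in genome.chrom_names:
        if name not in profile.chrom_pct:
            raise KeyError(f"profile lacks chromosome {name!r}")
        m, s = panel.chrom_stats(name)  # raises if the panel lacks the unit
        chrom_z[name] = (profile.chrom_pct[name] - m) / s
    auto = genome.autosome_bin_mask
    corrected, _ = gc_correct(profile.bin_ratio[auto], genome.gc[auto],
                              panel.gc_curve)
    bin_z = np.full(genome.n_bins, np.nan)
    bin_z[auto] = (corrected - panel.bin_mean[auto]) / panel.bin_sd[auto]
    if center_bins:
        bin_z[auto] -= np.median(bin_z[auto])
    return ZProfile(profile.sample_id, chrom_z, bin_z)


def loo_zscores(values: np.ndarray) -> np.ndarray:
    """Leave-one-out Z of each row of ``values`` against the remaining rows.

    ``values`` has one row per sample and one column per tested unit (e.g.
    %chrN).  Used to calibrate the null of the chromosome statistic without
    building n separate panels.
    """
    x = np.asarray(values, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out Z")
    mean = x.mean(axis=0)
    ssd = ((x - mean) ** 2).sum(axis=0)
    mean_loo = (n * mean - x) / (n - 1)
    ssd_loo = ssd - (x - mean) ** 2 * n / (n - 1)
    sd_loo = np.sqrt(np.clip(ssd_loo, 0.0, None) / (n - 2))
    return (x - mean_loo) / sd_loo


# ---------------------------------------------------------------------------
# chromosome-level calls

def call_aneuploidy(zp: ZProfile, threshold: float = Z_THRESHOLD_CHROM,
                    autosomes_only: bool = True) -> list[tuple[str, str]]:
    """Chromosomes with |Z| strictly greater than the threshold.

    Returns (chromosome, "gain"|"loss") pairs; Z exactly at the threshold is
    negative.  Sex chromosomes are excluded by default (their ratios shift
    with fetal sex and fraction, not only with aneuploidy).
    """
    flags = []
    for name, z in zp.chrom_z.items():
        if autosomes_only and name in SEX_CHROMOSOMES:
            continue
        if abs(z) > threshold:
            flags.append((name, "gain" if z > 0 else "loss"))
    return flags


# ---------------------------------------------------------------------------
# segment calling

@dataclass(frozen=True)
class CallerParams:
    """Tunables of the segment scan.

    ``min_bins`` (25 bins = 0.5 Mb at 20 kb) is the smallest reportable
    event; ``z_region`` is the combined-Z threshold calibrated on the null
    scan maximum; ``refine_window`` bounds the change-point boundary
    refinement; ``max_bins`` optionally caps the scanned segment length.
    """

    min_bins: int = 25
    z_region: float = 5.0
    max_bins: int | None = None
    refine: bool = True
    refine_window: int = 50

    def __post_init__(self) -> None:
        if self.min_bins < 1 or self.z_region <= 0:
            raise ValueError("invalid caller parameters")


@dataclass(frozen=True)
class CnvCall:
    """A called deletion/duplication segment with its Z evidence."""

    chrom: str
    start: int
    end: int
    kind: str
    size_mb: float
    mean_z: float
    stouffer_z: float
    n_bins: int
    stratum: str
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if (self.kind == "duplication") != (self.mean_z > 0):
            raise ValueError("call type must match the sign of the regional Z")
        if self.stratum != size_stratum(self.size_mb):
            raise ValueError("stratum inconsistent with size")


def _best_segment(prefix: np.ndarray, lo: int, hi: int, min_bins: int,
                  max_bins: int | None) -> tuple[float, int, int] | None:
    """Max-|Stouffer| contiguous segment of z[lo:hi] via prefix sums.

    Ties resolve to the shortest segment, then the smallest start (strict
    improvement required), making the search order-deterministic.
    """
    n = hi - lo
    if n < min_bins:
        return None
    top = n if max_bins is None else min(n, max_bins)
    best_v, best_i, best_j = -1.0, -1, -1
    for length in range(min_bins, top + 1):
        s = prefix[lo + length:hi + 1] - prefix[lo:hi - length + 1]
        stat = np.abs(s) / math.sqrt(length)
        i = int(np.argmax(stat))
        if stat[i] > best_v:
            best_v = float(stat[i])
            best_i, best_j = lo + i, lo + i + length
    return best_v, best_i, best_j


def _refine_boundaries(z: np.ndarray, prefix: np.ndarray, i: int, j: int,
                       lo: int, hi: int, window: int) -> tuple[int, int]:
    """Change-point likelihood refinement of one segment's edges.

    With estimated segment mean m, the log-likelihood gain of placing the
    left edge at k is sign(m)*sum(z[k:j]) - |m|/2*(j-k); ditto on the right.
    Search is confined to ``window`` bins around each scan edge and to the
    enclosing (lo, hi) interval so refined calls cannot collide.
    """
    m = float((prefix[j] - prefix[i]) / (j - i))
    s, a = math.copysign(1.0, m), abs(m)
    ks = np.arange(max(lo, i - window), min(j - 1, i + window) + 1)
    score = s * (prefix[j] - prefix[ks]) - a / 2.0 * (j - ks)
    i2 = int(ks[np.argmax(score)])
    ks = np.arange(max(i2 + 1, j - window), min(hi, j + window) + 1)
    score = s * (prefix[ks] - prefix[i2]) - a / 2.0 * (ks - i2)
    j2 = int(ks[np.argmax(score)])
    return i2, j2


def scan_segments(z: np.ndarray, params: CallerParams = CallerParams()
                  ) -> list[tuple[int, int, float, float]]:
    """Recursive max-|Stouffer| segmentation of one chromosome's bin Z.

    Returns (start_bin, end_bin, mean_z, stouffer_z) tuples, sorted by
    position.  The best segment is extracted when its combined |Z| clears
    ``params.z_region``; the scan then recurses on both flanks.  Detection
    is decided by the scan alone: boundary refinement afterwards only moves
    the reported edges (and the regional statistics are recomputed on the
    refined extent), it never revokes a detection.
    """
    z = np.asarray(z, dtype=float)
    prefix = np.concatenate([[0.0], np.cumsum(z)])
    raw: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        found = _best_segment(prefix, lo, hi, params.min_bins, params.max_bins)
        if found is None:
            return
        v, i, j = found
        if v <= params.z_region:
            return
        raw.append((i, j))
        recurse(lo, i)
        recurse(j, hi)

    recurse(0, z.size)
    raw.sort()

    calls = []
    for idx, (i, j) in enumerate(raw):
        if params.refine:
            lo = raw[idx - 1][1] if idx > 0 else 0
            hi = raw[idx + 1][0] if idx + 1 < len(raw) else z.size
            i2, j2 = _refine_boundaries(z, prefix, i, j, lo, hi,
                                        params.refine_window)
            if j2 - i2 >= params.min_bins:  # refinement may not undersize a call
                i, j = i2, j2
        n = j - i
        seg_sum = float(prefix[j] - prefix[i])
        calls.append((i, j, seg_sum / n, seg_sum / math.sqrt(n)))
    return calls


def call_cnv(zp: ZProfile, genome: GenomeModel,
             params: CallerParams = CallerParams(),
             chromosomes: Iterable[str] | None = None) -> list[CnvCall]:
    """Call deletion/duplication segments from a sample's per-bin Z profile.

    Ratios are compositional: a genuine CNV shifts the autosomal read total,
    displacing every unaffected bin's Z by a small common offset that a
    genome-wide segment scan would amplify into chromosome-spanning spurious
    calls of the opposite sign.  The caller therefore runs two passes: a
    provisional scan marks candidate segments, the baseline offset is
    re-estimated as the mean Z of the bins *outside* those candidates, and
    the recentred profile is scanned again for the reported calls.

    A segment's type follows the sign of its regional Z, and its size and
    stratum are reported from the called bin extent (0-based, half-open bp).
    """
    chroms = list(chromosomes) if chromosomes is not None else list(genome.autosome_names)
    zmap: dict[str, np.ndarray] = {}
    for name in chroms:
        z = zp.bin_z[genome.chrom_slice(name)]
        if not np.all(np.isnan(z)):
            zmap[name] = np.nan_to_num(z)

    # pass 1: provisional segments, no refinement, to mask CNV bins
    pass1 = CallerParams(params.min_bins, params.z_region, params.max_bins,
                         refine=False)
    baseline_parts = []
    for name, z in zmap.items():
        mask = np.zeros(z.size, dtype=bool)
        for i, j, _, _ in scan_segments(z, pass1):
            mask[i:j] = True
        baseline_parts.append(z[~mask])
    unmasked = np.concatenate(baseline_parts) if baseline_parts else np.empty(0)
    offset = float(unmasked.mean()) if unmasked.size else 0.0

    calls: list[CnvCall] = []
    for name, z in zmap.items():
        sl = genome.chrom_slice(name)
        for i, j, mean_z, stouffer in scan_segments(z - offset, params):
            start = int(genome.bin_start[sl.start + i])
            end = int(genome.bin_start[sl.start + j - 1]) + genome.bin_size
            size_mb = round((end - start) / 1e6, 2)
            kind = "duplication" if mean_z > 0 else "deletion"
            calls.append(CnvCall(name, start, end, kind, size_mb,
                                 mean_z, stouffer, j - i,
                                 size_stratum(size_mb), zp.sample_id))
    return calls


# ---------------------------------------------------------------------------
# fetal fraction estimation

def estimate_fetal_fraction(counts: np.ndarray, genome: GenomeModel,
                            fetal_sex: str,
                            truth_ff: float | None = None,
                            y_female_baseline: float = 0.0,
                            ) -> tuple[float, str]:
    """Chromosome-Y fetal-fraction estimate for male pregnancies.

    The fetal male genome carries Y at one copy against the diploid autosome
    baseline, so %chrY of the sample is ff/2 times the %chrY a fully diploid
    Y would produce; inverting gives
    ``ff = 2 (%chrY - baseline) / (%chrY_diploid - baseline)``, clipped to
    [0, 1].  For female fetuses the method does not apply: the simulator's
    recorded truth is passed through with a ``"not_estimated"`` flag.
    """
    if fetal_sex == "female":
        return (truth_ff if truth_ff is not None else float("nan"),
                "not_estimated")
    y_name = next((n for n in genome.chrom_names if n.lstrip("chr") == "Y"), None)
    if y_name is None:
        raise ValueError("genome has no Y chromosome; cannot estimate ff")
    profile = compute_chr_ratio(counts, genome)
    auto = genome.autosome_bin_mask
    y_sl = genome.chrom_slice(y_name)
    # %chrY expected if Y were at autosome-like diploid intensity
    y_diploid_pct = (genome.mappability[y_sl].sum()
                     / genome.mappability[auto].sum() * 100.0)
    est = 2.0 * (profile.chrom_pct[y_name] - y_female_baseline) \
        / (y_diploid_pct - y_female_baseline)
    flag = "ok"
    if est < 0.0:
        est, flag = 0.0, "clipped"
    elif est > 1.0:
        est, flag = 1.0, "clipped"
    return float(est), flag
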