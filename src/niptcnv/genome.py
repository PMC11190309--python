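"""Genome bin grids for shallow-sequencing read-count analysis.

The screening statistic operates on unique-read counts tallied in fixed
non-overlapping genomic bins (20 kb by default).  A :class:`GenomeModel`
freezes the bin tiling together with a per-bin GC fraction and a
mappability weight, so that every downstream stage — simulation, panel
construction, Z-scoring, CNV calling — shares one coordinate system.

Coordinates are 0-based, half-open.  Bins tile each chromosome from its
start; a trailing remainder shorter than one bin is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})

#: hg19 chromosome lengths (bp), autosomes 1..22 plus X and Y.
HG19_CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}

#: Desk-scale default genome: four 60 Mb autosomes plus small sex chromosomes.
MINI_GENOME_LENGTHS: dict[str, int] = {
    "1": 60_000_000, "2": 60_000_000, "3": 60_000_000, "4": 60_000_000,
    "X": 40_000_000, "Y": 20_000_000,
}

#: Compact two-autosome genome used for segment-recovery experiments, where
#: the read mass of a whole sample is concentrated on 4,000 bins.
RECOVERY_GENOME_LENGTHS: dict[str, int] = {
    "1": 40_000_000, "2": 40_000_000,
}

DEFAULT_BIN_SIZE = 20_000


@dataclass(frozen=True)
class GenomeModel:
    """A binned genome: chromosome table, bin tiling, GC and mappability.

    Attributes
    ----------
    chrom_names : tuple of str
        Chromosome names in genome order.
    chrom_lengths : tuple of int
        Chromosome lengths in bp, same order as ``chrom_names``.
    bin_size : int
        Bin width in bp (> 0).
    bin_chrom : ndarray of int
        For each bin, the index of its chromosome in ``chrom_names``.
    bin_start : ndarray of int
        0-based start coordinate (bp) of each bin on its chromosome.
    gc : ndarray of float
        Per-bin GC fraction in [0, 1], frozen at construction.
    mappability : ndarray of float
        Per-bin mappability weight (>= 0), default 1 everywhere.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int
    bin_chrom: np.ndarray
    bin_start: np.ndarray
    gc: np.ndarray
    mappability: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("per-bin GC fractions must lie in [0, 1]")
        if np.any(self.mappability < 0):
            raise ValueError("mappability weights must be non-negative")

    # -- bin bookkeeping ---------------------------------------------------

    @property
    def n_bins(self) -> int:
        return int(self.bin_chrom.size)

    @property
    def autosome_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.chrom_names if n not in SEX_CHROMOSOMES)

    @property
    def autosome_bin_mask(self) -> np.ndarray:
        """Boolean mask over bins selecting autosomal bins."""
        auto_idx = {i for i, n in enumerate(self.chrom_names)
                    if n not in SEX_CHROMOSOMES}
        return np.isin(self.bin_chrom, sorted(auto_idx))

    def chrom_index(self, name: str) -> int:
        try:
            return self.chrom_names.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def chrom_slice(self, name: str) -> slice:
        """Contiguous bin slice for one chromosome."""
        ci = self.chrom_index(name)
        idx = np.flatnonzero(self.bin_chrom == ci)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def n_bins_of(self, name: str) -> int:
        return int(self.chrom_lengths[self.chrom_index(name)] // self.bin_size)

    def overlap_fractions(self, chrom: str, start: int, end: int) -> tuple[slice, np.ndarray]:
        """Bins overlapping [start, end) on ``chrom`` and their overlap fractions.

        Returns the genome-wide bin slice touched by the interval and, for
        each bin in that slice, the fraction of the bin covered (in (0, 1]).
        """
        ci = self.chrom_index(chrom)
        clen = self.chrom_lengths[ci]
        if not (0 <= start < end <= clen):
            raise ValueError(
                f"segment {chrom}:{start}-{end} falls off the chromosome "
                f"(length {clen})")
        sl = self.chrom_slice(chrom)
        first = sl.start + start // self.bin_size
        last = sl.start + min((end - 1) // self.bin_size, self.n_bins_of(chrom) - 1)
        if first > last:  # interval entirely inside the dropped remainder
            return slice(first, first), np.empty(0)
        starts = self.bin_start[first:last + 1]
        lo = np.maximum(starts, start)
        hi = np.minimum(starts + self.bin_size, end)
        return slice(first, last + 1), (hi - lo) / self.bin_size


def _smooth_gc_field(n: int, bin_size: int, gc_mean: float, gc_sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth GC track: a few random long-wavelength sinusoids over the chromosome."""
    if n == 0:
        return np.empty(0)
    x = (np.arange(n) + 0.5) * bin_size
    field = np.zeros(n)
    k = 6
    wavelengths = np.exp(rng.uniform(np.log(2e6), np.log(3e7), size=k))
    phases = rng.uniform(0, 2 * np.pi, size=k)
    amps = rng.uniform(0.5, 1.0, size=k)
    for lam, ph, a in zip(wavelengths, phases, amps):
        field += a * np.sin(2 * np.pi * x / lam + ph)
    sd = field.std()
    if sd > 0:
        field *= gc_sd / sd
    return np.clip(gc_mean + field, 0.30, 0.60)


def build_genome(chrom_lengths: Mapping[str, int],
                 bin_size: int = DEFAULT_BIN_SIZE,
                 gc_mean: float = 0.415,
                 gc_sd: float = 0.015,
                 mappability_sd: float = 0.0,
                 seed: int = 0) -> GenomeModel:
    """Construct a deterministic binned genome.

    The GC track is drawn once from a smooth random field under ``seed`` and
    then frozen in the returned model; two calls with identical arguments
    yield bit-identical genomes.

    Parameters
    ----------
    chrom_lengths : mapping name -> length (bp)
        Every chromosome must be at least one bin long.
    bin_size : int
        Bin width in bp; 20 kb by default.
    gc_mean, gc_sd : float
        Centre and spread of the smooth GC field.
    mappability_sd : float
        If > 0, per-bin mappability is 1 + N(0, sd) clipped at 0.2.
    seed : int
        Seed freezing the GC/mappability fields.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    names = tuple(chrom_lengths)
    lengths = tuple(int(chrom_lengths[n]) for n in names)
    for n, ln in zip(names, lengths):
        if ln <= 0:
            raise ValueError(f"chromosome {n!r} has non-positive length {ln}")
        if ln < bin_size:
            raise ValueError(
                f"chromosome {n!r} (length {ln}) is shorter than one bin "
                f"({bin_size})")

    rng = np.random.default_rng(seed)
    bin_chrom, bin_start, gc_parts = [], [], []
    for ci, (n, ln) in enumerate(zip(names, lengths)):
        nb = ln // bin_size
        bin_chrom.append(np.full(nb, ci, dtype=np.int32))
        bin_start.append(np.arange(nb, dtype=np.int64) * bin_size)
        gc_parts.append(_smooth_gc_field(nb, bin_size, gc_mean, gc_sd, rng))
    bin_chrom = np.concatenate(bin_chrom)
    bin_start = np.concatenate(bin_start)
    gc = np.concatenate(gc_parts)
    if mappability_sd > 0:
        mapp = np.clip(1.0 + rng.normal(0.0, mappability_sd, gc.size), 0.2, None)
    else:
        mapp = np.ones(gc.size)
    return GenomeModel(names, lengths, int(bin_size), bin_chrom, bin_start, gc, mapp)


def mini_genome(seed: int = 0, **kwargs) -> GenomeModel:
    """The 4 x 60 Mb desk-scale genome (plus 40 Mb X and 20 Mb Y)."""
    return build_genome(MINI_GENOME_LENGTHS, seed=seed, **kwargs)


def hg19_genome(seed: int = 0, include_sex: bool = True, **kwargs) -> GenomeModel:
    """Full 22-autosome genome at hg19-like lengths (~1.44e5 autosomal bins)."""
    lengths = dict(HG19_CHROM_LENGTHS)
    if not include_sex:
        lengths.pop("X")
        lengths.pop("Y")
    return build_genome(lengths, seed=seed, **kwargs)
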