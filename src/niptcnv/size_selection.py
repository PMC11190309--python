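"""Fragment-size selection and its effect on fetal fraction.

Retaining only cfDNA fragments below a length threshold (230 bp by default)
preferentially keeps the shorter fetal fragments.  If a fraction ``P_f`` of
fetal and ``P_m`` of maternal fragment mass survives the cut, the fetal
fraction updates as

    ff' = ff * P_f / (ff * P_f + (1 - ff) * P_m),

the exact mixture-proportion update.  Selection acts on composition only:
library re-amplification is assumed to restore sequencing mass, so total
read counts are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import integrate

from .fragments import DEFAULT_FRAGMENT_MODEL, FragmentLengthModel
from .simulate import SampleRecord

DEFAULT_THRESHOLD_BP = 230.0


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one size-selection enrichment step."""

    input_ff: float
    threshold_bp: float
    fetal_retention: float
    maternal_retention: float
    output_ff: float

    def __post_init__(self) -> None:
        for name in ("fetal_retention", "maternal_retention", "input_ff", "output_ff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def retention_probability(model: FragmentLengthModel, population: str,
                          threshold_bp: float, logistic_width: float = 0.0) -> float:
    """Probability that a fragment of the given population survives the cut.

    A sharp cut (``logistic_width == 0``) retains fragments with length
    strictly below the threshold, i.e. the truncated-mixture CDF.  A positive
    width models soft bead selection: retention probability
    ``sigmoid((threshold - length) / width)``, integrated against the length
    density.  Monotone nondecreasing in the threshold either way.
    """
    if threshold_bp <= 0:
        raise ValueError("threshold must be positive")
    mix = model.population(population)  # raises on unknown label
    if logistic_width <= 0.0:
        if threshold_bp <= mix.lower:
            return 0.0
        if threshold_bp >= mix.upper:
            return 1.0
        return float(mix.cdf(threshold_bp))
    value, _ = integrate.quad(
        lambda L: mix.pdf(L) / (1.0 + np.exp(-(threshold_bp - L) / logistic_width)),
        mix.lower, mix.upper, limit=200)
    return float(min(max(value, 0.0), 1.0))


def enrich_fetal_fraction(ff: float,
                          model: FragmentLengthModel = DEFAULT_FRAGMENT_MODEL,
                          threshold_bp: float = DEFAULT_THRESHOLD_BP,
                          logistic_width: float = 0.0) -> EnrichmentResult:
    """Apply the mixture-proportion update to one sample's fetal fraction."""
    if not 0.0 <= ff <= 1.0:
        raise ValueError("fetal fraction must lie in [0, 1]")
    p_f = retention_probability(model, "fetal", threshold_bp, logistic_width)
    p_m = retention_probability(model, "maternal", threshold_bp, logistic_width)
    num = ff * p_f
    den = num + (1.0 - ff) * p_m
    out = ff if den == 0.0 else num / den  # nothing retained: composition unchanged
    return EnrichmentResult(ff, float(threshold_bp), p_f, p_m, out)


def apply_enrichment_to_cohort(cohort: Sequence[SampleRecord],
                               model: FragmentLengthModel = DEFAULT_FRAGMENT_MODEL,
                               threshold_bp: float = DEFAULT_THRESHOLD_BP,
                               logistic_width: float = 0.0) -> list[SampleRecord]:
    """Enrich every post-improvement sample's fetal fraction.

    Pre-improvement samples pass through unchanged.  Enriched samples have
    stale counts cleared (``counts=None``): the dosage signal depends on ff,
    so counts must be regenerated after enrichment.
    """
    out: list[SampleRecord] = []
    for rec in cohort:
        if rec.era != "post_improvement":
            out.append(rec)
            continue
        res = enrich_fetal_fraction(rec.fetal_fraction, model, threshold_bp,
                                    logistic_width)
        out.append(replace(rec, fetal_fraction=res.output_ff, counts=None))
    return out
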