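"""Sample-acceptance filters, the re-test policy and the cohort failure rate.

Acceptance requires all five criteria: mean read length strictly > 100 bp,
Q20 strictly > 50%, sample GC inside the inclusive 38-45% window, fetal
fraction >= 4%, and >= 3.5 million unique reads.  A failing sample may be
re-drawn (fresh specimen) up to a configured number of attempts before it
is failed out of the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

from .simulate import SampleRecord


@dataclass(frozen=True)
class QcConfig:
    min_read_length: float = 100.0   # strict >
    min_q20: float = 0.50            # strict >
    gc_window: tuple[float, float] = (0.38, 0.45)  # inclusive
    min_fetal_fraction: float = 0.04  # >=
    min_unique_reads: float = 3.5e6   # >=
    max_attempts: int = 3             # initial test + up to 2 re-tests

    def __post_init__(self) -> None:
        if min(self.min_read_length, self.min_q20, self.min_fetal_fraction,
               self.min_unique_reads) < 0 or self.max_attempts < 1:
            raise ValueError("QC thresholds must be positive")
        if not self.gc_window[0] < self.gc_window[1]:
            raise ValueError("GC window must be a nonempty interval")


@dataclass(frozen=True)
class QcVerdict:
    sample_id: str
    passed: bool
    failed_criteria: tuple[str, ...]
    attempt: int = 1
    status: Literal["accepted", "failed_out"] = "accepted"

    def __post_init__(self) -> None:
        if self.passed and self.failed_criteria:
            raise ValueError("a passing verdict cannot list failed criteria")


_FIELDS = (
    ("mean_read_length", "read_length"),
    ("q20", "q20"),
    ("gc_fraction", "gc_window"),
    ("fetal_fraction", "fetal_fraction"),
    ("total_reads", "unique_reads"),
)


def evaluate_sample(sample: SampleRecord, cfg: QcConfig = QcConfig(),
                    attempt: int = 1) -> QcVerdict:
    """Evaluate the five acceptance criteria for one sample.

    Boundary semantics follow the filter definitions verbatim: read length
    and Q20 are strict inequalities, the GC window is inclusive at both
    ends, and fetal fraction / unique reads are >= thresholds.
    """
    for attr, name in _FIELDS:
        v = getattr(sample, attr)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"sample {sample.sample_id}: missing QC metadata "
                             f"field {attr!r}")
    failed = []
    if not sample.mean_read_length > cfg.min_read_length:
        failed.append("read_length")
    if not sample.q20 > cfg.min_q20:
        failed.append("q20")
    if not cfg.gc_window[0] <= sample.gc_fraction <= cfg.gc_window[1]:
        failed.append("gc_window")
    if not sample.fetal_fraction >= cfg.min_fetal_fraction:
        failed.append("fetal_fraction")
    if not sample.total_reads >= cfg.min_unique_reads:
        failed.append("unique_reads")
    return QcVerdict(sample.sample_id, not failed, tuple(failed), attempt)


def run_retest_policy(sample: SampleRecord, cfg: QcConfig,
                      redraw: Callable[[SampleRecord, int], SampleRecord],
                      ) -> tuple[QcVerdict, SampleRecord]:
    """Re-test a failing sample with fresh draws up to ``cfg.max_attempts``.

    ``redraw(sample, attempt)`` simulates a new specimen for the same
    pregnancy (it must be deterministic under its own seeding).  Returns the
    final verdict and the sample version it refers to.
    """
    current = sample
    for attempt in range(1, cfg.max_attempts + 1):
        verdict = evaluate_sample(current, cfg, attempt)
        if verdict.passed:
            return verdict, current
        if attempt < cfg.max_attempts:
            current = redraw(current, attempt + 1)
    from dataclasses import replace as _replace
    return _replace(verdict, status="failed_out"), current


def failure_rate(verdicts: Sequence[QcVerdict]) -> float:
    """Failed-out share of the cohort, as a percentage rounded to 3 decimals."""
    if not verdicts:
        raise ValueError("cannot compute a failure rate on an empty cohort")
    failed = sum(1 for v in verdicts if v.status == "failed_out")
    return round(100.0 * failed / len(verdicts), 3)
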