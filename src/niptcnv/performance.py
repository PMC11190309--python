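"""Screening-performance arithmetic: PPV, positive rate, stratified tables,
era contrasts and pregnancy-outcome bookkeeping.

Only quantities computable without knowing the true negatives are reported
for real-mode data (PPV, positive rate, diagnosis rate); sensitivity and
specificity are available in simulation mode, where ground truth exists.
Percentages are rounded to 2 decimals and chi-square statistics to 2
decimals, matching the precision of the clinical tables this module is
validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detection import SIZE_STRATA_MB, size_stratum

STRATUM_ORDER = [label for label, _, _ in SIZE_STRATA_MB]


@dataclass(frozen=True)
class ScreeningTable:
    """TP/FP bookkeeping for one stratum (size bin, CNV type, or era)."""

    tp: int
    fp: int
    label: str = "total"
    screened: int | None = None
    positives: int | None = None

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0:
            raise ValueError("counts must be non-negative")
        if (self.screened is not None and self.positives is not None
                and self.positives > self.screened):
            raise ValueError("positives cannot exceed screened")

    @property
    def diagnosed(self) -> int:
        return self.tp + self.fp


def ppv(table: ScreeningTable | None = None, *, tp: int | None = None,
        fp: int | None = None) -> float:
    """Positive predictive value, 100*TP/(TP+FP), rounded to 2 decimals."""
    if table is not None:
        tp, fp = table.tp, table.fp
    if tp is None or fp is None or tp < 0 or fp < 0:
        raise ValueError("ppv needs non-negative TP and FP counts")
    if tp + fp == 0:
        raise ValueError("PPV undefined: no diagnosed positives (TP+FP=0)")
    return round(100.0 * tp / (tp + fp), 2)


def positive_rate(positives: int, screened: int) -> float:
    """Screen-positive rate, 100*positives/screened, rounded to 2 decimals."""
    if screened <= 0:
        raise ValueError("screened total must be positive")
    if positives < 0 or positives > screened:
        raise ValueError("positives must lie in [0, screened]")
    return round(100.0 * positives / screened, 2)


def stratify_calls(records: Sequence[Mapping] | pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate diagnosed calls by size stratum and CNV type.

    ``records`` carries one row per diagnosed call with fields ``size_mb``
    (or ``stratum``), ``kind`` ("deletion"/"duplication") and
    ``true_positive`` (bool).  Returns a table with TP/FP/PPV per stratum x
    type plus margins; empty strata appear with zero counts and PPV NaN.
    """
    df = pd.DataFrame(records)
    if len(df) and "stratum" not in df:
        if (df["size_mb"] < 0).any():
            raise ValueError("negative CNV size")
        df["stratum"] = df["size_mb"].map(size_stratum)
    rows = []
    kinds = ("deletion", "duplication")
    for stratum in STRATUM_ORDER + ["total"]:
        sub = df if stratum == "total" else (
            df[df["stratum"] == stratum] if len(df) else df)
        row: dict = {"stratum": stratum}
        for kind in kinds + ("total",):
            part = sub if kind == "total" else (
                sub[sub["kind"] == kind] if len(sub) else sub)
            tp = int(part["true_positive"].sum()) if len(part) else 0
            fp = int((~part["true_positive"]).sum()) if len(part) else 0
            row[f"{kind}_tp"] = tp
            row[f"{kind}_fp"] = fp
            row[f"{kind}_ppv"] = ppv(tp=tp, fp=fp) if tp + fp else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


def pearson_chi2(table: np.ndarray | Sequence[Sequence[int]]
                 ) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Returns (statistic rounded to 2 decimals, df, p-value).  Rejects tables
    with a zero marginal, where the expected counts are degenerate.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal: chi-square undefined")
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return round(float(stat), 2), int(dof), float(p)


def summarize_cohort(values: Mapping[str, Sequence] | pd.DataFrame) -> dict:
    """Mean +/- SD (denominator n-1) for continuous columns, percentage
    tables (2 decimals) for categorical ones."""
    df = pd.DataFrame(values)
    if df.empty:
        raise ValueError("cannot summarise an empty cohort")
    out: dict = {}
    for col in df.columns:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            out[col] = {"mean": float(s.mean()),
                        "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
                        "n": int(s.notna().sum())}
        else:
            pct = (s.value_counts(normalize=True) * 100).round(2)
            out[col] = {k: float(v) for k, v in pct.items()}
    return out


# ---------------------------------------------------------------------------
# pregnancy-outcome ledger

#: parent -> child branches of the outcome flowchart
OUTCOME_TREE: dict[str, tuple[str, ...]] = {
    "enrolled": ("qc_failed", "screened"),
    "screened": ("positive", "negative"),
    "positive": ("diagnosed", "not_diagnosed"),
    "diagnosed": ("tp", "fp"),
    "tp": ("tp_termination", "tp_continue"),
    "fp": ("fp_continue",),
    "not_diagnosed": ("nd_termination", "nd_normal_delivery"),
    "negative": ("neg_lost", "neg_accident", "neg_ca_induced",
                 "neg_no_abnormality", "neg_false_negative"),
}


@dataclass(frozen=True)
class OutcomeLedger:
    """Counts for every branch of the screening-outcome flowchart."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, children in OUTCOME_TREE.items():
            if node in self.counts and all(c in self.counts for c in children):
                total = sum(self.counts[c] for c in children)
                if total != self.counts[node]:
                    raise ValueError(
                        f"outcome ledger violates conservation at {node!r}: "
                        f"{self.counts[node]} != sum(children) {total}")

    def __getitem__(self, key: str) -> int:
        return self.counts[key]


def build_outcome_ledger(node_counts: Mapping[str, int],
                         branch_probs: Mapping[str, Mapping[str, float]],
                         rng: np.random.Generator | int | None = None,
                         ) -> OutcomeLedger:
    """Allocate cases through the outcome flowchart.

    ``node_counts`` fixes the counts of root nodes (e.g. tp, fp,
    not_diagnosed, negative); ``branch_probs`` gives, per parent node, the
    probability of each child branch (must sum to 1).  With an RNG the
    allocation is multinomial (simulation mode); without one, provided
    child counts are simply validated (real-mode tabulation).
    """
    counts = dict(node_counts)
    if rng is not None and isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    for node, probs in branch_probs.items():
        children = OUTCOME_TREE.get(node)
        if children is None:
            raise ValueError(f"unknown outcome node {node!r}")
        p = np.array([probs.get(c, 0.0) for c in children], dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError(f"branch probabilities for {node!r} outside [0,1]")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError(f"branch probabilities for {node!r} must sum to 1")
        n = counts.get(node, 0)
        if rng is None:
            alloc = np.round(p * n).astype(int)
            alloc[-1] = n - alloc[:-1].sum()
        else:
            alloc = rng.multinomial(n, p)
        for c, k in zip(children, alloc):
            counts[c] = int(k)
    return OutcomeLedger(counts)
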