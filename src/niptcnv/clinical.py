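"""Bundled tallies from a published 68,588-pregnancy NIPT screening cohort.

The counts below are the printed cross-tabulations of a large retrospective
clinical evaluation of cfDNA screening for subchromosomal CNVs: diagnosed
true/false positives by size stratum and CNV type, screen-positive and PPV
contrasts between the library-construction eras, the cohort failure tally
and the pregnancy-outcome flowchart.  They serve as ground truth for the
screening-performance arithmetic: :func:`reproduce_tables` recomputes every
rate and test statistic from the raw counts and diffs the results against
the printed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .performance import (OutcomeLedger, ScreeningTable, pearson_chi2,
                          positive_rate, ppv)


@dataclass(frozen=True)
class ClinicalTallies:
    """Raw counts of the reference screening cohort."""

    enrolled: int = 68_592
    qc_failed: int = 4
    positives: int = 281
    deletion_positives: int = 193
    duplication_positives: int = 88
    diagnosed: int = 161
    #: stratum -> (deletion TP, deletion FP, duplication TP, duplication FP)
    strata: dict = field(default_factory=lambda: {
        "0-5": (31, 30, 15, 8),
        "5-10": (17, 11, 7, 5),
        "10-20": (8, 1, 4, 4),
        ">=20": (5, 6, 5, 4),
    })
    around_1mb: tuple = (22, 12)  # (TP, FP) among calls near 1 Mb
    #: era -> (screen positives, screened)
    era_pr: dict = field(default_factory=lambda: {
        "pre_improvement": (19, 12_885),
        "post_improvement": (262, 55_703),
    })
    #: era -> (TP, FP) among diagnosed
    era_ppv: dict = field(default_factory=lambda: {
        "pre_improvement": (4, 10),
        "post_improvement": (88, 59),
    })
    #: pregnancy-outcome flowchart branches
    outcomes: dict = field(default_factory=lambda: {
        "tp_termination": 80, "tp_continue": 12,
        "fp_continue": 69,
        "nd_termination": 7, "nd_normal_delivery": 113,
        "neg_lost": 735, "neg_accident": 286, "neg_ca_induced": 331,
        "neg_no_abnormality": 66_954, "neg_false_negative": 1,
    })

    @property
    def screened(self) -> int:
        return self.enrolled - self.qc_failed

    def stratum_table(self, stratum: str, kind: str) -> ScreeningTable:
        d_tp, d_fp, u_tp, u_fp = self.strata[stratum]
        if kind == "deletion":
            return ScreeningTable(d_tp, d_fp, f"{stratum}/deletion")
        if kind == "duplication":
            return ScreeningTable(u_tp, u_fp, f"{stratum}/duplication")
        return ScreeningTable(d_tp + u_tp, d_fp + u_fp, f"{stratum}/total")

    def margin(self, kind: str) -> ScreeningTable:
        tp = sum(self.stratum_table(s, kind).tp for s in self.strata)
        fp = sum(self.stratum_table(s, kind).fp for s in self.strata)
        return ScreeningTable(tp, fp, kind)

    def outcome_ledger(self) -> OutcomeLedger:
        tp, fp = self.margin("total").tp, self.margin("total").fp
        counts = dict(self.outcomes)
        counts.update({
            "enrolled": self.enrolled, "qc_failed": self.qc_failed,
            "screened": self.screened, "positive": self.positives,
            "negative": self.screened - self.positives,
            "diagnosed": self.diagnosed,
            "not_diagnosed": self.positives - self.diagnosed,
            "tp": tp, "fp": fp,
        })
        return OutcomeLedger(counts)


CLINICAL_TALLIES = ClinicalTallies()

#: The printed values the recomputation must reproduce exactly.
PRINTED_VALUES: dict[str, float] = {
    "overall_ppv": 57.14,
    "deletion_ppv": 55.96,
    "duplication_ppv": 59.62,
    "ppv_0_5mb": 54.76,
    "ppv_5_10mb": 60.00,
    "ppv_10_20mb": 70.59,
    "ppv_ge20mb": 50.00,
    "ppv_around_1mb": 64.71,
    "positive_rate": 0.41,
    "pr_pre_era": 0.15,
    "pr_post_era": 0.47,
    "ppv_pre_era": 28.57,
    "ppv_post_era": 59.86,
    "diagnosis_rate": 57.30,
    "failure_rate": 0.006,
    "chi2_pr": 26.74,
    "chi2_ppv": 5.11,
}

_STRATUM_KEY = {"0-5": "ppv_0_5mb", "5-10": "ppv_5_10mb",
                "10-20": "ppv_10_20mb", ">=20": "ppv_ge20mb"}


@dataclass(frozen=True)
class ReproductionReport:
    """Computed-vs-printed diff of the screening tables."""

    computed: dict[str, float]
    expected: dict[str, float]

    @property
    def mismatches(self) -> dict[str, tuple[float, float]]:
        return {k: (self.computed[k], v) for k, v in self.expected.items()
                if self.computed.get(k) != v}

    @property
    def ok(self) -> bool:
        return not self.mismatches


def compute_screening_values(tallies: ClinicalTallies = CLINICAL_TALLIES
                             ) -> dict[str, float]:
    """Recompute every printed rate and statistic from the raw counts."""
    values: dict[str, float] = {
        "overall_ppv": ppv(tallies.margin("total")),
        "deletion_ppv": ppv(tallies.margin("deletion")),
        "duplication_ppv": ppv(tallies.margin("duplication")),
        "ppv_around_1mb": ppv(tp=tallies.around_1mb[0], fp=tallies.around_1mb[1]),
        "positive_rate": positive_rate(tallies.positives, tallies.screened),
        "diagnosis_rate": round(100.0 * tallies.diagnosed / tallies.positives, 2),
        "failure_rate": round(100.0 * tallies.qc_failed / tallies.enrolled, 3),
    }
    for stratum, key in _STRATUM_KEY.items():
        values[key] = ppv(tallies.stratum_table(stratum, "total"))
    for era, tag in (("pre_improvement", "pre_era"), ("post_improvement", "post_era")):
        pos, screened = tallies.era_pr[era]
        values[f"pr_{tag}"] = positive_rate(pos, screened)
        tp, fp = tallies.era_ppv[era]
        values[f"ppv_{tag}"] = ppv(tp=tp, fp=fp)
    (pos_pre, scr_pre) = tallies.era_pr["pre_improvement"]
    (pos_post, scr_post) = tallies.era_pr["post_improvement"]
    values["chi2_pr"], _, _ = pearson_chi2(
        [[pos_pre, scr_pre - pos_pre], [pos_post, scr_post - pos_post]])
    values["chi2_ppv"], _, _ = pearson_chi2(
        [list(tallies.era_ppv["pre_improvement"]),
         list(tallies.era_ppv["post_improvement"])])
    return values


def reproduce_tables(tallies: ClinicalTallies = CLINICAL_TALLIES,
                     expected: dict[str, float] | None = None
                     ) -> ReproductionReport:
    """Recompute the screening tables and diff them against printed values.

    Any mismatch is listed in the report; with the bundled tallies the
    report must be clean.  Perturbing a single count (via
    ``dataclasses.replace``) flags the affected cells, which makes the diff
    harness itself testable.
    """
    return ReproductionReport(compute_screening_values(tallies),
                              dict(expected or PRINTED_VALUES))


def perturbed(tallies: ClinicalTallies, stratum: str, delta: int
              ) -> ClinicalTallies:
    """A copy of the tallies with the deletion-TP count of one stratum shifted."""
    strata = dict(tallies.strata)
    d_tp, d_fp, u_tp, u_fp = strata[stratum]
    strata[stratum] = (d_tp + delta, d_fp, u_tp, u_fp)
    return replace(tallies, strata=strata)
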