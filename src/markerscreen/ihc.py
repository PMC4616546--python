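"""Diagnostic evaluation of ordinal immunohistochemistry (IHC) grading.

Each stained specimen is graded on two ordinal axes: staining intensity
(``negative`` / ``weak`` / ``strong``) and the proportion of positive
tumor cells (``none`` <1%, ``partial`` 1-90%, ``diffuse`` >=90%).  A
*positivity rule* maps (intensity, proportion) grades to a binary call;
two rules are built in:

* ``strict``  — strong diffuse staining only; and
* ``lenient`` — strong diffuse plus any weak staining (partial or
  diffuse).

Sensitivity and specificity for a target tumor type are computed from
the resulting 2x2 table, with Wilson score 95% confidence intervals
(well-behaved at the 0%/100% proportions that clean markers produce).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._format import percent, round_half_up

__all__ = [
    "INTENSITIES",
    "PROPORTIONS",
    "IHCRecord",
    "PositivityRule",
    "STRICT_RULE",
    "LENIENT_RULE",
    "call_positivity",
    "tabulate",
    "metrics",
    "ConfusionCounts",
    "DiagnosticMetrics",
    "records_from_frame",
]

INTENSITIES = ("negative", "weak", "strong")
PROPORTIONS = ("none", "partial", "diffuse")


@dataclass(frozen=True)
class IHCRecord:
    """One case's grade for one marker.

    Intensity ``negative`` and proportion ``none`` imply each other: a
    stain with no positive cells has no intensity to grade, and a graded
    stain must have nonzero extent.
    """

    case_id: str
    tumor_type: str
    marker: str
    intensity: str
    proportion: str

    def __post_init__(self) -> None:
        if self.intensity not in INTENSITIES:
            raise ValueError(
                f"unknown intensity {self.intensity!r}; allowed: {', '.join(INTENSITIES)}"
            )
        if self.proportion not in PROPORTIONS:
            raise ValueError(
                f"unknown proportion {self.proportion!r}; allowed: {', '.join(PROPORTIONS)}"
            )
        if (self.intensity == "negative") != (self.proportion == "none"):
            raise ValueError(
                f"case {self.case_id!r}: intensity {self.intensity!r} inconsistent with "
                f"proportion {self.proportion!r} (negative <=> none)"
            )


@dataclass(frozen=True)
class PositivityRule:
    """Set of (intensity, proportion) grades called positive."""

    name: str
    accepted: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for inten, prop in self.accepted:
            if inten not in INTENSITIES or prop not in PROPORTIONS:
                raise ValueError(f"invalid grade pair ({inten!r}, {prop!r}) in rule {self.name!r}")
        if ("negative", "none") in self.accepted:
            raise ValueError("a positivity rule cannot accept the (negative, none) grade")


STRICT_RULE = PositivityRule("strict", frozenset({("strong", "diffuse")}))
LENIENT_RULE = PositivityRule(
    "lenient",
    frozenset({("strong", "diffuse"), ("weak", "diffuse"), ("weak", "partial")}),
)

RULES = {r.name: r for r in (STRICT_RULE, LENIENT_RULE)}


def call_positivity(r: IHCRecord, rule: PositivityRule) -> bool:
    """True iff the record's (intensity, proportion) grade is accepted by the rule."""
    return (r.intensity, r.proportion) in rule.accepted


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally of positivity calls against target tumor-type membership."""

    tp: int
    fp: int
    tn: int
    fn: int
    target_type: str
    rule_name: str

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_target(self) -> int:
        return self.tp + self.fn

    @property
    def n_other(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity with Wilson score 95% confidence intervals.

    Point estimates are exact rationals; ``*_percent`` values are the
    half-up one-decimal display forms.
    """

    sensitivity: Fraction
    specificity: Fraction
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    counts: ConfusionCounts

    @property
    def sensitivity_percent(self) -> float:
        return percent(self.sensitivity.numerator, self.sensitivity.denominator)

    @property
    def specificity_percent(self) -> float:
        return percent(self.specificity.numerator, self.specificity.denominator)


def tabulate(
    records: list[IHCRecord],
    marker: str,
    target_type: str,
    rule: PositivityRule,
) -> ConfusionCounts:
    """Count positives/negatives for one marker against a target tumor type.

    One record per (case, marker) pair; a duplicate pair is a hard error.
    Cases of the target type are positives-to-be-found (tp/fn); all other
    tumor types are negatives-to-be-excluded (tn/fp).
    """
    seen: set[tuple[str, str]] = set()
    tp = fp = tn = fn = 0
    for r in records:
        if r.marker != marker:
            continue
        key = (r.case_id, r.marker)
        if key in seen:
            raise ValueError(f"duplicate record for case {r.case_id!r}, marker {marker!r}")
        seen.add(key)
        pos = call_positivity(r, rule)
        if r.tumor_type == target_type:
            tp += pos
            fn += not pos
        else:
            fp += pos
            tn += not pos
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, target_type=target_type, rule_name=rule.name)


def metrics(c: ConfusionCounts, alpha: float = 0.05) -> DiagnosticMetrics:
    """Sensitivity tp/(tp+fn) and specificity tn/(tn+fp) with Wilson CIs."""
    if c.n_target == 0:
        raise ValueError("sensitivity undefined: no target-type cases")
    if c.n_other == 0:
        raise ValueError("specificity undefined: no non-target cases")
    sens = Fraction(c.tp, c.n_target)
    spec = Fraction(c.tn, c.n_other)

    def wilson(k: int, n: int) -> tuple[float, float]:
        lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
        # at p-hat = 0 or 1 the Wilson bound equals the estimate exactly;
        # guard against floating-point wobble crossing it
        est = k / n
        return max(0.0, min(float(lo), est)), min(1.0, max(float(hi), est))

    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=wilson(c.tp, c.n_target),
        specificity_ci=wilson(c.tn, c.n_other),
        counts=c,
    )


def positivity_rate(records: list[IHCRecord], marker: str, tumor_type: str,
                    rule: PositivityRule) -> tuple[Fraction, float]:
    """Fraction of one tumor type's cases called positive, with display percent.

    Used for tumor types evaluated for marker overlap (e.g. renal
    oncocytoma) rather than as a diagnostic target.
    """
    c = tabulate(records, marker, tumor_type, rule)
    if c.n_target == 0:
        raise ValueError(f"no cases of tumor type {tumor_type!r} for marker {marker!r}")
    frac = Fraction(c.tp, c.n_target)
    return frac, percent(frac.numerator, frac.denominator)


def records_from_frame(df: pd.DataFrame) -> list[IHCRecord]:
    """Build validated records from a case_id,tumor_type,marker,intensity,proportion table."""
    needed = ["case_id", "tumor_type", "marker", "intensity", "proportion"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"IHC table missing column(s): {', '.join(missing)}")
    return [
        IHCRecord(
            case_id=str(row.case_id),
            tumor_type=str(row.tumor_type),
            marker=str(row.marker),
            intensity=str(row.intensity),
            proportion=str(row.proportion),
        )
        for row in df.itertuples(index=False)
    ]


def metrics_frame(m: DiagnosticMetrics, marker: str) -> pd.DataFrame:
    """One-row summary table for report output."""
    c = m.counts
    return pd.DataFrame(
        [
            {
                "marker": marker,
                "target_type": c.target_type,
                "rule": c.rule_name,
                "tp": c.tp,
                "fn": c.fn,
                "fp": c.fp,
                "tn": c.tn,
                "sensitivity_percent": m.sensitivity_percent,
                "specificity_percent": m.specificity_percent,
                "sensitivity_ci_low": round_half_up(m.sensitivity_ci[0], 4),
                "sensitivity_ci_high": round_half_up(m.sensitivity_ci[1], 4),
                "specificity_ci_low": round_half_up(m.specificity_ci[0], 4),
                "specificity_ci_high": round_half_up(m.specificity_ci[1], 4),
            }
        ]
    )
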