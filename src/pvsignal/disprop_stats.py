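"""Reporting odds ratio (ROR) estimation for disproportionality analysis.

For a target exposure and a comparator, reports are cross-classified into a
2×2 table

    ============  =========  ===========
                  event      no event
    ============  =========  ===========
    target        a          b
    comparator    c          d
    ============  =========  ===========

and the ROR is the odds ratio ``(a/b)/(c/d)``: how much more often the event
is reported under the target than under the comparator.  The 95% confidence
interval is the Wald interval on the log scale,

    exp( ln(ROR) ± 1.959964 · sqrt(1/a + 1/b + 1/c + 1/d) ),

and a result is flagged as a *signal* when the CI lower bound exceeds 1 and
there are at least 3 event cases.  Counting is case-level: a report counts
once toward a cell no matter how many qualifying terms it carries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .report_model import AgeBand, Report, ReportSet, Sex
from .vocabulary import DrugDictionary, Vocabulary, exposure_products

__all__ = [
    "Z_95",
    "TwoByTwo",
    "RorResult",
    "ComparatorDesign",
    "StratumResult",
    "DegenerateTableError",
    "build_contingency",
    "ror",
    "is_signal",
    "stratified_rors",
    "round_half_up",
]

#: Two-sided 95% normal quantile used throughout.
Z_95 = 1.959964


class DegenerateTableError(ValueError):
    """Raised when a zero cell makes the ROR or its CI undefined."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as results are conventionally printed
    (Python's builtin round is half-to-even).  Display only; internal
    values are never rounded."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TwoByTwo:
    """Contingency counts: a/b event/non-event under the target exposure,
    c/d under the comparator."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_target(self) -> int:
        return self.a + self.b

    @property
    def n_comparator(self) -> int:
        return self.c + self.d

    def zero_cells(self) -> list[str]:
        return [n for n in ("a", "b", "c", "d") if getattr(self, n) == 0]


@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_lower: float
    ci_upper: float
    n_cases: int
    is_signal: bool
    correction_applied: bool = False
    table: TwoByTwo | None = None


@dataclass(frozen=True)
class ComparatorDesign:
    """Which reports form the target and comparator cohorts.

    ``comparator=None`` means rest-of-database (every report not exposed to
    a target product).  With ``exclusive`` (the default) reports exposed to
    both a target and a comparator product are dropped from the contrast,
    so each report contributes to at most one cohort.
    """

    target: frozenset[str]
    comparator: frozenset[str] | None = None
    exclusive: bool = True

    def __post_init__(self) -> None:
        if not self.target:
            raise ValueError("target product set must be non-empty")
        if self.comparator is not None and not self.comparator:
            raise ValueError("reference product set must be non-empty when given")


def build_contingency(
    rs: ReportSet,
    dictionary: DrugDictionary,
    vocab: Vocabulary,
    design: ComparatorDesign,
    group_id: str,
) -> TwoByTwo:
    """Cross-classify deduplicated reports into the 2×2 table for one
    event group under a comparator design.

    A report is an event case if any of its PTs classifies into
    ``group_id``; it is counted once regardless of how many qualifying PTs
    it carries.
    """
    group = vocab.group(group_id)  # raises KeyError for unknown group
    a = b = c = d = dropped_dual = 0
    for rep in rs:
        products = exposure_products(dictionary, rep)
        in_target = bool(products & design.target)
        if design.comparator is None:
            in_comp = not in_target
        else:
            in_comp = bool(products & design.comparator)
        if in_target and in_comp:
            if design.exclusive:
                dropped_dual += 1
                continue
            in_comp = False  # non-exclusive: target membership wins
        if not in_target and not in_comp:
            continue
        is_case = any(pt in group.terms for pt in rep.events)
        if in_target:
            a += is_case
            b += not is_case
        else:
            c += is_case
            d += not is_case
    if dropped_dual:
        import logging
        logging.getLogger(__name__).info(
            "build_contingency(%s): dropped %d dual-exposed reports",
            group_id, dropped_dual)
    return TwoByTwo(a, b, c, d)


def ror(t: TwoByTwo, correction: str = "none") -> RorResult:
    """Estimate the reporting odds ratio and its 95% Wald CI.

    With ``correction="none"`` a zero cell is a hard error (the table is
    degenerate).  With ``correction="haldane_half"`` 0.5 is added to all
    four cells whenever any cell is zero (Haldane–Anscombe), for
    exploratory output; ``n_cases`` always reports the uncorrected count.
    """
    if correction not in ("none", "haldane_half"):
        raise ValueError(f"unknown correction: {correction!r}")
    zero = t.zero_cells()
    applied = False
    if zero and correction == "none":
        raise DegenerateTableError(
            f"zero cell(s) {', '.join(zero)}: ROR undefined without correction")
    cells = [float(t.a), float(t.b), float(t.c), float(t.d)]
    if zero:
        cells = [x + 0.5 for x in cells]
        applied = True
    a, b, c, d = cells
    est = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(est) - Z_95 * se)
    hi = math.exp(math.log(est) + Z_95 * se)
    return RorResult(
        ror=est, ci_lower=lo, ci_upper=hi, n_cases=t.a,
        is_signal=lo > 1.0 and t.a >= 3,
        correction_applied=applied, table=t,
    )


def is_signal(r: RorResult) -> bool:
    """Signal rule: 95% CI lower bound strictly above 1 and at least 3 cases."""
    return r.ci_lower > 1.0 and r.n_cases >= 3


# ---------------------------------------------------------------------------
# stratified estimates

@dataclass(frozen=True)
class StratumResult:
    """Per-stratum outcome: the table always, the estimate when defined."""

    stratum: str
    table: TwoByTwo
    result: RorResult | None
    reason: str | None = None  # set when degenerate


def _stratum_of(rep: Report, strata: str) -> str:
    if strata == "sex":
        return rep.sex.value
    if strata == "age_band":
        return rep.age_band.value
    raise ValueError(f"unknown stratification: {strata!r}")


def stratified_rors(
    rs: ReportSet,
    dictionary: DrugDictionary,
    vocab: Vocabulary,
    design: ComparatorDesign,
    group_id: str,
    strata: str,
    correction: str = "none",
) -> dict[str, StratumResult]:
    """One estimate per stratum (sex or age band) with at least one report
    in each cohort; strata whose table has a zero cell under
    ``correction="none"`` are returned as degenerate with counts only."""
    levels = [s.value for s in (Sex if strata == "sex" else AgeBand)]
    out: dict[str, StratumResult] = {}
    for level in levels:
        sub = ReportSet([r for r in rs if _stratum_of(r, strata) == level],
                        provenance=rs.provenance)
        t = build_contingency(sub, dictionary, vocab, design, group_id)
        if t.n_target == 0 or t.n_comparator == 0:
            continue  # stratum absent from one cohort: no row
        try:
            res = ror(t, correction=correction)
            out[level] = StratumResult(level, t, res)
        except DegenerateTableError as err:
            out[level] = StratumResult(level, t, None, reason=str(err))
    return out
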