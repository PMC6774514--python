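"""2x2 contingency statistics and frequency tables for case-control HLA data.

Every association reported by the pipeline reduces to a category-vs-rest 2x2
table between two groups::

                category   rest
    cases          a        b        (a + b = case denominator)
    controls       c        d        (c + d = control denominator)

with the cross-product odds ratio ad/bc, its Woolf (log-normal) 95% CI, and a
two-sided p-value from either the 1-df Pearson chi-square statistic (no
continuity correction) or Fisher's exact test.  Test selection follows the
classical expected-cell rule (any expected count < 5 -> Fisher) and is always
recorded in the result, since the choice matters for small cells.

Counting units:

* ``haplotype_slots`` — each subject contributes two observations (one per
  chromosome); denominators are 2N.
* ``carriers`` — each subject contributes once if they carry >= 1 copy;
  denominators are N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

from scipy import stats

__all__ = [
    "CountTable2x2",
    "AssociationResult",
    "FrequencyTable",
    "build_frequency_table",
    "category_vs_rest",
    "cross_product_or",
    "conditional_mle_or",
    "woolf_ci",
    "pearson_chi2_p",
    "fisher_exact_p",
    "expected_cells",
    "choose_test",
    "associate",
    "rare_partition",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ZeroDivisionError):
    """A statistic is undefined for this table (zero cell or margin)."""


@dataclass(frozen=True)
class CountTable2x2:
    """Cells of a category-vs-rest comparison between two groups."""

    a: int  # case, category
    b: int  # case, rest
    c: int  # control, category
    d: int  # control, rest

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError(f"cells must be non-negative integers, got {cell}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def case_total(self) -> int:
        return self.a + self.b

    @property
    def control_total(self) -> int:
        return self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) margins."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class AssociationResult:
    """One category's association: counts, OR, 95% CI, p, and the test used."""

    category: str
    table: CountTable2x2
    or_: float | None
    ci_low: float | None
    ci_high: float | None
    p: float
    test_used: str  # "chi2" | "fisher"
    estimator: str = "cross_product"  # "cross_product" | "conditional"

    @property
    def case_pct(self) -> float:
        return 100.0 * self.table.a / self.table.case_total

    @property
    def control_pct(self) -> float:
        return 100.0 * self.table.c / self.table.control_total


def cross_product_or(t: CountTable2x2) -> float:
    """Cross-product (sample) odds ratio ad/bc."""
    if t.b * t.c == 0:
        raise UndefinedStatisticError("cross-product OR undefined: b*c == 0")
    return (t.a * t.d) / (t.b * t.c)


def conditional_mle_or(t: CountTable2x2) -> float:
    """Conditional maximum-likelihood OR (the estimator of exact 2x2 tests)."""
    res = stats.contingency.odds_ratio(
        [[t.a, t.b], [t.c, t.d]], kind="conditional"
    )
    return float(res.statistic)


def woolf_ci(t: CountTable2x2, level: float = 0.95) -> tuple[float, float]:
    """Woolf log-normal CI: exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d))."""
    if min(t.a, t.b, t.c, t.d) == 0:
        raise UndefinedStatisticError("Woolf CI undefined with a zero cell")
    z = stats.norm.ppf(0.5 + level / 2.0)
    log_or = math.log(cross_product_or(t))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def conditional_exact_ci(t: CountTable2x2, level: float = 0.95) -> tuple[float, float]:
    """Exact (conditional) CI accompanying the conditional-MLE estimator."""
    res = stats.contingency.odds_ratio(
        [[t.a, t.b], [t.c, t.d]], kind="conditional"
    )
    ci = res.confidence_interval(confidence_level=level)
    return (float(ci.low), float(ci.high))


def expected_cells(t: CountTable2x2) -> tuple[float, float, float, float]:
    """Expected counts under independence, in (a, b, c, d) order."""
    r1, r2, c1, c2 = t.margins()
    n = t.n
    if n == 0:
        raise UndefinedStatisticError("empty table")
    return (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)


def pearson_chi2_p(t: CountTable2x2) -> float:
    """Two-sided p from the 1-df Pearson statistic, no continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    r1, r2, c1, c2 = t.margins()
    if min(r1, r2, c1, c2) == 0:
        raise UndefinedStatisticError("chi-square undefined with a zero margin")
    stat = t.n * (t.a * t.d - t.b * t.c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stats.chi2.sf(stat, df=1))


def fisher_exact_p(t: CountTable2x2) -> float:
    """Two-sided Fisher exact p by exact integer enumeration.

    Sums hypergeometric probabilities (margins fixed) of every table whose
    probability is <= that of the observed table.  Weights C(r1,x)*C(r2,c1-x)
    share the denominator C(N,c1), so the tie comparison is exact integer
    arithmetic — no floating-point tolerance is involved.
    """
    r1, r2, c1, _ = t.margins()
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    observed = comb(r1, t.a) * comb(r2, c1 - t.a)
    total = 0
    kept = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        total += w
        if w <= observed:
            kept += w
    return kept / total


def choose_test(t: CountTable2x2, rule: str = "expected5") -> str:
    """Select ``"chi2"`` or ``"fisher"`` for a table.

    ``expected5`` (default): Fisher when any expected cell is < 5, else the
    Pearson chi-square.  ``always_chi2`` / ``always_fisher`` force one test
    (the chi-square still falls back to Fisher on a zero margin).
    """
    if rule == "always_fisher":
        return "fisher"
    r1, r2, c1, c2 = t.margins()
    if min(r1, r2, c1, c2) == 0:
        return "fisher"
    if rule == "always_chi2":
        return "chi2"
    if rule != "expected5":
        raise ValueError(f"unknown test-selection rule {rule!r}")
    return "fisher" if min(expected_cells(t)) < 5 else "chi2"


def associate(
    category: str,
    t: CountTable2x2,
    estimator: str = "cross_product",
    test_rule: str = "expected5",
    level: float = 0.95,
) -> AssociationResult:
    """Full association for one table: OR, CI, p, with degenerate-cell care.

    Rows where the OR or CI is undefined (zero cells) report ``None`` there,
    matching the blank treatment of degenerate rows in printed tables.
    """
    test = choose_test(t, test_rule)
    p = pearson_chi2_p(t) if test == "chi2" else fisher_exact_p(t)
    or_: float | None
    ci: tuple[float | None, float | None]
    if estimator == "conditional":
        try:
            or_ = conditional_mle_or(t)
            ci = conditional_exact_ci(t, level)
        except (ValueError, UndefinedStatisticError):
            or_, ci = None, (None, None)
    elif estimator == "cross_product":
        try:
            or_ = cross_product_or(t)
        except UndefinedStatisticError:
            or_ = None
        try:
            ci = woolf_ci(t, level)
        except UndefinedStatisticError:
            ci = (None, None)
    else:
        raise ValueError(f"unknown OR estimator {estimator!r}")
    return AssociationResult(
        category=category,
        table=t,
        or_=or_,
        ci_low=ci[0],
        ci_high=ci[1],
        p=p,
        test_used=test,
        estimator=estimator,
    )


@dataclass
class FrequencyTable:
    """Per-category counts and denominators for each group."""

    unit: str  # "haplotype_slots" | "carriers"
    counts: dict[str, dict[str, int]]  # group -> category -> count
    denominators: dict[str, int]  # group -> denominator

    def categories(self) -> list[str]:
        cats: set[str] = set()
        for group_counts in self.counts.values():
            cats.update(group_counts)
        return sorted(cats)

    def count(self, group: str, category: str) -> int:
        return self.counts[group].get(category, 0)

    def pct(self, group: str, category: str) -> float:
        return 100.0 * self.count(group, category) / self.denominators[group]


def build_frequency_table(
    items: Mapping[str, Sequence[Sequence[str]]],
    unit: str = "haplotype_slots",
) -> FrequencyTable:
    """Count categories per group from per-subject category lists.

    ``items`` maps a group label to one entry per subject, each entry the
    subject's category labels (two haplotype labels, or the two allele labels
    at a locus).  ``haplotype_slots`` counts every entry (homozygotes twice,
    denominator 2N by construction of two-entry lists); ``carriers`` counts a
    subject once if any entry matches (denominator N).
    """
    if unit not in ("haplotype_slots", "carriers"):
        raise ValueError(f"unknown counting unit {unit!r}")
    counts: dict[str, dict[str, int]] = {}
    denominators: dict[str, int] = {}
    for group, subjects in items.items():
        group_counts: dict[str, int] = {}
        slots = 0
        for labels in subjects:
            if unit == "haplotype_slots":
                slots += len(labels)
                for lab in labels:
                    group_counts[lab] = group_counts.get(lab, 0) + 1
            else:
                for lab in set(labels):
                    group_counts[lab] = group_counts.get(lab, 0) + 1
        denominators[group] = slots if unit == "haplotype_slots" else len(subjects)
        counts[group] = group_counts
    return FrequencyTable(unit=unit, counts=counts, denominators=denominators)


def category_vs_rest(
    freq: FrequencyTable, category: str, group_case: str, group_control: str
) -> CountTable2x2:
    """2x2 table of one category against all others, cases vs controls."""
    a = freq.count(group_case, category)
    c = freq.count(group_control, category)
    if a == 0 and c == 0:
        raise KeyError(f"category {category!r} absent from both groups")
    return CountTable2x2(
        a=a,
        b=freq.denominators[group_case] - a,
        c=c,
        d=freq.denominators[group_control] - c,
    )


def rare_partition(
    freq: FrequencyTable, threshold_pct: float = 1.0
) -> tuple[list[str], list[str]]:
    """Split categories into common (>= threshold in ANY group) and rare.

    The boundary is inclusive: a category at exactly the threshold is common.
    """
    common: list[str] = []
    rare: list[str] = []
    for cat in freq.categories():
        if any(freq.pct(g, cat) >= threshold_pct for g in freq.counts):
            common.append(cat)
        else:
            rare.append(cat)
    return common, rare
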