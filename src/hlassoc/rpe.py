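"""Relative predispositional effects (RPE) by sequential elimination.

After a dominant association is established at a locus, weaker effects are
masked: every category-vs-rest table shares its "rest" with the dominant
category.  The RPE procedure removes that mask iteratively.  Each round tests
every remaining category against the rest of the (shrinking) totals; the
category with the largest deviation — operationalised as the smallest
p-value — is excluded, its counts removed from both groups, and the next
round begins.  The procedure stops when no eligible category reaches the
significance threshold.  Categories with too few case observations
(``case count < min_case_count``, default 2, i.e. at most one affected
carrier chromosome) are never considered significant and can never be
excluded, but stay in the background totals.

The full per-round, per-category p-value grid is retained — it is the
multi-column p structure of the published RPE tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .association import CountTable2x2, choose_test, expected_cells, fisher_exact_p, pearson_chi2_p

__all__ = ["RPERound", "RPETrace", "run_rpe"]


@dataclass(frozen=True)
class RPERound:
    """One round of the elimination procedure."""

    round_index: int  # 1-based
    case_total: int  # totals *entering* this round
    control_total: int
    per_category_p: dict[str, float]
    per_category_test: dict[str, str]
    excluded_category: str | None  # None on the terminal round


@dataclass
class RPETrace:
    """Ordered rounds plus the categories excluded as significant."""

    rounds: list[RPERound]
    significant: list[str]
    alpha: float
    min_case_count: int

    def p_grid(self) -> dict[str, list[float | None]]:
        """category -> one p per round (None once the category is excluded)."""
        grid: dict[str, list[float | None]] = {}
        for r in self.rounds:
            for cat in r.per_category_p:
                grid.setdefault(cat, [None] * (r.round_index - 1))
            for cat, row in grid.items():
                row.append(r.per_category_p.get(cat))
        return grid


def _deviation(t: CountTable2x2) -> float:
    """|observed - expected| case-cell deviation, the documented tie-break."""
    return abs(t.a - expected_cells(t)[0])


def run_rpe(
    case_counts: Mapping[str, int],
    control_counts: Mapping[str, int],
    alpha: float = 0.05,
    min_case_count: int = 2,
    test_rule: str = "expected5",
    background: Iterable[str] = (),
) -> RPETrace:
    """Run sequential elimination on per-category counts of two groups.

    ``background`` labels are counted in the totals and tested like any other
    category but are never eligible for exclusion — used when the input is an
    aggregated remainder (published tables list only their significant rows)
    rather than a real category.

    Ties on the minimum p are broken by the larger case-cell deviation
    |observed - expected|, then by label order.
    """
    labels = sorted(set(case_counts) | set(control_counts))
    if not labels:
        raise ValueError("no categories supplied")
    case = {lab: int(case_counts.get(lab, 0)) for lab in labels}
    control = {lab: int(control_counts.get(lab, 0)) for lab in labels}
    if any(v < 0 for v in list(case.values()) + list(control.values())):
        raise ValueError("negative counts")
    background = set(background)
    case_total = sum(case.values())
    control_total = sum(control.values())
    if case_total <= 0 or control_total <= 0:
        raise ValueError("both groups need positive totals")

    remaining = list(labels)
    rounds: list[RPERound] = []
    significant: list[str] = []

    while remaining:
        per_p: dict[str, float] = {}
        per_test: dict[str, str] = {}
        candidates: list[tuple[float, float, str]] = []
        for lab in remaining:
            a, c = case[lab], control[lab]
            t = CountTable2x2(a, case_total - a, c, control_total - c)
            if a + c == 0 or (t.b + t.d) == 0:
                continue  # degenerate category-vs-rest split, no test
            test = choose_test(t, test_rule)
            p = pearson_chi2_p(t) if test == "chi2" else fisher_exact_p(t)
            per_p[lab] = p
            per_test[lab] = test
            if lab not in background and a >= min_case_count:
                candidates.append((p, -_deviation(t), lab))
        excluded = None
        if candidates:
            p_best, _, lab_best = min(candidates)
            if p_best < alpha:
                excluded = lab_best
        rounds.append(
            RPERound(
                round_index=len(rounds) + 1,
                case_total=case_total,
                control_total=control_total,
                per_category_p=per_p,
                per_category_test=per_test,
                excluded_category=excluded,
            )
        )
        if excluded is None:
            break
        significant.append(excluded)
        case_total -= case.pop(excluded)
        control_total -= control.pop(excluded)
        remaining.remove(excluded)
        if case_total <= 0 or control_total <= 0:
            break

    return RPETrace(
        rounds=rounds,
        significant=significant,
        alpha=alpha,
        min_case_count=min_case_count,
    )
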