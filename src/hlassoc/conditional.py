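"""Analyses conditioned on carrying the anchor risk haplotype.

In a cohort where nearly every case carries one high-risk haplotype, the
interesting question moves to the *other* chromosome: among carriers, does a
particular second haplotype — or a second copy of the risk haplotype itself
(homozygosity) — add risk?  Both analyses compare anchor carriers between
groups:

* second-haplotype association: among heterozygous carriers, each observed
  second haplotype vs the rest;
* homozygosity: homozygote vs heterozygote carriers.

Because published conditional tables have used inconsistent denominators for
such blocks, results carry both candidate denominators (all carriers, and
heterozygous carriers only) explicitly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .association import AssociationResult, CountTable2x2, associate
from .nomenclature import truncate_to_resolution
from .phasing import Haplotype, PhasedSubject

__all__ = [
    "CarrierSet",
    "select_carriers",
    "second_haplotype_association",
    "homozygosity_test",
]


def _match_at_resolution(a: Haplotype, b: Haplotype, n_fields: int) -> bool:
    if a.slots != b.slots:
        return False
    for ca, cb in zip(a.calls, b.calls):
        ta = truncate_to_resolution(ca, n_fields) if not ca.is_null else ca
        tb = truncate_to_resolution(cb, n_fields) if not cb.is_null else cb
        if ta != tb:
            return False
    return True


def matches_anchor(h: Haplotype, anchor: Haplotype, resolution: int = 3) -> bool:
    """Anchor identity at ``resolution`` fields, retried at two fields.

    The same risk haplotype circulates in the literature under two-field and
    three-field spellings; the two-field fallback lets either convention in
    configuration match three-field calls in data.
    """
    if _match_at_resolution(h, anchor, resolution):
        return True
    return resolution > 2 and _match_at_resolution(h, anchor, 2)


@dataclass
class CarrierSet:
    """Anchor carriers of one group, split by anchor dose."""

    group: str
    carriers: list[PhasedSubject]
    homozygotes: list[PhasedSubject]
    heterozygotes: list[PhasedSubject]
    second_haplotypes: Counter  # label -> count, one per heterozygote
    n_unresolved: int  # phased-but-ambiguous or unphased subjects skipped

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)

    @property
    def n_homozygous(self) -> int:
        return len(self.homozygotes)


def select_carriers(
    phased: Sequence[PhasedSubject],
    anchor: Haplotype,
    group: str = "",
    resolution: int = 3,
) -> CarrierSet:
    """Partition a phased cohort into anchor homozygotes / heterozygotes.

    Unresolved subjects cannot be classified and are excluded, with their
    number reported for diagnostics.
    """
    carriers: list[PhasedSubject] = []
    homo: list[PhasedSubject] = []
    het: list[PhasedSubject] = []
    seconds: Counter = Counter()
    unresolved = 0
    for ps in phased:
        if not ps.resolved or ps.hap1 is None or ps.hap2 is None:
            unresolved += 1
            continue
        m1 = matches_anchor(ps.hap1, anchor, resolution)
        m2 = matches_anchor(ps.hap2, anchor, resolution)
        if not (m1 or m2):
            continue
        carriers.append(ps)
        if m1 and m2:
            homo.append(ps)
        else:
            het.append(ps)
            second = ps.hap2 if m1 else ps.hap1
            seconds[second.label] += 1
    return CarrierSet(
        group=group,
        carriers=carriers,
        homozygotes=homo,
        heterozygotes=het,
        second_haplotypes=seconds,
        n_unresolved=unresolved,
    )


def second_haplotype_association(
    cases: CarrierSet,
    controls: CarrierSet,
    estimator: str = "cross_product",
    test_rule: str = "expected5",
) -> list[AssociationResult]:
    """Each second haplotype vs the rest, among heterozygous carriers.

    Rows are ordered by descending case frequency, ties by label; haplotypes
    absent from both groups emit no row.
    """
    n_case = len(cases.heterozygotes)
    n_ctrl = len(controls.heterozygotes)
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both carrier sets need heterozygous carriers")
    labels = set(cases.second_haplotypes) | set(controls.second_haplotypes)
    results = []
    for lab in sorted(
        labels, key=lambda l: (-cases.second_haplotypes.get(l, 0), l)
    ):
        a = cases.second_haplotypes.get(lab, 0)
        c = controls.second_haplotypes.get(lab, 0)
        t = CountTable2x2(a, n_case - a, c, n_ctrl - c)
        results.append(associate(lab, t, estimator=estimator, test_rule=test_rule))
    return results


def homozygosity_test(
    cases: CarrierSet,
    controls: CarrierSet,
    estimator: str = "cross_product",
    test_rule: str = "expected5",
) -> AssociationResult:
    """Anchor homozygote vs heterozygote among carriers, cases vs controls."""
    if cases.n_carriers == 0 or controls.n_carriers == 0:
        raise ValueError("both groups need anchor carriers")
    t = CountTable2x2(
        cases.n_homozygous,
        cases.n_carriers - cases.n_homozygous,
        controls.n_homozygous,
        controls.n_carriers - controls.n_homozygous,
    )
    return associate(
        "anchor_homozygosity", t, estimator=estimator, test_rule=test_rule
    )
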