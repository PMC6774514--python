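"""Extended-haplotype reconstruction.

Two reconstruction routes, mirroring how family and population cohorts differ:

* **descent phasing** (families): enumerate every assignment of each member's
  per-locus genotype into two haplotypes and keep the assignments consistent
  with Mendelian transmission of *intact* haplotypes (no recombination inside
  the DR-DQ block).  A member is phased when exactly one unordered haplotype
  pair survives; otherwise the member is reported unresolved with the number
  of admissible pairs.

* **anchor assembly** (unrelated subjects): the stepwise scheme seeded by a
  designated high-LD risk haplotype.  (1) homozygotes phase trivially;
  (2) carriers of every anchor allele phase by subtraction, the remainders
  entering a growing set of known haplotypes; (3) remaining subjects are
  decomposed as one known haplotype plus a remainder, in passes until a fixed
  point, preferring the most frequent known haplotype; (4) when a subject's
  two candidate haplotypes are both known with the *same* DRB3/4/5 allele,
  the shared allele goes to the more common haplotype and the other haplotype
  takes the remaining allele.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .nomenclature import AlleleCall, SLOT_ORDER, parse_allele

__all__ = [
    "Haplotype",
    "PhasedSubject",
    "KnownHaplotypeSet",
    "Genotype",
    "PhasingError",
    "MendelianError",
    "phase_by_descent",
    "assemble_by_anchor",
    "haplotype_label",
]

#: A subject's unphased genotype: slot name -> canonically ordered allele pair.
Genotype = Mapping[str, tuple[AlleleCall, AlleleCall]]


class PhasingError(ValueError):
    """Raised when reconstruction hits an internally inconsistent state."""


class MendelianError(PhasingError):
    """A family's genotypes are incompatible with Mendelian transmission."""


@dataclass(frozen=True)
class Haplotype:
    """An ordered run of allele calls, one per haplotype slot."""

    calls: tuple[AlleleCall, ...]

    def __post_init__(self) -> None:
        slots = [c.locus.slot for c in self.calls]
        order = [s for s in SLOT_ORDER if s in slots]
        if slots != order or len(set(slots)) != len(slots):
            raise PhasingError(f"calls out of slot order or duplicated: {slots}")
        # label determines the haplotype; cache it and hash on it (the
        # reconstruction loops hash haplotypes heavily)
        object.__setattr__(self, "_label", "-".join(c.label for c in self.calls))
        object.__setattr__(self, "_hash", hash(("Haplotype", self._label)))

    def __hash__(self) -> int:
        return self._hash

    @property
    def slots(self) -> tuple[str, ...]:
        return tuple(c.locus.slot for c in self.calls)

    @property
    def label(self) -> str:
        return self._label

    def call_at(self, slot: str) -> AlleleCall:
        for c in self.calls:
            if c.locus.slot == slot:
                return c
        raise KeyError(slot)

    def project(self, slots: Sequence[str]) -> "Haplotype":
        keep = set(slots)
        return Haplotype(tuple(c for c in self.calls if c.locus.slot in keep))

    @classmethod
    def from_label(cls, label: str) -> "Haplotype":
        calls = tuple(parse_allele(part) for part in label.split("-"))
        return cls(calls)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    def __lt__(self, other: "Haplotype") -> bool:
        return self.label < other.label


def haplotype_label(h: Haplotype, locus_subset: Sequence[str] | None = None) -> str:
    """Hyphen-joined label, optionally projected onto a subset of slots."""
    if locus_subset is None:
        return h.label
    return h.project(locus_subset).label


@dataclass(frozen=True)
class PhasedSubject:
    """One subject's reconstructed haplotype pair and how it was obtained."""

    subject_id: str
    hap1: Haplotype | None
    hap2: Haplotype | None
    provenance: str  # descent|homozygote|anchor_subtraction|known_match|conflict_rule|unresolved
    ambiguity_count: int = 1

    @property
    def resolved(self) -> bool:
        return self.provenance != "unresolved"

    def pair(self) -> tuple[Haplotype, Haplotype] | None:
        if self.hap1 is None or self.hap2 is None:
            return None
        return tuple(sorted((self.hap1, self.hap2)))  # type: ignore[return-value]


class KnownHaplotypeSet:
    """Haplotypes seen so far with their observation counts.

    Iteration order is descending count with ties broken by label, which is
    the preference order of assembly step 3 and the tie rule of step 4.
    """

    def __init__(self, initial: Iterable[tuple[Haplotype, int]] = ()) -> None:
        self._counts: dict[str, int] = {}
        self._haps: dict[str, Haplotype] = {}
        for h, n in initial:
            self.add(h, n)

    def add(self, h: Haplotype, n: int = 1) -> None:
        if n < 0:
            raise ValueError("counts must be non-negative")
        self._haps[h.label] = h
        self._counts[h.label] = self._counts.get(h.label, 0) + n

    def count(self, h: Haplotype) -> int:
        return self._counts.get(h.label, 0)

    def __contains__(self, h: Haplotype) -> bool:
        return h.label in self._haps

    def __len__(self) -> int:
        return len(self._haps)

    def __iter__(self):
        return iter(self.ordered())

    def ordered(self) -> list[Haplotype]:
        return [
            self._haps[lab]
            for lab in sorted(self._counts, key=lambda l: (-self._counts[l], l))
        ]

    def items(self) -> list[tuple[Haplotype, int]]:
        return [(h, self._counts[h.label]) for h in self.ordered()]


# ---------------------------------------------------------------------------
# descent phasing
# ---------------------------------------------------------------------------


def _subject_phasings(
    genotype: Genotype, slots: Sequence[str]
) -> list[tuple[Haplotype, Haplotype]]:
    """All distinct assignments of a genotype into an ordered haplotype pair."""
    per_slot: list[list[tuple[AlleleCall, AlleleCall]]] = []
    for slot in slots:
        a, b = genotype[slot]
        if a == b:
            per_slot.append([(a, b)])
        else:
            per_slot.append([(a, b), (b, a)])
    out = []
    for combo in itertools.product(*per_slot):
        h1 = Haplotype(tuple(x for x, _ in combo))
        h2 = Haplotype(tuple(y for _, y in combo))
        out.append((h1, h2))
    return out


def _unordered(pair: tuple[Haplotype, Haplotype]) -> tuple[Haplotype, Haplotype]:
    return tuple(sorted(pair))  # type: ignore[return-value]


def _check_locuswise_mendelian(
    family_id: str,
    genotypes: Mapping[str, Genotype],
    trios: Sequence[tuple[str, str | None, str | None]],
    slots: Sequence[str],
) -> None:
    """Per-locus transmission check, to name the offending subject and locus."""
    for child, father, mother in trios:
        for slot in slots:
            ca, cb = genotypes[child][slot]
            fp = set(genotypes[father][slot]) if father else None
            mp = set(genotypes[mother][slot]) if mother else None
            ok = False
            for x, y in ((ca, cb), (cb, ca)):
                from_f = fp is None or x in fp
                from_m = mp is None or y in mp
                if from_f and from_m:
                    ok = True
                    break
            if not ok:
                raise MendelianError(
                    f"family {family_id}: subject {child} incompatible with "
                    f"parents at {slot}"
                )


def phase_by_descent(
    family_id: str,
    genotypes: Mapping[str, Genotype],
    parents: Mapping[str, tuple[str | None, str | None]],
    slots: Sequence[str] = ("DRB345", "DRB1", "DQA1", "DQB1"),
) -> list[PhasedSubject]:
    """Phase a family by joint enumeration over transmission-consistent splits.

    ``parents`` maps each subject to (father_id, mother_id), ``None`` for a
    missing/founder parent; parent ids not genotyped are treated as missing.
    Haplotypes are transmitted intact (no recombination inside the block), so
    a child's unordered pair must combine one haplotype from each available
    parent's split.  Exhaustive over members' 2^(het loci - 1) splits —
    exact, and cheap for nuclear families over <= 8 loci.
    """
    members = [m for m in genotypes if all(s in genotypes[m] for s in slots)]
    if len(members) < 2:
        raise PhasingError(f"family {family_id}: need >= 2 genotyped members")
    trios = []
    for m in members:
        f, mo = parents.get(m, (None, None))
        f = f if f in genotypes else None
        mo = mo if mo in genotypes else None
        if f or mo:
            trios.append((m, f, mo))
    _check_locuswise_mendelian(family_id, genotypes, trios, slots)

    options = {m: _subject_phasings(genotypes[m], slots) for m in members}
    admissible: dict[str, set[tuple[Haplotype, Haplotype]]] = {
        m: set() for m in members
    }
    any_solution = False
    child_ids = {c for c, _, _ in trios}
    parent_ids = {p for _, f, mo in trios for p in (f, mo) if p}

    def _child_choices(child, f_haps, m_haps):
        good = []
        for c1, c2 in options[child]:
            for x, y in ((c1, c2), (c2, c1)):
                if (f_haps is None or x in f_haps) and (
                    m_haps is None or y in m_haps
                ):
                    good.append((c1, c2))
                    break
        return good

    if child_ids & parent_ids:
        # multi-generation pedigree: joint product over every member
        for combo in itertools.product(*(options[m] for m in members)):
            assign = dict(zip(members, combo))
            ok = all(
                _child_choices(
                    child,
                    set(assign[father]) if father else None,
                    set(assign[mother]) if mother else None,
                ).count(assign[child])
                > 0
                for child, father, mother in trios
            )
            if ok:
                any_solution = True
                for m in members:
                    admissible[m].add(_unordered(assign[m]))
    else:
        # nuclear family: given the parents' splits, each child's admissible
        # splits are independent, so enumerate parents only
        parent_list = sorted(parent_ids)
        free = [m for m in members if m not in child_ids and m not in parent_ids]
        for combo in itertools.product(*(options[p] for p in parent_list)):
            passign = dict(zip(parent_list, combo))
            per_child: dict[str, list] = {}
            ok = True
            for child, father, mother in trios:
                good = _child_choices(
                    child,
                    set(passign[father]) if father else None,
                    set(passign[mother]) if mother else None,
                )
                if not good:
                    ok = False
                    break
                per_child[child] = good
            if not ok:
                continue
            any_solution = True
            for p in parent_list:
                admissible[p].add(_unordered(passign[p]))
            for child, good in per_child.items():
                for pr in good:
                    admissible[child].add(_unordered(pr))
        if not trios:
            any_solution = True
        for m in free:
            for pr in options[m]:
                admissible[m].add(_unordered(pr))
    if not any_solution:
        raise MendelianError(
            f"family {family_id}: genotypes require recombinant transmission"
        )
    out = []
    for m in members:
        pairs = sorted(admissible[m])
        h1, h2 = pairs[0]
        if len(pairs) == 1:
            out.append(PhasedSubject(m, h1, h2, "descent", 1))
        else:
            out.append(PhasedSubject(m, h1, h2, "unresolved", len(pairs)))
    return out


# ---------------------------------------------------------------------------
# anchor assembly
# ---------------------------------------------------------------------------


def _fits(h: Haplotype, genotype: Genotype, slots: Sequence[str]) -> bool:
    return all(h.call_at(s) in genotype[s] for s in slots)


def _subtract(h: Haplotype, genotype: Genotype, slots: Sequence[str]) -> Haplotype:
    """Remainder haplotype after removing one copy of ``h``'s alleles."""
    calls = []
    for s in slots:
        a, b = genotype[s]
        calls.append(b if h.call_at(s) == a else a)
    return Haplotype(tuple(calls))


def _full_decompositions(
    genotype: Genotype, known: KnownHaplotypeSet, slots: Sequence[str]
) -> list[tuple[Haplotype, Haplotype]]:
    """Distinct unordered pairs (known h, remainder) fitting the genotype."""
    seen: dict[tuple[str, str], tuple[Haplotype, Haplotype]] = {}
    for h in known:
        if _fits(h, genotype, slots):
            rem = _subtract(h, genotype, slots)
            key = tuple(sorted((h.label, rem.label)))
            seen.setdefault(key, _unordered((h, rem)))
    return [seen[k] for k in sorted(seen)]


def _is_drb345_swap_family(
    pairs: Sequence[tuple[Haplotype, Haplotype]], slots: Sequence[str]
) -> bool:
    """True when candidate decompositions differ only in which haplotype
    carries which DRB3/4/5 allele — the conflict the step-4 rule resolves."""
    if "DRB345" not in slots or len(pairs) < 2:
        return False
    rest = [s for s in slots if s != "DRB345"]
    projections = {
        tuple(sorted(h.project(rest).label for h in pr)) for pr in pairs
    }
    return len(projections) == 1


def assemble_by_anchor(
    genotypes: Mapping[str, Genotype],
    anchor: Haplotype,
    known: KnownHaplotypeSet | None = None,
    slots: Sequence[str] | None = None,
) -> tuple[list[PhasedSubject], KnownHaplotypeSet]:
    """Assemble extended haplotypes for unrelated subjects around an anchor.

    Returns one :class:`PhasedSubject` per input subject (input order) and
    the grown :class:`KnownHaplotypeSet`.  Subjects whose genotype admits
    more than one known-haplotype decomposition keep the pair preferred by
    frequency but are flagged unresolved with the number of distinct pairs;
    subjects admitting none get ``ambiguity_count == 0``.
    """
    if slots is None:
        slots = anchor.slots
    known = known if known is not None else KnownHaplotypeSet()
    known.add(anchor, 0)

    results: dict[str, PhasedSubject] = {}

    # step 1: homozygotes
    for sid, g in genotypes.items():
        if all(g[s][0] == g[s][1] for s in slots):
            h = Haplotype(tuple(g[s][0] for s in slots))
            results[sid] = PhasedSubject(sid, h, h, "homozygote")
            known.add(h, 2)

    # step 2: carriers of every anchor allele, phased by subtraction
    for sid, g in genotypes.items():
        if sid in results or not _fits(anchor, g, slots):
            continue
        rem = _subtract(anchor, g, slots)
        results[sid] = PhasedSubject(sid, anchor, rem, "anchor_subtraction")
        known.add(anchor)
        known.add(rem)

    # step 3: iterative decomposition against the known set, to a fixed point
    pending = [sid for sid in genotypes if sid not in results]
    changed = True
    while changed:
        changed = False
        still = []
        for sid in pending:
            g = genotypes[sid]
            pairs = _full_decompositions(g, known, slots)
            if not pairs:
                still.append(sid)
                continue
            # prefer the decomposition whose known haplotype is most frequent
            best = sorted(
                pairs,
                key=lambda pr: (
                    -max(known.count(pr[0]), known.count(pr[1])),
                    min(pr[0].label, pr[1].label),
                ),
            )[0]
            if len(pairs) == 1:
                provenance, ambiguity = "known_match", 1
            elif _is_drb345_swap_family(pairs, slots):
                # step 4: both candidate haplotypes are known with the same
                # DRB3/4/5 allele; the frequency-preferred decomposition keeps
                # the shared allele on the more common haplotype
                provenance, ambiguity = "conflict_rule", 1
            else:
                provenance, ambiguity = "unresolved", len(pairs)
            results[sid] = PhasedSubject(sid, best[0], best[1], provenance, ambiguity)
            if provenance != "unresolved":
                known.add(best[0])
                known.add(best[1])
            changed = True
        pending = still

    for sid in pending:
        results[sid] = PhasedSubject(sid, None, None, "unresolved", 0)

    ordered = [results[sid] for sid in genotypes]
    for ps in ordered:
        if ps.pair() is not None:
            _check_conservation(ps, genotypes[ps.subject_id], slots)
    return ordered, known


def _check_conservation(
    ps: PhasedSubject, genotype: Genotype, slots: Sequence[str]
) -> None:
    """hap1 + hap2 must reproduce the genotype's allele multiset per slot."""
    assert ps.hap1 is not None and ps.hap2 is not None
    for s in slots:
        got = sorted((ps.hap1.call_at(s), ps.hap2.call_at(s)))
        want = sorted(genotype[s])
        if got != want:
            raise PhasingError(
                f"subject {ps.subject_id}: allele conservation violated at {s}"
            )
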