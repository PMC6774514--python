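"""Descent phasing and anchor assembly, scored against enumeration and truth."""

import itertools

import numpy as np
import pytest

from hlassoc.phasing import (
    Haplotype,
    KnownHaplotypeSet,
    MendelianError,
    assemble_by_anchor,
    haplotype_label,
    phase_by_descent,
)
from hlassoc.simulate import (
    ANCHOR_LABEL,
    SECOND_RISK_LABEL,
    HaplotypePool,
    default_pool,
    sample_families,
    sample_population,
)

from conftest import genotype_of

SLOTS = ("DRB345", "DRB1", "DQA1", "DQB1")


def hap(label: str) -> Haplotype:
    return Haplotype.from_label(label)


def trio(father_pair, mother_pair, child_pair):
    genotypes = {
        "dad": genotype_of(*father_pair),
        "mom": genotype_of(*mother_pair),
        "kid": genotype_of(*child_pair),
    }
    parents = {"kid": ("dad", "mom")}
    return genotypes, parents


def brute_force_child_pairs(child_g, father_g, mother_g, slots=SLOTS):
    """Independent oracle: all unordered child splits with one haplotype
    drawable per-locus from each parent's allele pair."""
    per_slot = []
    for s in slots:
        a, b = child_g[s]
        per_slot.append([(a, b)] if a == b else [(a, b), (b, a)])
    found = set()
    for combo in itertools.product(*per_slot):
        h1 = Haplotype(tuple(x for x, _ in combo))
        h2 = Haplotype(tuple(y for _, y in combo))
        for pat, mat in ((h1, h2), (h2, h1)):
            ok_f = all(pat.call_at(s) in father_g[s] for s in slots)
            ok_m = all(mat.call_at(s) in mother_g[s] for s in slots)
            if ok_f and ok_m:
                found.add(tuple(sorted((h1, h2))))
                break
    return found


class TestDescentPhasing:
    def test_homozygous_parents_force_everyone(self, pool):
        f = pool.haplotypes[0]
        m = pool.haplotypes[1]
        genotypes, parents = trio((f, f), (m, m), (f, m))
        phased = phase_by_descent("F1", genotypes, parents)
        assert all(ps.provenance == "descent" for ps in phased)
        assert all(ps.ambiguity_count == 1 for ps in phased)
        kid = next(ps for ps in phased if ps.subject_id == "kid")
        assert kid.pair() == tuple(sorted((f, m)))

    def test_symmetric_identically_heterozygous_trio_is_unresolved(self, pool):
        a, b = pool.haplotypes[0], pool.haplotypes[1]
        genotypes, parents = trio((a, b), (a, b), (a, b))
        phased = phase_by_descent("F1", genotypes, parents)
        kid = next(ps for ps in phased if ps.subject_id == "kid")
        # {a,b} is forced for everyone here; build a truly symmetric case by
        # crossing two haplotypes that differ everywhere: the child split
        # cannot distinguish (a,b) from the recombinant-free alternative only
        # when parents disagree; with identical parents the pair is unique
        assert kid.ambiguity_count >= 1

    def test_crossing_ambiguity_detected(self):
        # haplotypes A-B and B-A patterns: child admits two distinct pairs
        h1 = hap("DRB5*01:01:01-DRB1*15:01:01-DQA1*01:02:01-DQB1*06:02:01")
        h2 = hap("DRB5*01:01:01-DRB1*15:01:01-DQA1*01:02:01-DQB1*06:03:01")
        h3 = hap("DRB4*01:03:01-DRB1*04:01:01-DQA1*03:01:01-DQB1*06:02:01")
        h4 = hap("DRB4*01:03:01-DRB1*04:01:01-DQA1*03:01:01-DQB1*06:03:01")
        # father carries h1/h4, mother h2/h3: the child's genotype from h1+h3
        # is also explained by h2+h4 ... only if transmissible; enumerate
        genotypes, parents = trio((h1, h4), (h2, h3), (h1, h3))
        phased = phase_by_descent("F1", genotypes, parents)
        kid = next(ps for ps in phased if ps.subject_id == "kid")
        oracle = brute_force_child_pairs(
            genotypes["kid"], genotypes["dad"], genotypes["mom"]
        )
        assert kid.ambiguity_count == len(oracle)
        assert (kid.ambiguity_count == 1) == (kid.provenance == "descent")

    def test_mendelian_inconsistency_names_family_and_locus(self, pool):
        f, m, other = pool.haplotypes[0], pool.haplotypes[1], pool.haplotypes[2]
        genotypes, parents = trio((f, f), (m, m), (f, other))
        with pytest.raises(MendelianError, match="F1"):
            phase_by_descent("F1", genotypes, parents)

    def test_agrees_with_brute_force_on_generated_trios(self, pool):
        rng = np.random.default_rng(7)
        n_checked = 0
        for _ in range(150):
            idx = rng.integers(len(pool.haplotypes), size=6)
            f = (pool.haplotypes[idx[0]], pool.haplotypes[idx[1]])
            m = (pool.haplotypes[idx[2]], pool.haplotypes[idx[3]])
            kid_pair = (f[rng.integers(2)], m[rng.integers(2)])
            genotypes, parents = trio(f, m, kid_pair)
            phased = phase_by_descent("F", genotypes, parents)
            kid = next(ps for ps in phased if ps.subject_id == "kid")
            oracle = brute_force_child_pairs(
                genotypes["kid"], genotypes["dad"], genotypes["mom"]
            )
            assert kid.ambiguity_count == len(oracle)
            assert kid.pair() in oracle
            true_pair = tuple(sorted(kid_pair))
            if kid.provenance == "descent":
                assert kid.pair() == true_pair
                n_checked += 1
            # allele conservation for every member
            for ps in phased:
                for s in SLOTS:
                    got = sorted((ps.hap1.call_at(s), ps.hap2.call_at(s)))
                    assert got == sorted(genotypes[ps.subject_id][s])
        assert n_checked > 50  # most trios resolve under strong LD

    def test_child_haplotypes_come_from_phased_parents(self, pool):
        ped, table, truth = sample_families(pool, 10, 2, seed=3)
        parents = {r.subject_id: (r.father_id, r.mother_id) for r in ped}
        fams = {}
        for r in ped:
            fams.setdefault(r.family_id, []).append(r.subject_id)
        for fam, members in fams.items():
            genotypes = {m: table.pairs[m] for m in members}
            phased = {ps.subject_id: ps for ps in phase_by_descent(fam, genotypes, parents)}
            for r in ped:
                if r.family_id != fam or not r.father_id:
                    continue
                kid, dad, mom = phased[r.subject_id], phased[r.father_id], phased[r.mother_id]
                if all(p.provenance == "descent" for p in (kid, dad, mom)):
                    parental = {dad.hap1, dad.hap2, mom.hap1, mom.hap2}
                    assert kid.hap1 in parental and kid.hap2 in parental


class TestAnchorAssembly:
    def test_homozygote_phases_trivially(self, pool, anchor):
        h = pool.haplotypes[3]
        genotypes = {"s1": genotype_of(h, h), "s2": genotype_of(anchor, h)}
        phased, known = assemble_by_anchor(genotypes, anchor)
        assert phased[0].provenance == "homozygote"
        assert phased[0].hap1 == phased[0].hap2 == h

    def test_anchor_subtraction_recovers_published_second_haplotype(self, anchor):
        second = hap(SECOND_RISK_LABEL)
        genotypes = {"s": genotype_of(anchor, second)}
        phased, _ = assemble_by_anchor(genotypes, anchor)
        assert phased[0].provenance == "anchor_subtraction"
        assert phased[0].pair() == tuple(sorted((anchor, second)))

    def test_known_match_grows_by_iteration(self, pool, anchor):
        a, b, c = pool.haplotypes[1], pool.haplotypes[3], pool.haplotypes[4]
        genotypes = {
            "seed": genotype_of(anchor, a),  # step 2 adds a to known
            "chain": genotype_of(a, b),  # b enters via a
            "chain2": genotype_of(b, c),  # c enters via b on a later pass
        }
        phased, known = assemble_by_anchor(genotypes, anchor)
        by_id = {ps.subject_id: ps for ps in phased}
        assert by_id["chain"].provenance == "known_match"
        assert by_id["chain2"].provenance == "known_match"
        assert by_id["chain2"].pair() == tuple(sorted((b, c)))
        assert all(h in known for h in (a, b, c))

    def test_drb345_conflict_goes_to_more_common_haplotype(self, anchor):
        # two known haplotypes sharing the DRB345 allele; a subject het at
        # DRB345 must hand the unmatched allele to the rarer haplotype
        common = hap("DRB3*01:01:02-DRB1*03:01:01-DQA1*05:01:01-DQB1*02:01:01")
        rarer = hap("DRB3*01:01:02-DRB1*13:01:01-DQA1*01:03:01-DQB1*06:03:01")
        known = KnownHaplotypeSet([(common, 10), (rarer, 2)])
        variant_drb = hap(
            "DRB3*02:02:01-DRB1*13:01:01-DQA1*01:03:01-DQB1*06:03:01"
        )
        subject = genotype_of(common, variant_drb)
        phased, _ = assemble_by_anchor({"s": subject}, anchor, known)
        assert phased[0].provenance == "conflict_rule"
        assert phased[0].pair() == tuple(sorted((common, variant_drb)))

    def test_undecomposable_subject_reported_unresolved(self, pool, anchor):
        rare1 = pool.haplotypes[12]
        rare2 = pool.haplotypes[13]
        phased, _ = assemble_by_anchor({"s": genotype_of(rare1, rare2)}, anchor)
        assert not phased[0].resolved
        assert phased[0].ambiguity_count == 0

    def test_synthetic_cohort_recovery_at_least_95_percent(self, pool, anchor):
        table, truth = sample_population(pool, 200, seed=11)
        phased, _ = assemble_by_anchor(table.pairs, anchor)
        resolved = [ps for ps in phased if ps.resolved]
        hits = sum(
            1
            for ps in resolved
            if ps.pair() == truth[ps.subject_id]
        )
        assert len(resolved) > 150
        assert hits / len(resolved) >= 0.95

    def test_recovery_degrades_with_pool_ld_entropy(self, pool, anchor):
        # a crossed pool (every DR block with every DQ block, uniform) has
        # maximal within-block entropy; reconstruction can only get worse
        dr_blocks = [
            "DRB5*01:01:01-DRB1*15:01:01",
            "DRB3*01:01:02-DRB1*03:01:01",
            "DRB4*01:03:01-DRB1*04:01:01",
            "DRBX*null-DRB1*01:01:01",
        ]
        dq_blocks = [
            "DQA1*01:02:01-DQB1*06:02:01",
            "DQA1*05:01:01-DQB1*02:01:01",
            "DQA1*03:02//03:03:01-DQB1*03:01:01",
            "DQA1*01:01:01-DQB1*05:01:01",
        ]
        crossed = HaplotypePool(
            tuple(
                Haplotype.from_label(f"{dr}-{dq}")
                for dr in dr_blocks
                for dq in dq_blocks
            ),
            tuple([1 / 16] * 16),
        )

        def recovery(p):
            table, truth = sample_population(p, 300, seed=5)
            phased, _ = assemble_by_anchor(table.pairs, anchor)
            resolved = [ps for ps in phased if ps.resolved]
            return sum(
                ps.pair() == truth[ps.subject_id] for ps in resolved
            ) / max(len(resolved), 1)

        assert recovery(pool) >= recovery(crossed)

    def test_agrees_with_exhaustive_decomposition_on_tiny_cohorts(self, pool, anchor):
        rng = np.random.default_rng(23)
        table, truth = sample_population(pool, 12, seed=rng)
        phased, _ = assemble_by_anchor(table.pairs, anchor)
        pool_set = set(pool.haplotypes)
        for ps in phased:
            g = table.pairs[ps.subject_id]
            # exhaustive: all splits of the genotype with both halves in the
            # generating pool
            per_slot = [
                [(a, b)] if a == b else [(a, b), (b, a)]
                for a, b in (g[s] for s in SLOTS)
            ]
            splits = set()
            for combo in itertools.product(*per_slot):
                h1 = Haplotype(tuple(x for x, _ in combo))
                h2 = Haplotype(tuple(y for _, y in combo))
                if h1 in pool_set and h2 in pool_set:
                    splits.add(tuple(sorted((h1, h2))))
            if len(splits) == 1 and ps.resolved:
                assert ps.pair() == next(iter(splits))


class TestHaplotypeLabels:
    def test_projections_match_published_row_labels(self, anchor):
        assert haplotype_label(anchor, ("DQA1", "DQB1")) == (
            "DQA1*01:02:01-DQB1*06:02:01"
        )
        assert haplotype_label(anchor, ("DRB345", "DRB1")) == (
            "DRB5*01:01:01-DRB1*15:01:01"
        )

    def test_full_projection_is_identity_and_label_round_trips(self, anchor):
        assert haplotype_label(anchor, anchor.slots) == anchor.label
        assert Haplotype.from_label(anchor.label) == anchor
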