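"""Orchestration: raw genotype tables to association/RPE/conditional outputs.

Two entry modes:

* :func:`run_pipeline` — subject-level mode: family phasing by descent,
  anchor assembly of controls seeded with the family haplotypes, then the
  full ladder of result tables in chromosomal order (per-locus alleles,
  DR-DRB1 and DQ haplotypes, extended haplotypes, genotypes, conditional
  carrier analyses), each with its RPE trace.

* :func:`run_from_counts` / :func:`analyze_counts` — counts mode: the same
  statistical path starting from published per-category counts (the only
  public form of the cohort this package was built around).  When the listed
  categories do not exhaust the declared totals, the remainder becomes a
  background ``OTHER`` category that is counted but never excludable.

Every emitted p-value is appended to the run log with its 2x2 cells and the
test used, so printed-vs-computed discrepancies are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from .association import (
    AssociationResult,
    CountTable2x2,
    FrequencyTable,
    associate,
    build_frequency_table,
    category_vs_rest,
    rare_partition,
)
from .cohort_io import (
    GenotypeTable,
    PedigreeRecord,
    write_association_table,
    write_haplotype_table,
)
from .conditional import (
    CarrierSet,
    homozygosity_test,
    second_haplotype_association,
    select_carriers,
)
from .nomenclature import DEFAULT_MERGE_RULES, AlleleMergeRule, SLOT_ORDER
from .phasing import (
    Haplotype,
    KnownHaplotypeSet,
    PhasedSubject,
    assemble_by_anchor,
    phase_by_descent,
)
from .refdata import ANCHOR, OTHER
from .rpe import RPETrace, run_rpe

__all__ = [
    "PipelineConfig",
    "BlockResult",
    "PipelineResult",
    "analyze_counts",
    "run_from_counts",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults encode the analysis choices the result tables assume."""

    slots: tuple[str, ...] = ("DRB345", "DRB1", "DQA1", "DQB1")
    anchor: str = ANCHOR
    merge_rules: tuple[AlleleMergeRule, ...] = DEFAULT_MERGE_RULES
    rare_threshold_pct: float = 1.0
    alpha: float = 0.05
    min_case_count: int = 2
    estimator: str = "cross_product"  # or "conditional"
    test_rule: str = "expected5"
    anchor_resolution: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rare_threshold_pct < 100:
            raise ValueError("rare threshold must be in (0, 100) percent")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for s in self.slots:
            if s not in SLOT_ORDER:
                raise ValueError(f"unknown haplotype slot {s!r}")

    def anchor_haplotype(self) -> Haplotype:
        return Haplotype.from_label(self.anchor)


@dataclass
class BlockResult:
    """One comparison block: association rows plus the RPE trace."""

    name: str
    results: list[AssociationResult]
    trace: RPETrace
    common: list[str] = field(default_factory=list)
    rare: list[str] = field(default_factory=list)

    def result_for(self, category: str) -> AssociationResult:
        for r in self.results:
            if r.category == category:
                return r
        raise KeyError(category)


def analyze_counts(
    case_counts: Mapping[str, int],
    control_counts: Mapping[str, int],
    config: PipelineConfig = PipelineConfig(),
    name: str = "counts",
    background: Sequence[str] = (OTHER,),
    log: list[str] | None = None,
) -> BlockResult:
    """Association rows and an RPE trace from per-category counts."""
    case_total = sum(case_counts.values())
    control_total = sum(control_counts.values())
    results: list[AssociationResult] = []
    for lab in sorted(set(case_counts) | set(control_counts)):
        if lab in background:
            continue
        a = case_counts.get(lab, 0)
        c = control_counts.get(lab, 0)
        if a == 0 and c == 0:
            continue
        t = CountTable2x2(a, case_total - a, c, control_total - c)
        res = associate(lab, t, estimator=config.estimator, test_rule=config.test_rule)
        results.append(res)
        if log is not None:
            log.append(
                f"{name}\t{lab}\t({t.a},{t.b},{t.c},{t.d})\t{res.test_used}"
                f"\tp={res.p:.6E}"
            )
    trace = run_rpe(
        case_counts,
        control_counts,
        alpha=config.alpha,
        min_case_count=config.min_case_count,
        test_rule=config.test_rule,
        background=background,
    )
    return BlockResult(name=name, results=results, trace=trace)


def run_from_counts(
    counts: "pd.DataFrame",  # noqa: F821 - columns category, case_n, control_n
    case_total: int,
    control_total: int,
    config: PipelineConfig = PipelineConfig(),
    name: str = "counts",
) -> BlockResult:
    """Counts mode from a tidy table; the remainder becomes background.

    Counts exceeding the declared totals are rejected.
    """
    case = {str(r.category): int(r.case_n) for r in counts.itertuples()}
    control = {str(r.category): int(r.control_n) for r in counts.itertuples()}
    if sum(case.values()) > case_total or sum(control.values()) > control_total:
        raise ValueError(f"{name}: counts exceed the declared totals")
    case[OTHER] = case_total - sum(case.values())
    control[OTHER] = control_total - sum(control.values())
    return analyze_counts(case, control, config, name=name)


# ---------------------------------------------------------------------------
# subject-level mode
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Everything the subject-level pipeline produces."""

    allele_blocks: dict[str, dict[str, BlockResult]]  # slot -> comparison -> block
    haplotype_blocks: dict[str, BlockResult]  # projection -> block (NT1 vs GP)
    genotype_block: BlockResult | None
    carriers: dict[str, CarrierSet]
    second_haplotype: list[AssociationResult]
    homozygosity: AssociationResult | None
    phased: dict[str, list[PhasedSubject]]  # group -> phased subjects
    known: KnownHaplotypeSet
    log: list[str]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for slot, comparisons in self.allele_blocks.items():
            for comp, block in comparisons.items():
                write_association_table(
                    block.results,
                    out / f"alleles_{slot}_{comp}.csv",
                    block.trace.p_grid(),
                )
        for proj, block in self.haplotype_blocks.items():
            write_association_table(
                block.results, out / f"haplotypes_{proj}.csv", block.trace.p_grid()
            )
        if self.genotype_block is not None:
            write_association_table(
                self.genotype_block.results,
                out / "genotypes.csv",
                self.genotype_block.trace.p_grid(),
            )
        if self.second_haplotype:
            write_association_table(
                self.second_haplotype, out / "conditional_second_haplotype.csv"
            )
        for group, phased in self.phased.items():
            write_haplotype_table(phased, out / f"phased_{group}.tsv")
        (out / "run_log.txt").write_text(
            "\n".join(self.log) + "\n", encoding="utf-8"
        )


def _allele_items(
    table: GenotypeTable, group: str, slot: str
) -> list[list[str]]:
    items = []
    for sid in table.subjects_in_group(group):
        g = table.pairs[sid]
        if slot in g:
            items.append([g[slot][0].label, g[slot][1].label])
    return items


def _phase_families(
    table: GenotypeTable,
    pedigree: Sequence[PedigreeRecord],
    slots: Sequence[str],
    log: list[str],
) -> dict[str, list[PhasedSubject]]:
    parents = {
        r.subject_id: (r.father_id, r.mother_id) for r in pedigree
    }
    families: dict[str, list[str]] = {}
    for sid, sub in table.subjects.items():
        if sub.family_id:
            families.setdefault(sub.family_id, []).append(sid)
    phased: dict[str, list[PhasedSubject]] = {"NT1": [], "FDR": []}
    for fam, members in sorted(families.items()):
        genos = {
            sid: table.pairs[sid]
            for sid in members
            if all(s in table.pairs[sid] for s in slots)
        }
        if len(genos) < 2:
            log.append(f"descent\tfamily {fam}\tskipped (<2 genotyped members)")
            continue
        for ps in phase_by_descent(fam, genos, parents, slots):
            phased[table.subjects[ps.subject_id].group].append(ps)
    return phased


def run_pipeline(
    config: PipelineConfig,
    table: GenotypeTable,
    pedigree: Sequence[PedigreeRecord] = (),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Full subject-level analysis; see the module docstring for the ladder."""
    log: list[str] = []
    nt1 = table.subjects_in_group("NT1")
    gp = table.subjects_in_group("GP")
    fdr = table.subjects_in_group("FDR")
    if not nt1:
        raise ValueError("empty case (NT1) group")
    if not gp:
        raise ValueError("empty control (GP) group")

    # 1. family phasing by descent
    phased = _phase_families(table, pedigree, config.slots, log)
    known = KnownHaplotypeSet()
    for group_phased in phased.values():
        for ps in group_phased:
            if ps.resolved and ps.pair() is not None:
                known.add(ps.hap1)  # type: ignore[arg-type]
                known.add(ps.hap2)  # type: ignore[arg-type]
    log.append(f"descent\tknown haplotypes from families: {len(known)}")

    # 2. anchor assembly for the unrelated: controls first (they define the
    #    haplotype pool), then any case/FDR subjects without a usable family
    anchor = config.anchor_haplotype().project(config.slots)
    already = {ps.subject_id for group in phased.values() for ps in group}
    for group in ("GP", "NT1", "FDR"):
        genos = {
            sid: table.pairs[sid]
            for sid in table.subjects_in_group(group)
            if sid not in already
            and all(s in table.pairs[sid] for s in config.slots)
        }
        if not genos:
            continue
        assembled, known = assemble_by_anchor(genos, anchor, known, config.slots)
        phased.setdefault(group, []).extend(assembled)
        n_unres = sum(1 for ps in assembled if not ps.resolved)
        log.append(
            f"assembly\t{group} assigned {len(assembled) - n_unres}/{len(assembled)}"
        )
    phased.setdefault("GP", [])

    # 3. per-locus allele tables, both comparisons
    allele_blocks: dict[str, dict[str, BlockResult]] = {}
    for slot in table.slots:
        comparisons: dict[str, BlockResult] = {}
        for comp, ctrl_group in (("nt1_vs_gp", "GP"), ("nt1_vs_fdr", "FDR")):
            if ctrl_group == "FDR" and not fdr:
                continue
            items = {
                "NT1": _allele_items(table, "NT1", slot),
                ctrl_group: _allele_items(table, ctrl_group, slot),
            }
            freq = build_frequency_table(items, unit="haplotype_slots")
            if freq.denominators["NT1"] == 0 or freq.denominators[ctrl_group] == 0:
                continue
            case_counts = dict(freq.counts["NT1"])
            control_counts = dict(freq.counts[ctrl_group])
            block = analyze_counts(
                case_counts,
                control_counts,
                config,
                name=f"alleles_{slot}_{comp}",
                background=(),
                log=log,
            )
            block.common, block.rare = rare_partition(
                freq, config.rare_threshold_pct
            )
            comparisons[comp] = block
        allele_blocks[slot] = comparisons

    # 4. haplotype tables on three projections of the phased cohorts
    projections = {
        "DR_DRB1": ("DRB345", "DRB1"),
        "DQ": ("DQA1", "DQB1"),
        "extended": tuple(config.slots),
    }
    haplotype_blocks: dict[str, BlockResult] = {}
    for proj, proj_slots in projections.items():
        proj_slots = [s for s in proj_slots if s in config.slots]
        items = {
            group: [
                [ps.hap1.project(proj_slots).label, ps.hap2.project(proj_slots).label]
                for ps in phased[group]
                if ps.resolved and ps.pair() is not None
            ]
            for group in ("NT1", "GP")
        }
        freq = build_frequency_table(items, unit="haplotype_slots")
        block = analyze_counts(
            dict(freq.counts["NT1"]),
            dict(freq.counts["GP"]),
            config,
            name=f"haplotypes_{proj}",
            background=(),
            log=log,
        )
        block.common, block.rare = rare_partition(freq, config.rare_threshold_pct)
        haplotype_blocks[proj] = block

    # 5. extended genotypes (subject-level categories)
    geno_items = {
        group: [
            [" + ".join(sorted([ps.hap1.label, ps.hap2.label]))]
            for ps in phased[group]
            if ps.resolved and ps.pair() is not None
        ]
        for group in ("NT1", "GP")
    }
    genotype_block = None
    if geno_items["NT1"] and geno_items["GP"]:
        freq = build_frequency_table(geno_items, unit="carriers")
        genotype_block = analyze_counts(
            dict(freq.counts["NT1"]),
            dict(freq.counts["GP"]),
            config,
            name="genotypes",
            background=(),
            log=log,
        )

    # 6. conditional analyses among anchor carriers
    carriers = {
        group: select_carriers(
            phased[group], anchor, group, config.anchor_resolution
        )
        for group in ("NT1", "GP")
    }
    second = []
    homo = None
    if carriers["NT1"].heterozygotes and carriers["GP"].heterozygotes:
        second = second_haplotype_association(
            carriers["NT1"], carriers["GP"], config.estimator, config.test_rule
        )
        for r in second:
            log.append(
                f"conditional\t{r.category}\t({r.table.a},{r.table.b},"
                f"{r.table.c},{r.table.d})\t{r.test_used}\tp={r.p:.6E}"
            )
    if carriers["NT1"].carriers and carriers["GP"].carriers:
        homo = homozygosity_test(
            carriers["NT1"], carriers["GP"], config.estimator, config.test_rule
        )
        log.append(
            f"conditional\thomozygosity\t({homo.table.a},{homo.table.b},"
            f"{homo.table.c},{homo.table.d})\t{homo.test_used}\tp={homo.p:.6E}"
        )

    result = PipelineResult(
        allele_blocks=allele_blocks,
        haplotype_blocks=haplotype_blocks,
        genotype_block=genotype_block,
        carriers=carriers,
        second_haplotype=second,
        homozygosity=homo,
        phased=phased,
        known=known,
        log=log,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
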