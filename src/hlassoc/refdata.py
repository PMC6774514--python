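"""Published reference counts for the Swedish Pandemrix-narcolepsy cohort.

Subject-level data for this cohort (31 NT1 patients, 66 first-degree
relatives, 636 general-population controls) are not public; what is public
are the per-category counts behind every reported association.  These counts
are the fixture inputs for the pipeline's counts mode: each block below lists
the categories reported as significant, with chromosome counts per group and
the group denominators (haplotype slots: 62 NT1, 1272 GP, 132 FDR; subjects
for genotype blocks: 31 NT1, 636 GP).

Published blocks list only their significant rows, so within each block the
unpublished remainder is aggregated into the ``OTHER`` category, which the
RPE procedure must treat as background (countable, never excludable).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CountBlock",
    "OTHER",
    "NT1_SLOTS",
    "GP_SLOTS",
    "FDR_SLOTS",
    "NT1_SUBJECTS",
    "GP_SUBJECTS",
    "ALLELE_BLOCKS_NT1_VS_GP",
    "ALLELE_BLOCKS_NT1_VS_FDR",
    "HAPLOTYPE_BLOCKS_NT1_VS_GP",
    "GENOTYPE_BLOCK_NT1_VS_GP",
    "CONDITIONAL_SECOND_HAPLOTYPE",
    "ANCHOR",
    "all_blocks",
]

OTHER = "OTHER"

NT1_SLOTS = 62
GP_SLOTS = 1272
FDR_SLOTS = 132
NT1_SUBJECTS = 31
GP_SUBJECTS = 636

ANCHOR = "DRB5*01:01:01-DRB1*15:01:01-DQA1*01:02:01-DQB1*06:02:01"


@dataclass(frozen=True)
class CountBlock:
    """One published block: categories with (case, control) counts."""

    name: str
    case_total: int
    control_total: int
    rows: tuple[tuple[str, int, int], ...]  # (category, case_n, control_n)
    anchor_category: str | None = None  # the anchor-bearing row, if any

    def case_counts(self) -> dict[str, int]:
        counts = {lab: a for lab, a, _ in self.rows}
        counts[OTHER] = self.case_total - sum(counts.values())
        if counts[OTHER] < 0:
            raise ValueError(f"{self.name}: case counts exceed the total")
        return counts

    def control_counts(self) -> dict[str, int]:
        counts = {lab: c for lab, _, c in self.rows}
        counts[OTHER] = self.control_total - sum(counts.values())
        if counts[OTHER] < 0:
            raise ValueError(f"{self.name}: control counts exceed the total")
        return counts


ALLELE_BLOCKS_NT1_VS_GP: tuple[CountBlock, ...] = (
    CountBlock(
        "DRB345_alleles_NT1_vs_GP",
        NT1_SLOTS,
        GP_SLOTS,
        (
            ("DRB3*03:01:01", 4, 56),
            ("DRB4*01:03:01", 13, 307),
            ("DRB5*01:01:01", 34, 205),
        ),
        anchor_category="DRB5*01:01:01",
    ),
    CountBlock(
        "DRB1_alleles_NT1_vs_GP",
        NT1_SLOTS,
        GP_SLOTS,
        (
            ("DRB1*04:01:01", 7, 126),
            ("DRB1*13:02:01", 4, 56),
            ("DRB1*15:01:01", 34, 202),
        ),
        anchor_category="DRB1*15:01:01",
    ),
    CountBlock(
        "DQA1_alleles_NT1_vs_GP",
        NT1_SLOTS,
        GP_SLOTS,
        (
            ("DQA1*01:02:01", 38, 265),
            ("DQA1*03:02//03:03:01", 9, 81),
        ),
        anchor_category="DQA1*01:02:01",
    ),
    CountBlock(
        "DQB1_alleles_NT1_vs_GP",
        NT1_SLOTS,
        GP_SLOTS,
        (
            ("DQB1*03:01:01", 11, 203),
            ("DQB1*06:02:01", 34, 201),
            ("DQB1*06:04:01", 4, 52),
        ),
        anchor_category="DQB1*06:02:01",
    ),
    CountBlock(
        "DPA1_alleles_NT1_vs_GP",
        NT1_SLOTS,
        GP_SLOTS,
        (("DPA1*02:06", 3, 6),),
    ),
    CountBlock(
        "DPB1_alleles_NT1_vs_GP",
        NT1_SLOTS,
        GP_SLOTS,
        (
            ("DPB1*02:01:02", 3, 178),
            ("DPB1*04:02:01", 2, 152),
            ("DPB1*23:01:01", 2, 4),
        ),
    ),
)

ALLELE_BLOCKS_NT1_VS_FDR: tuple[CountBlock, ...] = (
    CountBlock(
        "DRB345_alleles_NT1_vs_FDR",
        NT1_SLOTS,
        FDR_SLOTS,
        (("DRB3*01:01:02", 1, 18),),
    ),
    CountBlock(
        "DRB1_alleles_NT1_vs_FDR",
        NT1_SLOTS,
        FDR_SLOTS,
        (("DRB1*03:01:01", 1, 16),),
    ),
    CountBlock(
        "DQA1_alleles_NT1_vs_FDR",
        NT1_SLOTS,
        FDR_SLOTS,
        (
            ("DQA1*01:02:01", 38, 55),
            ("DQA1*03:02//03:03:01", 9, 13),
        ),
        anchor_category="DQA1*01:02:01",
    ),
    CountBlock(
        "DQB1_alleles_NT1_vs_FDR",
        NT1_SLOTS,
        FDR_SLOTS,
        (("DQB1*02:01:01", 1, 16),),
    ),
)

HAPLOTYPE_BLOCKS_NT1_VS_GP: tuple[CountBlock, ...] = (
    CountBlock(
        "DR_DRB1_haplotypes_NT1_vs_GP",
        NT1_SLOTS,
        GP_SLOTS,
        (
            ("DRB5*01:01:01-DRB1*15:01:01", 34, 201),
            ("DRB4*01:03:01-DRB1*04:01:01", 7, 123),
            ("DRB3*03:01:01-DRB1*13:02:01", 4, 55),
        ),
        anchor_category="DRB5*01:01:01-DRB1*15:01:01",
    ),
    CountBlock(
        "DQ_haplotypes_NT1_vs_GP",
        NT1_SLOTS,
        GP_SLOTS,
        (
            ("DQA1*01:02:01-DQB1*06:02:01", 34, 200),
            ("DQA1*03:02//03:03:01-DQB1*03:01:01", 7, 56),
            ("DQA1*01:02:01-DQB1*06:04:01", 4, 52),
        ),
        anchor_category="DQA1*01:02:01-DQB1*06:02:01",
    ),
    CountBlock(
        "extended_haplotypes_NT1_vs_GP",
        NT1_SLOTS,
        GP_SLOTS,
        (
            (ANCHOR, 34, 194),
            (
                "DRB4*01:03:01-DRB1*04:01:01-DQA1*03:02//03:03:01-DQB1*03:01:01",
                5,
                39,
            ),
            (
                "DRB3*03:01:01-DRB1*13:02:01-DQA1*01:02:01-DQB1*06:04:01",
                4,
                51,
            ),
            (
                "DRB4*01:03:01-DRB1*07:01:01-DQA1*02:01//02:01:01-DQB1*02:02:01",
                3,
                41,
            ),
        ),
        anchor_category=ANCHOR,
    ),
)

# Genotypes among all subjects (denominators are subjects, not chromosomes).
GENOTYPE_BLOCK_NT1_VS_GP = CountBlock(
    "extended_genotypes_NT1_vs_GP",
    NT1_SUBJECTS,
    GP_SUBJECTS,
    (
        (
            ANCHOR
            + " + DRB4*01:03:01-DRB1*04:01:01-DQA1*03:02//03:03:01-DQB1*03:01:01",
            5,
            6,
        ),
        (ANCHOR + " + " + ANCHOR, 4, 16),
        (
            ANCHOR
            + " + DRB3*03:01:01-DRB1*13:02:01-DQA1*01:02:01-DQB1*06:04:01",
            3,
            10,
        ),
        (
            ANCHOR
            + " + DRBX*null-DRB1*08:01:01-DQA1*04:01:01-DQB1*04:02:01",
            2,
            6,
        ),
        (
            ANCHOR
            + " + DRB3*02:02:01-DRB1*12:01:01-DQA1*05:05:01-DQB1*03:01:01",
            2,
            7,
        ),
        (
            ANCHOR
            + " + DRB4*01:03:01-DRB1*07:01:01-DQA1*02:01//02:01:01-DQB1*02:02:01",
            2,
            8,
        ),
    ),
)

#: Second-haplotype counts among anchor carriers: 30 NT1 carriers (4
#: homozygous, 26 heterozygous) vs 178 GP carriers (16 homozygous, 162
#: heterozygous); the second-risk haplotype rides the other chromosome in
#: 5 NT1 and 6 GP heterozygotes.
CONDITIONAL_SECOND_HAPLOTYPE = {
    "nt1": {"carriers": 30, "homozygous": 4, "second_risk": 5},
    "gp": {"carriers": 178, "homozygous": 16, "second_risk": 6},
}


def all_blocks() -> tuple[CountBlock, ...]:
    return (
        ALLELE_BLOCKS_NT1_VS_GP
        + ALLELE_BLOCKS_NT1_VS_FDR
        + HAPLOTYPE_BLOCKS_NT1_VS_GP
        + (GENOTYPE_BLOCK_NT1_VS_GP,)
    )
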