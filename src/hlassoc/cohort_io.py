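"""Read subject genotype tables and pedigrees; write result tables.

All I/O is plain text, UTF-8, LF newlines.

Genotype tables are TSV with ``subject_id``, ``group``, optional
``family_id`` and two columns ``<SLOT>_1`` / ``<SLOT>_2`` per haplotype slot
(DRB345, DRB1, DQA1, DQB1, DPA1, DPB1).  DRB345 cells carry the paralog in
the allele string (``DRB3*01:01:02`` or ``DRBX*null`` / ``null``); other
slots may omit the locus prefix (``06:02:01``).  Both cells of a slot empty
means the locus was not typed — the subject simply drops out of that locus's
denominator.  Phase is never encoded in the input: pairs are canonicalised
(sorted) on read.

Pedigrees are 6-column PED-like text: family, subject, father (0 = missing),
mother, sex, affected (2/1 = affected in PED convention; "1"/"0" accepted).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .association import AssociationResult
from .nomenclature import (
    LOCI,
    SLOT_ORDER,
    AlleleCall,
    AlleleMergeRule,
    AlleleParseError,
    apply_merge_rules,
    parse_allele,
)
from .phasing import PhasedSubject

__all__ = [
    "Subject",
    "PedigreeRecord",
    "GenotypeTable",
    "CohortIOError",
    "read_genotype_table",
    "write_genotype_table",
    "read_pedigree",
    "read_counts",
    "write_association_table",
    "write_haplotype_table",
    "format_p",
    "format_or",
]

GROUPS = ("NT1", "FDR", "GP")


class CohortIOError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortIOError(
                f"subject {self.subject_id}: unknown group {self.group!r}"
            )
        if self.group in ("NT1", "FDR") and not self.family_id:
            raise CohortIOError(
                f"subject {self.subject_id}: {self.group} subjects need a family_id"
            )
        if self.group == "GP" and self.family_id:
            raise CohortIOError(
                f"subject {self.subject_id}: GP subjects must not carry a family_id"
            )


@dataclass(frozen=True)
class PedigreeRecord:
    family_id: str
    subject_id: str
    father_id: str | None
    mother_id: str | None
    affected: bool


@dataclass
class GenotypeTable:
    """Per-subject unordered allele pairs, keyed by haplotype slot."""

    slots: tuple[str, ...]
    subjects: dict[str, Subject]
    pairs: dict[str, dict[str, tuple[AlleleCall, AlleleCall]]]  # sid -> slot -> pair

    def genotype(self, subject_id: str) -> dict[str, tuple[AlleleCall, AlleleCall]]:
        return self.pairs[subject_id]

    def subjects_in_group(self, group: str) -> list[str]:
        return [s for s, sub in self.subjects.items() if sub.group == group]

    def typed_at(self, slot: str) -> list[str]:
        """Subjects with data at ``slot`` (the locus denominator is 2x this)."""
        return [s for s, g in self.pairs.items() if slot in g]


def _parse_cell(text: str, slot: str) -> AlleleCall:
    text = text.strip()
    if slot == "DRB345" and text.lower() == "null":
        return parse_allele("DRBX*null")
    if "*" not in text:
        if slot == "DRB345":
            raise AlleleParseError(
                f"DRB345 cell {text!r} must name its paralog (e.g. DRB3*...)"
            )
        text = f"{slot}*{text}"
    call = parse_allele(text)
    if call.locus.slot != slot:
        raise CohortIOError(f"allele {call.label} in the {slot} column")
    return call


def _is_blank(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() in ("", "NA", ".")


def read_genotype_table(
    path: str | Path,
    slots: Sequence[str] = SLOT_ORDER,
    merge_rules: Sequence[AlleleMergeRule] = (),
) -> GenotypeTable:
    """Read a TSV genotype table; parse alleles, apply merges, canonicalise."""
    # na_filter off: "null" is a real DRB345 token, not missing data
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise CohortIOError(f"{path}: need subject_id and group columns")
    present_slots = [s for s in slots if f"{s}_1" in df.columns]
    for s in present_slots:
        if f"{s}_2" not in df.columns:
            raise CohortIOError(f"{path}: column {s}_2 missing")
    missing = [s for s in slots if s not in present_slots]
    if missing == list(slots):
        raise CohortIOError(f"{path}: no genotype columns found")

    subjects: dict[str, Subject] = {}
    pairs: dict[str, dict[str, tuple[AlleleCall, AlleleCall]]] = {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        if sid in subjects:
            raise CohortIOError(f"{path}: duplicate subject_id {sid!r}")
        fam = None if _is_blank(row.get("family_id")) else str(row["family_id"])
        subjects[sid] = Subject(sid, str(row["group"]), fam)
        g: dict[str, tuple[AlleleCall, AlleleCall]] = {}
        for s in present_slots:
            v1, v2 = row[f"{s}_1"], row[f"{s}_2"]
            if _is_blank(v1) and _is_blank(v2):
                continue
            if _is_blank(v1) or _is_blank(v2):
                raise CohortIOError(
                    f"{path}: subject {sid}: half-missing pair at {s}"
                )
            try:
                calls = [_parse_cell(str(v1), s), _parse_cell(str(v2), s)]
            except AlleleParseError as e:
                raise CohortIOError(f"{path}: subject {sid}: {e}") from e
            calls = [apply_merge_rules(c, merge_rules) for c in calls]
            calls.sort()
            g[s] = (calls[0], calls[1])
        pairs[sid] = g
    return GenotypeTable(tuple(present_slots), subjects, pairs)


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    """Inverse of :func:`read_genotype_table` (canonical pair order)."""
    cols = ["subject_id", "group", "family_id"]
    for s in table.slots:
        cols += [f"{s}_1", f"{s}_2"]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for sid, sub in table.subjects.items():
            row = [sid, sub.group, sub.family_id or ""]
            g = table.pairs[sid]
            for s in table.slots:
                if s in g:
                    row += [g[s][0].label, g[s][1].label]
                else:
                    row += ["", ""]
            fh.write("\t".join(row) + "\n")


def read_pedigree(path: str | Path) -> list[PedigreeRecord]:
    """Read 6-column PED-like text; validate parent links and acyclicity."""
    records: list[PedigreeRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise CohortIOError(f"{path}:{lineno}: expected 6 columns")
            fam, sid, father, mother, _sex, affected = parts
            if sid in (father, mother):
                raise CohortIOError(f"{path}:{lineno}: subject {sid} is its own parent")
            records.append(
                PedigreeRecord(
                    family_id=fam,
                    subject_id=sid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    # PED convention: 2 = affected, 1 = unaffected, 0 = unknown
                    affected=(affected == "2"),
                )
            )
    by_family: dict[str, dict[str, PedigreeRecord]] = {}
    for r in records:
        by_family.setdefault(r.family_id, {})[r.subject_id] = r
    for fam, members in by_family.items():
        for r in members.values():
            for pid in (r.father_id, r.mother_id):
                if pid is not None and pid not in members:
                    raise CohortIOError(
                        f"{path}: family {fam}: parent {pid} of {r.subject_id} "
                        "not in file (use 0 for missing)"
                    )
        # cycle check by walking ancestry
        for r in members.values():
            seen = {r.subject_id}
            frontier = [p for p in (r.father_id, r.mother_id) if p]
            while frontier:
                pid = frontier.pop()
                if pid in seen:
                    raise CohortIOError(
                        f"{path}: family {fam}: cyclic ancestry at {pid}"
                    )
                seen.add(pid)
                rec = members[pid]
                frontier += [p for p in (rec.father_id, rec.mother_id) if p]
    return records


def read_counts(path: str | Path) -> pd.DataFrame:
    """Fixture-mode counts: CSV with category, case_n, control_n columns."""
    df = pd.read_csv(path)
    for col in ("category", "case_n", "control_n"):
        if col not in df.columns:
            raise CohortIOError(f"{path}: missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# result formatting
# ---------------------------------------------------------------------------


def format_p(p: float | None) -> str:
    """Scientific notation, 3 significant digits: 8.24E-15."""
    return "" if p is None else f"{p:.2E}"


def format_or(v: float | None) -> str:
    return "" if v is None else f"{v:.2f}"


def _pct(n: int, denom: int) -> str:
    return f"{100.0 * n / denom:.1f}"


def write_association_table(
    results: Sequence[AssociationResult],
    path: str | Path,
    p_grid: Mapping[str, Sequence[float | None]] | None = None,
) -> None:
    """CSV mirroring the printed layout: counts (%), OR (CI), p per round.

    Row order is descending case frequency, ties by category label.  Floats
    follow the printed precision: percentages to 1 decimal, ORs and CI bounds
    to 2 decimals, p-values as 3-significant-digit scientific notation.
    """
    n_rounds = max((len(v) for v in (p_grid or {}).values()), default=0)
    header = [
        "category",
        "case_n",
        "case_pct",
        "control_n",
        "control_pct",
        "or",
        "ci_low",
        "ci_high",
        "p",
        "test_used",
    ] + [f"p_round{i + 2}" for i in range(max(0, n_rounds - 1))]
    ordered = sorted(results, key=lambda r: (-r.table.a, r.category))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        for r in ordered:
            row = [
                r.category,
                r.table.a,
                _pct(r.table.a, r.table.case_total),
                r.table.c,
                _pct(r.table.c, r.table.control_total),
                format_or(r.or_),
                format_or(r.ci_low),
                format_or(r.ci_high),
                format_p(r.p),
                r.test_used,
            ]
            if p_grid is not None:
                rounds = list(p_grid.get(r.category, []))
                rounds += [None] * (n_rounds - len(rounds))
                row += [format_p(p) for p in rounds[1:]]
            w.writerow(row)


def write_haplotype_table(
    assignments: Sequence[PhasedSubject], path: str | Path
) -> None:
    """Phased output TSV: subject, both haplotype labels, provenance."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("subject_id\thap1\thap2\tprovenance\tambiguity_count\n")
        for ps in assignments:
            fh.write(
                "\t".join(
                    [
                        ps.subject_id,
                        ps.hap1.label if ps.hap1 else "",
                        ps.hap2.label if ps.hap2 else "",
                        ps.provenance,
                        str(ps.ambiguity_count),
                    ]
                )
                + "\n"
            )
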