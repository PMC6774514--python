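"""HLA class II allele nomenclature: parsing, formatting, merging, truncation.

Allele names follow WHO colon-delimited nomenclature, ``LOCUS*FF:FF[:FF[:FF]]``
(e.g. ``DQB1*06:02:01``).  Three extensions used throughout this package:

* ``DRBX*null`` — a non-amplified DRB3/DRB4/DRB5 paralog.  DR haplotypes carry
  at most one of the three paralogous DRB genes; haplotypes carrying none are
  a real, countable category, so the null call is a first-class allele.
* merge groups, ``LOCUS*A//B[//C]`` — one analysis category covering several
  allele names typed at different resolutions (e.g. ``DQA1*03:02//03:03:01``
  groups DQA1*03:02, *03:02:01 and *03:03:01, which cannot be distinguished
  when cohorts were typed at two-field vs three-field resolution).
* optional expression-suffix letters (N, L, S, Q) are carried verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "Locus",
    "AlleleCall",
    "AlleleMergeRule",
    "LOCI",
    "SLOT_ORDER",
    "DEFAULT_MERGE_RULES",
    "AlleleParseError",
    "MergeRuleError",
    "parse_allele",
    "format_allele",
    "apply_merge_rules",
    "truncate_to_resolution",
]


class AlleleParseError(ValueError):
    """Raised when an allele string cannot be interpreted."""


class MergeRuleError(ValueError):
    """Raised for ill-formed or ambiguous merge-rule configurations."""


@dataclass(frozen=True, order=True)
class Locus:
    """One HLA class II locus (or the DRBX placeholder for a null paralog).

    ``rank`` gives chromosomal display order; ``slot`` names the haplotype
    slot the locus occupies — DRB3/DRB4/DRB5 (and DRBX) are mutually
    exclusive paralogs sharing the single ``DRB345`` slot.
    """

    rank: int
    name: str = field(compare=False)
    slot: str = field(compare=False)


# Chromosomal order on 6p21: DRB paralogs, DRB1, DQ, DP.
LOCI: dict[str, Locus] = {
    "DRB3": Locus(0, "DRB3", "DRB345"),
    "DRB4": Locus(1, "DRB4", "DRB345"),
    "DRB5": Locus(2, "DRB5", "DRB345"),
    "DRBX": Locus(3, "DRBX", "DRB345"),
    "DRB1": Locus(4, "DRB1", "DRB1"),
    "DQA1": Locus(5, "DQA1", "DQA1"),
    "DQB1": Locus(6, "DQB1", "DQB1"),
    "DPA1": Locus(7, "DPA1", "DPA1"),
    "DPB1": Locus(8, "DPB1", "DPB1"),
}

#: Haplotype slot display order (Tables are printed DRB345-DRB1-DQA1-DQB1-DP).
SLOT_ORDER: tuple[str, ...] = ("DRB345", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1")

_FIELD_RE = re.compile(r"^(\d{2,4})([NLSQ]?)$")


@dataclass(frozen=True)
class AlleleCall:
    """A single allele call at one locus.

    ``fields`` are the 1–4 numeric nomenclature fields as zero-padded strings.
    ``is_null`` marks a non-amplified DRB3/4/5 slot (empty fields).
    ``merged_members`` is non-empty iff this call is a merge group, in which
    case ``fields`` holds the first member's fields (used only for sorting).
    """

    locus: Locus
    fields: tuple[str, ...] = ()
    is_null: bool = False
    merged_members: tuple["AlleleCall", ...] = ()
    suffix: str = ""

    def __post_init__(self) -> None:
        if self.is_null:
            if self.fields or self.merged_members:
                raise AlleleParseError("null call cannot carry fields or members")
            if self.locus.slot != "DRB345":
                raise AlleleParseError("null calls exist only in the DRB345 slot")
        elif not self.fields and not self.merged_members:
            raise AlleleParseError("non-null call requires at least one field")
        for m in self.merged_members:
            if m.locus.name != self.locus.name:
                raise MergeRuleError("merge group members must share one locus")
        # the label fully determines the call (format/parse round-trips), so
        # caching it and hashing on it is both correct and much faster than
        # recursive dataclass hashing in the phasing hot loops
        object.__setattr__(self, "_label", format_allele(self))
        object.__setattr__(self, "_hash", hash(("AlleleCall", self._label)))

    def __hash__(self) -> int:
        return self._hash

    @property
    def is_merged(self) -> bool:
        return bool(self.merged_members)

    @property
    def label(self) -> str:
        return self._label

    def sort_key(self) -> tuple:
        return (self.locus.rank, self.is_null, self.fields, self.suffix)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    def __lt__(self, other: "AlleleCall") -> bool:
        return self.sort_key() < other.sort_key()


@dataclass(frozen=True)
class AlleleMergeRule:
    """Collapse several allele names at one locus into one analysis category."""

    locus: str
    members: tuple[tuple[str, ...], ...]
    merged_label: str

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise MergeRuleError(f"unknown locus {self.locus!r} in merge rule")
        if len(self.members) < 2:
            raise MergeRuleError("a merge rule needs at least two members")

    def matches(self, allele: AlleleCall) -> bool:
        if allele.locus.name != self.locus or allele.is_null:
            return False
        for member in self.members:
            # exact match, or member is a lower-resolution prefix of the call
            if allele.fields == member or allele.fields[: len(member)] == member:
                return True
        return False

    def merged_call(self) -> AlleleCall:
        # The displayed group label may abbreviate the member list (the
        # published convention), so build the call from merged_label.
        call = parse_allele(self.merged_label)
        if call.locus.name != self.locus or not call.is_merged:
            raise MergeRuleError(
                f"merged_label {self.merged_label!r} is not a merge label "
                f"at locus {self.locus}"
            )
        return call


def _parse_fields(text: str, context: str) -> tuple[tuple[str, ...], str]:
    parts = text.split(":")
    if not 1 <= len(parts) <= 4:
        raise AlleleParseError(f"expected 1-4 fields in {context!r}")
    fields: list[str] = []
    suffix = ""
    for i, part in enumerate(parts):
        m = _FIELD_RE.match(part)
        if not m:
            raise AlleleParseError(f"malformed field {part!r} in {context!r}")
        if m.group(2) and i != len(parts) - 1:
            raise AlleleParseError(f"suffix letter not terminal in {context!r}")
        fields.append(m.group(1))
        suffix = m.group(2)
    return tuple(fields), suffix


def parse_allele(text: str) -> AlleleCall:
    """Parse ``"DQB1*06:02:01"``, ``"DRBX*null"`` or a ``//`` merge label.

    Raises :class:`AlleleParseError` naming the offending text on unknown
    locus tokens, empty fields or malformed separators.
    """
    text = text.strip()
    if "*" not in text:
        raise AlleleParseError(f"missing '*' separator in {text!r}")
    locus_token, _, rest = text.partition("*")
    locus = LOCI.get(locus_token)
    if locus is None:
        raise AlleleParseError(f"unknown locus token {locus_token!r} in {text!r}")
    if rest == "null":
        if locus.slot != "DRB345":
            raise AlleleParseError(f"null call outside DRB345 slot: {text!r}")
        return AlleleCall(locus, is_null=True)
    if not rest:
        raise AlleleParseError(f"empty allele fields in {text!r}")
    if "//" in rest:
        member_fields = []
        for chunk in rest.split("//"):
            if not chunk:
                raise AlleleParseError(f"empty merge member in {text!r}")
            fields, sfx = _parse_fields(chunk, text)
            if sfx:
                raise AlleleParseError(f"suffix inside merge label {text!r}")
            member_fields.append(fields)
        if len(member_fields) < 2:
            raise AlleleParseError(f"merge label with a single member: {text!r}")
        members = tuple(AlleleCall(locus, f) for f in member_fields)
        return AlleleCall(locus, members[0].fields, merged_members=members)
    fields, suffix = _parse_fields(rest, text)
    return AlleleCall(locus, fields, suffix=suffix)


def format_allele(allele: AlleleCall) -> str:
    """Render a call back to text; ``parse_allele(format_allele(x)) == x``."""
    if allele.is_null:
        return f"{allele.locus.name}*null"
    if allele.is_merged:
        body = "//".join(":".join(m.fields) for m in allele.merged_members)
        return f"{allele.locus.name}*{body}"
    return f"{allele.locus.name}*{':'.join(allele.fields)}{allele.suffix}"


def apply_merge_rules(
    allele: AlleleCall, rules: Sequence[AlleleMergeRule]
) -> AlleleCall:
    """Replace ``allele`` by its merge-group category when a rule matches.

    Matching accepts exact fields or a rule member that is a prefix of the
    call (covers cohorts typed at different resolutions).  A call matching
    two rules is a configuration error.  Idempotent: merge groups match the
    rule that produced them and are returned unchanged.
    """
    if allele.is_merged:
        return allele
    hits = [r for r in rules if r.matches(allele)]
    if not hits:
        return allele
    if len(hits) > 1:
        raise MergeRuleError(
            f"allele {allele.label} matches {len(hits)} merge rules"
        )
    return hits[0].merged_call()


def truncate_to_resolution(allele: AlleleCall, n_fields: int) -> AlleleCall:
    """Drop nomenclature fields beyond ``n_fields`` (null calls unchanged)."""
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if allele.is_null or allele.is_merged or len(allele.fields) <= n_fields:
        return allele
    return replace(allele, fields=allele.fields[:n_fields], suffix="")


# The two merge groups created when control batches typed at two-field vs
# three-field resolution were pooled: DQA1*03:02 is indistinguishable from
# DQA1*03:02:01/03:03:01, and DQA1*02:01 from DQA1*02:01:01.
DEFAULT_MERGE_RULES: tuple[AlleleMergeRule, ...] = (
    AlleleMergeRule(
        "DQA1",
        (("03", "02"), ("03", "03", "01")),
        "DQA1*03:02//03:03:01",
    ),
    AlleleMergeRule(
        "DQA1",
        (("02", "01"), ("02", "01", "01")),
        "DQA1*02:01//02:01:01",
    ),
)
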