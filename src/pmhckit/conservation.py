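"""Alignment-based conservation analysis for MHC domain families.

The input is a hand-curated, gapped multi-sequence alignment of MHC domain
sequences (one block per domain class), with per-column canonical positions
including insertion codes.  Three things are computed on it:

* per-domain pairwise percent identity between sequences (matching columns
  over columns where both sequences are non-gap, restricted to the block);
* a rule-based residue-type conservation classifier reproducing the
  evolutionary shading used in comparative MHC alignments: a column is
  labelled *ancestral* when one residue-type is conserved across both the
  a-lineage (I-α1 + β₂-m / IIα) and b-lineage (I-α2 + I-α3 / IIβ) groups,
  *a-lineage*/*b-lineage* when conserved in one and absent from the other,
  class-specific when confined to a single class group, or
  *MHC-characteristic* when conserved across MHC groups but absent from a
  designated outgroup (e.g. the IgSF-consensus tryptophan at position i95);
* support values (fraction of group sequences matching the type), with a
  low-support tier for uncertain calls.

Residue-types are configurable sets of one-letter codes (e.g. {F, Y, W} for
aromatics); X/unknown residues count as mismatch, never as gap.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import AlignIO

__all__ = [
    "Alignment",
    "ResidueTypeSet",
    "LineageGroupConfig",
    "ConservationLabel",
    "DEFAULT_TYPE_SETS",
    "LABEL_PRECEDENCE",
    "read_alignment",
    "pairwise_domain_identity",
    "identity_matrix",
    "classify_column_conservation",
    "classify_alignment",
]

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")
_GAP = "-"

#: Residue-type sets used when a configuration supplies none: singletons for
#: each amino acid plus the similarity groupings used in MHC alignment work.
DEFAULT_TYPE_SETS = [
    *({aa} for aa in sorted(_AA20)),
    {"D", "E"}, {"D", "E", "N", "Q"}, {"N", "Q"}, {"S", "T"},
    {"K", "R"}, {"F", "Y"}, {"F", "Y", "W"}, {"I", "L", "V", "M"},
    {"A", "G"}, {"H", "N"}, {"D", "N"},
]

#: Fixed evaluation order: earlier labels win.  MHC-characteristic (conserved
#: across MHC lineages but absent from the non-MHC outgroup) outranks plain
#: ancestral, which, with an outgroup present, covers generic fold consensus.
LABEL_PRECEDENCE = [
    "mhc-characteristic",
    "ancestral",
    "a-lineage",
    "b-lineage",
    "I-a-specific",
    "IIa-specific",
    "I-b-specific",
    "IIb-specific",
]

#: Fig-style display colours per label (reporting only).
LABEL_COLORS = {
    "ancestral": "black",
    "a-lineage": "dark-blue",
    "b-lineage": "purple",
    "I-a-specific": "light-blue",
    "IIa-specific": "blue",
    "I-b-specific": "pink",
    "IIb-specific": "purple-light",
    "mhc-characteristic": "red",
    "none": "none",
}


@dataclass
class ResidueTypeSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"residue-type set {self.name!r} is empty")
        bad = self.members - _AA20
        if bad:
            raise ValueError(f"residue-type set {self.name!r} has non-standard codes {sorted(bad)}")


@dataclass
class LineageGroupConfig:
    """Sequence-name groups and the group-requirements of each label.

    ``groups`` maps a group name (e.g. "a-lineage", "outgroup") to sequence
    names.  ``label_rules`` maps a label to (required groups, excluded
    groups): the label applies when every required group conserves one
    shared residue-type at or above the support threshold while every
    excluded group stays below it.
    """

    groups: dict[str, set[str]]
    label_rules: dict[str, tuple[tuple[str, ...], tuple[str, ...]]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("no sequence groups defined")
        for label, (req, exc) in self.label_rules.items():
            for g in (*req, *exc):
                if g not in self.groups:
                    raise ValueError(f"label {label!r} references unknown group {g!r}")

    @staticmethod
    def two_lineage(a_members: set[str], b_members: set[str],
                    outgroup: set[str] | None = None) -> "LineageGroupConfig":
        """The standard a/b-lineage setup of comparative MHC alignments."""
        groups = {"a": set(a_members), "b": set(b_members)}
        rules = {
            "ancestral": (("a", "b"), ()),
            "a-lineage": (("a",), ("b",)),
            "b-lineage": (("b",), ("a",)),
        }
        if outgroup:
            groups["outgroup"] = set(outgroup)
            rules["ancestral"] = (("a", "b"), ())
            rules["mhc-characteristic"] = (("a", "b"), ("outgroup",))
        return LineageGroupConfig(groups=groups, label_rules=rules)


@dataclass
class ConservationLabel:
    column: int
    label: str
    support: float           # min over required groups of the best shared type
    residue_type: str | None  # name of the matched residue-type set
    low_confidence: bool = False


@dataclass
class Alignment:
    names: list[str]
    rows: dict[str, str]
    #: per-domain block: domain_class -> (start column, end column) inclusive
    blocks: dict[str, tuple[int, int]] = field(default_factory=dict)
    #: optional canonical label per column, e.g. "pa62b"
    column_positions: dict[int, str] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def column(self, i: int) -> dict[str, str]:
        return {name: self.rows[name][i] for name in self.names}


def read_alignment(text: str, blocks: dict[str, tuple[int, int]] | None = None,
                   column_positions: dict[int, str] | None = None) -> Alignment:
    """Parse a FASTA-with-gaps alignment plus optional block definitions.

    All sequences must have equal length; symbols outside the amino-acid
    alphabet, gap ``-`` and ``X`` are rejected with a listing.
    """
    try:
        msa = AlignIO.read(io.StringIO(text), "fasta")
    except ValueError as exc:
        raise ValueError(f"not a readable gapped-FASTA alignment: {exc}") from exc
    names = [rec.id for rec in msa]
    rows = {rec.id: str(rec.seq).upper() for rec in msa}
    bad: set[str] = set()
    for seq in rows.values():
        bad |= set(seq) - _AA20 - {_GAP, "X"}
    if bad:
        raise ValueError(f"unknown symbols in alignment: {sorted(bad)}")
    aln = Alignment(names=names, rows=rows, blocks=dict(blocks or {}),
                    column_positions=dict(column_positions or {}))
    for domain, (lo, hi) in aln.blocks.items():
        if not 0 <= lo <= hi < aln.n_columns:
            raise ValueError(f"block {domain!r} range ({lo}, {hi}) outside alignment")
    return aln


def pairwise_domain_identity(aln: Alignment, seq_a: str, seq_b: str,
                             domain_class: str | None = None) -> float:
    """Percent identity between two sequences over one domain block.

    identity = 100 x matches / (columns where both are non-gap), restricted
    to the block (whole alignment when ``domain_class`` is None).  ``X``
    counts as mismatch.  Raises when no column is shared.
    """
    for name in (seq_a, seq_b):
        if name not in aln.rows:
            raise KeyError(f"sequence {name!r} not in alignment")
    if domain_class is not None:
        if domain_class not in aln.blocks:
            raise KeyError(f"no block defined for domain {domain_class!r}")
        lo, hi = aln.blocks[domain_class]
    else:
        lo, hi = 0, aln.n_columns - 1
    sa, sb = aln.rows[seq_a], aln.rows[seq_b]
    shared = matches = 0
    for i in range(lo, hi + 1):
        ca, cb = sa[i], sb[i]
        if ca == _GAP or cb == _GAP:
            continue
        shared += 1
        if ca == cb and ca != "X":
            matches += 1
    if shared == 0:
        raise ValueError(
            f"{seq_a} vs {seq_b}: no shared non-gap columns in {domain_class}"
        )
    return 100.0 * matches / shared


def identity_matrix(aln: Alignment, domain_class: str | None = None,
                    names: list[str] | None = None):
    """Symmetric percent-identity matrix (rounded for report) as a dict."""
    names = names or aln.names
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i:]:
            v = 100.0 if a == b else pairwise_domain_identity(aln, a, b, domain_class)
            out[(a, b)] = v
            out[(b, a)] = v
    return out


def _group_support(aln: Alignment, column: int, members: set[str],
                   type_set: ResidueTypeSet) -> float:
    """Fraction of the group's sequences whose residue belongs to the type.

    Gaps count against support; X counts as mismatch."""
    present = [aln.rows[name][column] for name in members if name in aln.rows]
    if not present:
        return 0.0
    hits = sum(1 for c in present if c in type_set.members)
    return hits / len(present)


def classify_column_conservation(
    aln: Alignment, column: int,
    type_sets: list[ResidueTypeSet] | None = None,
    group_config: LineageGroupConfig | None = None,
    support_threshold: float = 0.8,
    low_support_floor: float = 0.5,
) -> ConservationLabel:
    """Label one column by the fixed precedence of conservation patterns.

    A label applies when some residue-type reaches ``support_threshold`` in
    every required group while staying below it in every excluded group.
    Support in [``low_support_floor``, threshold) in the required groups
    yields the same label flagged low-confidence (the small-font tier).
    """
    if group_config is None:
        raise ValueError("a LineageGroupConfig is required")
    if not 0 <= column < aln.n_columns:
        raise IndexError(f"column {column} outside alignment")
    sets = [ts if isinstance(ts, ResidueTypeSet) else ResidueTypeSet(str(sorted(ts)), ts)
            for ts in (type_sets or DEFAULT_TYPE_SETS)]

    def evaluate(threshold: float) -> ConservationLabel | None:
        for label in LABEL_PRECEDENCE:
            if label not in group_config.label_rules:
                continue
            required, excluded = group_config.label_rules[label]
            best: tuple[float, str] | None = None
            for ts in sets:
                support = min(
                    _group_support(aln, column, group_config.groups[g], ts)
                    for g in required
                )
                if support < threshold:
                    continue
                if any(
                    _group_support(aln, column, group_config.groups[g], ts)
                    >= threshold
                    for g in excluded
                ):
                    continue
                if best is None or support > best[0]:
                    best = (support, ts.name)
            if best is not None:
                return ConservationLabel(column=column, label=label,
                                         support=best[0], residue_type=best[1])
        return None

    hit = evaluate(support_threshold)
    if hit is not None:
        return hit
    low = evaluate(low_support_floor)
    if low is not None:
        low.low_confidence = True
        return low
    return ConservationLabel(column=column, label="none", support=0.0,
                             residue_type=None)


def classify_alignment(aln: Alignment, **kwargs) -> list[ConservationLabel]:
    """Classify every column; see :func:`classify_column_conservation`."""
    return [classify_column_conservation(aln, i, **kwargs)
            for i in range(aln.n_columns)]
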