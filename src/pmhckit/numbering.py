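"""Unified MHC domain nomenclature and canonical residue numbering.

MHC class I and class II ectodomains are built from four homologous domains.
This package follows the unified naming used in comparative work on the two
classes:

* ``pa`` — I-α1 or II-α1 (first peptide-binding half-domain)
* ``pb`` — I-α2 or II-β1 (second peptide-binding half-domain)
* ``ia`` — β₂-microglobulin or II-α2 (membrane-proximal IgSF domain, a-lineage)
* ``ib`` — I-α3 or II-β2 (membrane-proximal IgSF domain, b-lineage)
* ``pab`` — the pa+pb peptide-binding superdomain (a selector, not a fifth set)

Peptide ligand residues are numbered by groove register P1…P9/PΩ (with P-1,
P-2… for class-II overhang preceding P1).

Canonical positions within each domain come from a hand-curated cross-class
alignment rooted in the classic HLA-A2 α1/β₂-m numbering; because that
numbering carries insertion codes (e.g. p62b) and is uncertain in loop
regions, it is supplied as explicit per-structure configuration rather than
inferred at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structures import Residue, Structure

__all__ = [
    "DOMAIN_CLASSES",
    "CanonicalResidueID",
    "NumberingMap",
    "DomainAssignment",
    "RegionDefinition",
    "NumberingConfigError",
    "build_numbering_map",
    "assign_domains",
]

DOMAIN_CLASSES = ("pa", "pb", "ia", "ib", "peptide")

AuthorKey = tuple[str, int, str | None]


class NumberingConfigError(ValueError):
    """Raised for inconsistent numbering configuration."""


@dataclass(frozen=True)
class CanonicalResidueID:
    """A residue named in the cross-class canonical scheme.

    Non-peptide residues carry (domain_class, position, optional lowercase
    insertion code); peptide residues carry an integer register where
    1 means P1, 9 means P9 and 0/-1/… mean P-1/P-2 overhang positions.
    """

    domain_class: str
    position: int
    icode: str | None = None
    register: int | None = None

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"unknown domain class {self.domain_class!r}")
        if self.domain_class == "peptide":
            if self.register is None:
                raise ValueError("peptide residues must carry a register")
        else:
            if self.register is not None:
                raise ValueError("only peptide residues carry a register")
            if self.position < 1:
                raise ValueError("canonical position must be positive")
        if self.icode is not None and not (self.icode.isalpha() and self.icode.islower()):
            raise ValueError(f"insertion code must be a lowercase letter, got {self.icode!r}")

    @property
    def register_label(self) -> str | None:
        """Human label for peptide residues: 'P1'…'P9', 'P-1' for overhang."""
        if self.register is None:
            return None
        if self.register >= 1:
            return f"P{self.register}"
        return f"P{self.register - 1}"  # register 0 -> P-1, -1 -> P-2, ...

    def __str__(self) -> str:
        if self.domain_class == "peptide":
            return self.register_label or "P?"
        return f"{self.domain_class}{self.position}{self.icode or ''}"


@dataclass
class NumberingMap:
    """Bijection between author residue keys and canonical residue IDs."""

    class_label: str  # "MHC-I" or "MHC-II"
    forward: dict[AuthorKey, CanonicalResidueID] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.class_label not in ("MHC-I", "MHC-II"):
            raise NumberingConfigError(
                f"class_label must be 'MHC-I' or 'MHC-II', got {self.class_label!r}"
            )

    @property
    def inverse(self) -> dict[CanonicalResidueID, AuthorKey]:
        inv = {v: k for k, v in self.forward.items()}
        if len(inv) != len(self.forward):
            raise NumberingConfigError("numbering map is not bijective")
        return inv

    def canonical(self, key: AuthorKey) -> CanonicalResidueID | None:
        return self.forward.get(key)

    def author(self, cid: CanonicalResidueID) -> AuthorKey | None:
        return self.inverse.get(cid)

    def add(self, key: AuthorKey, cid: CanonicalResidueID) -> None:
        if key in self.forward:
            raise NumberingConfigError(f"author residue {key} mapped twice")
        if cid in set(self.forward.values()):
            raise NumberingConfigError(f"canonical position {cid} assigned twice")
        self.forward[key] = cid


@dataclass
class RegionDefinition:
    """A named set of canonical residues (a helix segment, a pocket, a pleat)."""

    name: str
    members: list[CanonicalResidueID]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"region {self.name!r} has no members")
        classes = {m.domain_class for m in self.members if m.domain_class != "peptide"}
        if len(classes) > 1:
            raise ValueError(
                f"region {self.name!r} mixes domain classes {sorted(classes)}"
            )


@dataclass
class DomainAssignment:
    """Disjoint per-domain residue sets for one structure."""

    sets: dict[str, list[Residue]]

    def __getitem__(self, selector: str) -> list[Residue]:
        """Look up a domain set; ``pab`` selects pa ∪ pb."""
        if selector == "pab":
            return self.sets.get("pa", []) + self.sets.get("pb", [])
        if selector not in DOMAIN_CLASSES:
            raise KeyError(f"unknown domain selector {selector!r}")
        return self.sets.get(selector, [])

    def domain_of(self, res: Residue) -> str | None:
        for name, members in self.sets.items():
            if any(m is res for m in members):
                return name
        return None


def build_numbering_map(structure: Structure, config: dict) -> tuple[NumberingMap, list[AuthorKey]]:
    """Build the author ↔ canonical bijection from a per-structure config.

    Config schema (per structure, typically loaded from YAML)::

        class_label: MHC-I
        domains:
          pa: {chain: A, range: [1, 90]}            # canonical = author number
          pb: {chain: A, range: [91, 182], offset: -90}
          ia: {chain: B, range: [1, 99]}
          ib: {chain: A, range: [183, 276], offset: -182}
        peptide: {chain: C, p1: 1}                  # register anchor: author num of P1
        insertions:                                 # optional per-domain icode table
          pb: {"95": [95, "a"]}                     # author 95 -> pb95a

    ``range`` is inclusive on both ends, in author numbering.  ``offset`` maps
    author numbers to canonical positions (canonical = author + offset,
    default 0).  Non-standard peptide residues are mapped by register like
    any other peptide residue; unmapped polymer residues are returned, never
    silently dropped.

    Returns the map and the list of unmapped polymer residue keys.
    """
    class_label = config.get("class_label")
    nmap = NumberingMap(class_label=class_label)

    domains = config.get("domains", {})
    _check_ranges_disjoint(domains)
    insertions = config.get("insertions", {})

    mapped: set[AuthorKey] = set()
    for domain_class, spec in domains.items():
        if domain_class not in ("pa", "pb", "ia", "ib"):
            raise NumberingConfigError(f"unknown domain class {domain_class!r} in config")
        chain = str(spec["chain"])
        ranges = spec.get("ranges") or [spec["range"]]
        offset = int(spec.get("offset", 0))
        icode_table = {str(k): v for k, v in insertions.get(domain_class, {}).items()}
        for lo, hi in ranges:
            for res in structure.chains.get(chain, []):
                if not lo <= res.author_seqnum <= hi:
                    continue
                author_tag = f"{res.author_seqnum}{res.author_icode or ''}"
                if author_tag in icode_table:
                    pos, icode = icode_table[author_tag]
                    cid = CanonicalResidueID(domain_class, int(pos), icode or None)
                elif res.author_icode is not None:
                    # insertion not described by the table: leave unmapped
                    continue
                else:
                    cid = CanonicalResidueID(domain_class, res.author_seqnum + offset)
                nmap.add(res.key, cid)
                mapped.add(res.key)

    pep = config.get("peptide")
    if pep:
        chain = str(pep["chain"])
        p1 = int(pep["p1"])
        for res in structure.chains.get(chain, []):
            register = res.author_seqnum - p1 + 1
            nmap.add(res.key, CanonicalResidueID("peptide", 1, register=register))
            mapped.add(res.key)

    unmapped = [r.key for r in structure.residues() if r.key not in mapped]
    nmap.inverse  # raises if not bijective
    return nmap, unmapped


def _check_ranges_disjoint(domains: dict) -> None:
    seen: dict[tuple[str, int], str] = {}
    for domain_class, spec in domains.items():
        chain = str(spec["chain"])
        ranges = spec.get("ranges") or [spec["range"]]
        for lo, hi in ranges:
            if hi < lo:
                raise NumberingConfigError(
                    f"{domain_class}: empty range [{lo}, {hi}] (inclusive bounds)"
                )
            for num in range(lo, hi + 1):
                key = (chain, num)
                if key in seen:
                    raise NumberingConfigError(
                        f"author residue {chain}{num} claimed by both "
                        f"{seen[key]} and {domain_class}"
                    )
                seen[key] = domain_class


def assign_domains(structure: Structure, nmap: NumberingMap) -> DomainAssignment:
    """Split a structure into the five disjoint canonical domain sets.

    Raises if the map names a residue absent from the structure.
    """
    present = {r.key: r for r in structure.residues()}
    for key in nmap.forward:
        if key not in present:
            raise NumberingConfigError(f"mapped residue {key} absent from structure")
    sets: dict[str, list[Residue]] = {d: [] for d in DOMAIN_CLASSES}
    for key, cid in nmap.forward.items():
        sets[cid.domain_class].append(present[key])
    return DomainAssignment(sets=sets)
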