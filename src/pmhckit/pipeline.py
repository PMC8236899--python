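"""End-to-end orchestration: per-structure analysis and cross-structure
comparison, emitting machine-readable report bundles.

A pipeline configuration (usually a YAML document) lists structure entries
— coordinate files with numbering configs, or synthetic fixtures with
built-in ground truth — plus an optional alignment entry and analysis
thresholds.  ``run_pipeline`` produces one JSON-serialisable bundle with a
section per enabled analysis per structure, cross-structure superposition
fits, conservation tables, and provenance (config hash, package version).
Timestamps live only in provenance, so two runs on identical inputs give
byte-identical analysis sections.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .conservation import (LineageGroupConfig, ResidueTypeSet, classify_alignment,
                           identity_matrix, read_alignment)
from .geometry import knob_insertion, peptide_geometry_report
from .interfaces import (contact_residues, detect_disulfides, interface_summary,
                         peptide_exposed_surface, polar_contacts)
from .numbering import DomainAssignment, NumberingMap, assign_domains, build_numbering_map
from .secondary import (assign_secondary_structure, build_beta_topology,
                        compute_backbone_hbonds, detect_beta_bulges, detect_s2s3_cleft)
from .structures import Structure, parse_structure
from .superpose import superpose_by_domain
from .synthetic import ToyComplexSpec, make_toy_pmhc

__all__ = ["PipelineConfig", "run_pipeline", "analyze_structure", "ConfigError"]

DEFAULT_THRESHOLDS = {
    "contact_cutoff": 4.0,
    "polar_cutoff": 3.5,
    "dsasa_threshold": 0.1,
    "knob_threshold": 0.6,
    "sasa_points": 240,
}


class ConfigError(ValueError):
    """Raised before any computation when a configuration is unusable."""


@dataclass
class PipelineConfig:
    structures: list[dict] = field(default_factory=list)
    alignment: dict | None = None
    thresholds: dict = field(default_factory=dict)
    analyses: dict = field(default_factory=dict)  # name -> bool toggles
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls(
            structures=list(raw.get("structures", [])),
            alignment=raw.get("alignment"),
            thresholds={**DEFAULT_THRESHOLDS, **raw.get("thresholds", {})},
            analyses=raw.get("analyses", {}),
            output_dir=raw.get("output_dir"),
            seed=int(raw.get("seed", 0)),
        )
        for t, v in cfg.thresholds.items():
            if not isinstance(v, (int, float)) or v <= 0:
                raise ConfigError(f"threshold {t!r} must be positive, got {v!r}")
        for entry in cfg.structures:
            if "synthetic" not in entry and not Path(entry.get("path", "")).exists():
                raise ConfigError(f"structure file missing: {entry.get('path')!r}")
        if cfg.alignment and not Path(cfg.alignment.get("path", "")).exists():
            raise ConfigError(f"alignment file missing: {cfg.alignment.get('path')!r}")
        return cfg

    def enabled(self, analysis: str) -> bool:
        return bool(self.analyses.get(analysis, True))

    def canonical_hash(self) -> str:
        blob = json.dumps(
            {"structures": self.structures, "alignment": self.alignment,
             "thresholds": self.thresholds, "analyses": self.analyses,
             "seed": self.seed},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_entry(entry: dict, seed: int) -> tuple[Structure, NumberingMap, object | None]:
    if "synthetic" in entry:
        params = dict(entry["synthetic"])
        kind = params.pop("kind", "toy_pmhc")
        if kind != "toy_pmhc":
            raise ConfigError(f"unknown synthetic kind {kind!r}")
        params.setdefault("seed", seed)
        st, nmap, truth = make_toy_pmhc(ToyComplexSpec(**params))
        st.id = entry.get("id", st.id)
        return st, nmap, truth
    path = Path(entry["path"])
    dialect = entry.get("dialect", "mmcif" if path.suffix in (".cif", ".mmcif") else "pdb")
    st = parse_structure(path.read_text(), dialect=dialect,
                         structure_id=entry.get("id", path.stem))
    if "numbering" not in entry:
        raise ConfigError(f"structure {st.id}: numbering config required")
    nmap, unmapped = build_numbering_map(st, entry["numbering"])
    if unmapped:
        warnings.warn(f"{st.id}: {len(unmapped)} polymer residues unmapped")
    return st, nmap, None


def _key(k) -> str:
    chain, num, icode = k
    return f"{chain}{num}{icode or ''}"


def analyze_structure(structure: Structure, nmap: NumberingMap,
                      thresholds: dict | None = None,
                      analyses: dict | None = None) -> dict:
    """All per-structure sections as one JSON-serialisable dict."""
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    on = analyses or {}

    def enabled(name: str) -> bool:
        return bool(on.get(name, True))

    domains = assign_domains(structure, nmap)
    out: dict = {"id": structure.id, "class_label": nmap.class_label}

    hbonds = compute_backbone_hbonds(structure)
    ss = assign_secondary_structure(hbonds, structure)
    topo = build_beta_topology(hbonds, structure, ss, domains=domains, nmap=nmap)

    if enabled("secondary_structure"):
        out["secondary_structure"] = [
            {"residue": _key(key), "canonical": str(nmap.canonical(key) or ""),
             "state": state}
            for key, state in ss.as_rows()
        ]
    if enabled("topology"):
        out["topology"] = {
            "strands": {label: [_key(k) for k in run]
                        for label, run in sorted(topo.strands.items())},
            "n_ladders": len(topo.ladders),
            "bulges": [
                {"pair": [_key(b.bulge_pair[0]), _key(b.bulge_pair[1])],
                 "opposite": _key(b.opposite_residue),
                 "direction": b.sidechain_direction}
                for b in detect_beta_bulges(topo, structure, domains)
            ],
            "cleft": {
                d: {"present": cs.cleft_present, "last_pair": cs.last_pair}
                for d in ("pa", "pb")
                for cs in [detect_s2s3_cleft(topo, d, nmap)]
            },
        }
    peptide = domains["peptide"]
    pab = domains["pab"]
    if enabled("contacts") and peptide and pab:
        records = contact_residues(peptide, pab + domains["ia"] + domains["ib"],
                                   cutoff=th["contact_cutoff"])
        out["peptide_contacts"] = [
            {"peptide": _key(r.residue_a), "receptor": _key(r.residue_b),
             "min_distance": round(r.min_atom_distance, 3),
             "n_pairs": r.n_atom_pairs_within_cutoff}
            for r in records
        ]
        out["peptide_polar_contacts"] = len(
            polar_contacts(peptide, pab, cutoff=th["polar_cutoff"])
        )
    if enabled("interfaces"):
        out["interfaces"] = {}
        pairs = [("ia", "pab"), ("ib", "pab"), ("ia", "ib")]
        if peptide:
            pairs.append(("peptide", "pab"))
        for a, b in pairs:
            ra, rb = domains[a], domains[b]
            if not ra or not rb:
                continue
            summ = interface_summary(ra, rb, dsasa_threshold=th["dsasa_threshold"],
                                     name_a=a, name_b=b, n_points=th["sasa_points"],
                                     contact_cutoff=th["contact_cutoff"])
            out["interfaces"][f"{a}-{b}"] = {
                "buried_area": round(summ.buried_area, 1),
                "interface_residues_a": [_key(k) for k in summ.interface_residues_a],
                "interface_residues_b": [_key(k) for k in summ.interface_residues_b],
            }
        if peptide and pab:
            out["peptide_exposed_surface"] = round(
                peptide_exposed_surface(
                    peptide, pab + domains["ia"] + domains["ib"],
                    n_points=th["sasa_points"]), 1)
    if enabled("geometry") and peptide:
        rep = peptide_geometry_report(structure, nmap, domains)
        out["peptide_geometry"] = {
            "register_distances": {k: round(v, 2)
                                   for k, v in rep.register_distances.items()},
            "bulge_height": round(rep.bulge_height, 2),
            "orientations": {str(k): v for k, v in sorted(rep.orientations.items())},
            "warnings": rep.warnings,
        }
    if enabled("knob") and domains["ia"] and pab:
        try:
            knob = knob_insertion(structure, nmap, domains,
                                  threshold=th["knob_threshold"],
                                  n_points=th["sasa_points"])
            out["knob"] = {
                "fractional_burial": round(knob.fractional_burial, 3),
                "inserted": knob.inserted,
                "per_residue": {k: round(v, 3) for k, v in knob.per_residue.items()},
            }
        except KeyError:
            out["knob"] = {"error": "knob residues ia56/ia60 not mapped"}
    if enabled("disulfides"):
        out["disulfides"] = [
            [_key(a), _key(b)] for a, b in detect_disulfides(structure)
        ]
    return out


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run every enabled analysis; isolate per-structure failures.

    Returns the report bundle.  A bundle with any recorded error should be
    treated as a failed run (the CLI exits non-zero)."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    bundle: dict = {
        "provenance": {
            "package": f"pmhckit {__version__}",
            "config_hash": config.canonical_hash(),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
        "structures": {},
        "errors": {},
    }
    loaded: dict[str, tuple[Structure, NumberingMap]] = {}
    for entry in config.structures:
        sid = entry.get("id") or entry.get("path", "synthetic")
        try:
            st, nmap, _truth = _load_entry(entry, config.seed)
            loaded[st.id] = (st, nmap)
            bundle["structures"][st.id] = analyze_structure(
                st, nmap, config.thresholds, config.analyses
            )
        except (OSError, ValueError, KeyError) as exc:
            bundle["errors"][str(sid)] = f"{type(exc).__name__}: {exc}"

    if config.enabled("superposition") and len(loaded) >= 2:
        bundle["superpositions"] = {}
        ids = sorted(loaded)
        ref_id = ids[0]
        ref_st, ref_map = loaded[ref_id]
        for other in ids[1:]:
            st, nmap = loaded[other]
            try:
                fit = superpose_by_domain(st, nmap, ref_st, ref_map, selector="pab")
                bundle["superpositions"][f"{other}->{ref_id}"] = {
                    "selector": "pab", "rmsd": round(fit.rmsd, 4),
                    "n_fitted": fit.n_fitted,
                }
            except ValueError as exc:
                bundle["errors"][f"superpose:{other}"] = str(exc)

    if config.alignment:
        try:
            bundle["conservation"] = _alignment_section(config.alignment)
        except (OSError, ValueError, KeyError) as exc:
            bundle["errors"]["alignment"] = f"{type(exc).__name__}: {exc}"

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(bundle_json(bundle))
    return bundle


def _alignment_section(entry: dict) -> dict:
    text = Path(entry["path"]).read_text()
    blocks = {k: tuple(v) for k, v in entry.get("blocks", {}).items()}
    aln = read_alignment(text, blocks=blocks)
    out: dict = {"n_sequences": len(aln.names), "n_columns": aln.n_columns}
    domains = list(blocks) or [None]
    out["identity"] = {}
    for domain in domains:
        mat = identity_matrix(aln, domain)
        out["identity"][domain or "all"] = {
            f"{a}|{b}": round(v) for (a, b), v in sorted(mat.items()) if a <= b
        }
    groups = entry.get("groups")
    if groups:
        gcfg = LineageGroupConfig.two_lineage(
            set(groups.get("a", [])), set(groups.get("b", [])),
            set(groups.get("outgroup", [])) or None,
        )
        type_sets = [ResidueTypeSet(name, frozenset(members))
                     for name, members in entry.get("type_sets", {}).items()] or None
        labels = classify_alignment(
            aln, type_sets=type_sets, group_config=gcfg,
            support_threshold=float(entry.get("support_threshold", 0.8)),
        )
        out["conservation_labels"] = [
            {"column": lab.column, "label": lab.label,
             "support": round(lab.support, 3),
             "low_confidence": lab.low_confidence}
            for lab in labels
        ]
    return out


def bundle_json(bundle: dict) -> str:
    """Canonical JSON for a bundle: timestamps isolated under provenance."""
    return json.dumps(bundle, indent=1, sort_keys=True)
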