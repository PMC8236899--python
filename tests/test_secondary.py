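"""Hydrogen bonds, secondary structure, β-topology and feature detectors."""

import warnings

import numpy as np
import pytest

from pmhckit.secondary import (HydrogenBond, assign_secondary_structure,
                               build_beta_topology, compute_backbone_hbonds,
                               detect_beta_bulges, detect_s2s3_cleft,
                               kabsch_sander_energy)
from pmhckit.structures import Atom, Residue, Structure, parse_structure, write_pdb
from pmhckit.synthetic import (HelixSpec, SheetSpec, make_beta_sheet,
                               make_ideal_helix)

from conftest import random_rigid_transform


def hbond_set(bonds):
    return {(b.donor, b.acceptor) for b in bonds}


class TestHydrogenBonds:
    def test_distant_residues_have_no_bond(self):
        # 1/r terms vanish at 50 Å separation
        def residue(chain, num, shift):
            return Residue(chain, num, None, "ALA", atoms=[
                Atom("N", "N", np.array([0.0, 0, 0]) + shift),
                Atom("CA", "C", np.array([1.5, 0, 0]) + shift),
                Atom("C", "C", np.array([2.1, 1.4, 0]) + shift),
                Atom("O", "O", np.array([2.1, 2.6, 0]) + shift),
            ])
        st = Structure(id="two", chains={
            "A": [residue("A", 1, np.zeros(3)), residue("A", 2, np.array([3.8, 0, 0.0]))],
            "B": [residue("B", 1, np.array([50.0, 0, 0])),
                  residue("B", 2, np.array([53.8, 0, 0]))],
        })
        bonds = compute_backbone_hbonds(st)
        assert not any(b.donor[0] != b.acceptor[0] for b in bonds)
        e = kabsch_sander_energy(st.chains["B"][1], st.chains["A"][0],
                                 donor_h=st.chains["B"][1].coord("N"))
        assert abs(e) < 0.1

    @pytest.mark.parametrize("kind,offset", [("alpha", 4), ("310", 3), ("pi", 5)])
    def test_ideal_helix_bond_pattern(self, kind, offset):
        st = make_ideal_helix(HelixSpec(n_residues=12, kind=kind))
        bonds = compute_backbone_hbonds(st)
        seps = {b.donor[1] - b.acceptor[1] for b in bonds}
        assert seps == {offset}

    def test_prefilter_is_lossless(self):
        # accepted set equals a no-prefilter exhaustive scan
        for fixture in (
            make_ideal_helix(HelixSpec(n_residues=12, kind="alpha")),
            make_beta_sheet(SheetSpec(n_strands=2, strand_length=8))[0],
            make_beta_sheet(SheetSpec(n_strands=4, strand_length=9))[0],
        ):
            fast = hbond_set(compute_backbone_hbonds(fixture, use_prefilter=True))
            brute = hbond_set(compute_backbone_hbonds(fixture, use_prefilter=False))
            assert fast == brute

    def test_energy_invariant_under_rigid_transform(self):
        st, _ = make_beta_sheet(SheetSpec(n_strands=2, strand_length=8))
        ref = {(b.donor, b.acceptor): b.energy for b in compute_backbone_hbonds(st)}
        rng = np.random.default_rng(7)
        for _ in range(5):
            Q, t = random_rigid_transform(rng)
            moved = st.transformed(Q, t)
            got = {(b.donor, b.acceptor): b.energy
                   for b in compute_backbone_hbonds(moved)}
            assert set(got) == set(ref)
            for key in ref:
                assert got[key] == pytest.approx(ref[key], abs=1e-9)

    def test_donor_equals_acceptor_rejected(self):
        with pytest.raises(ValueError):
            HydrogenBond(donor=("A", 1, None), acceptor=("A", 1, None), energy=-1.0)


class TestSecondaryStructureAssignment:
    @pytest.mark.parametrize("kind,state", [("alpha", "alpha"), ("310", "310"),
                                            ("pi", "pi")])
    def test_ideal_helices_interior(self, kind, state):
        st = make_ideal_helix(HelixSpec(n_residues=12, kind=kind))
        ss = assign_secondary_structure(compute_backbone_hbonds(st), st)
        interior = [s for _, s in ss.as_rows()][2:-2]
        assert all(s == state for s in interior)

    def test_sheet_interior_is_strand(self):
        st, _ = make_beta_sheet(SheetSpec(n_strands=2, strand_length=8))
        ss = assign_secondary_structure(compute_backbone_hbonds(st), st)
        states = dict(ss.as_rows())
        for chain in ("A", "B"):
            for num in range(3, 7):
                assert states[(chain, num, None)] == "strand"

    @pytest.mark.parametrize("kind,code", [("alpha", "H"), ("310", "G"), ("pi", "I")])
    def test_matches_reference_dssp_on_helices(self, kind, code, tmp_path):
        # oracle: an independent DSSP implementation on the same fixture
        mdtraj = pytest.importorskip("mdtraj")
        st = make_ideal_helix(HelixSpec(n_residues=12, kind=kind))
        pdb = tmp_path / "helix.pdb"
        pdb.write_text(write_pdb(st))
        ref = mdtraj.compute_dssp(mdtraj.load(str(pdb)), simplified=False)[0]
        ss = assign_secondary_structure(compute_backbone_hbonds(st), st)
        mine = {"alpha": "H", "310": "G", "pi": "I", "strand": "E"}
        for (key, state), ref_code in zip(ss.as_rows(), ref):
            if ref_code in ("H", "G", "I", "E"):
                assert mine.get(state) == ref_code

    def test_matches_reference_dssp_on_sheet(self, tmp_path):
        mdtraj = pytest.importorskip("mdtraj")
        st, _ = make_beta_sheet(SheetSpec(n_strands=2, strand_length=8))
        pdb = tmp_path / "sheet.pdb"
        pdb.write_text(write_pdb(st))
        ref = mdtraj.compute_dssp(mdtraj.load(str(pdb)), simplified=False)[0]
        ss = assign_secondary_structure(compute_backbone_hbonds(st), st)
        for (key, state), ref_code in zip(ss.as_rows(), ref):
            if ref_code == "E":
                assert state == "strand"


class TestBetaTopology:
    def test_ladder_pairs_match_construction(self):
        # interior template rungs must all be recovered; every reported rung
        # must be a template rung (two-sided containment against the
        # exhaustive construction oracle)
        rng = np.random.default_rng(3)
        for _ in range(10):
            L = int(rng.integers(5, 11))
            st, truth = make_beta_sheet(SheetSpec(n_strands=2, strand_length=L))
            topo = build_beta_topology(compute_backbone_hbonds(st), st)
            got = {((a[0], a[1]), (b[0], b[1])) for a, b, s in topo.bridges
                   if s == "antiparallel"}
            interior = set(map(tuple, truth.interior_pairs))
            full = set(map(tuple, truth.paired_positions))
            assert interior <= got <= full

    def test_helix_has_no_ladders(self):
        st = make_ideal_helix(HelixSpec(n_residues=12, kind="alpha"))
        topo = build_beta_topology(compute_backbone_hbonds(st), st)
        assert topo.ladders == []

    def test_toy_floor_has_eight_labelled_strands(self, toy_class_i_analysis):
        *_, topo = toy_class_i_analysis
        labels = {lab for lab in topo.strands if lab.startswith(("pa:", "pb:"))}
        assert labels == {f"{d}:S{k}" for d in ("pa", "pb") for k in range(1, 5)}

    def test_ladder_rungs_supported_by_hbonds(self):
        st, _ = make_beta_sheet(SheetSpec(n_strands=4, strand_length=9))
        hbonds = compute_backbone_hbonds(st)
        bond_res = {frozenset((b.donor, b.acceptor)) for b in hbonds}
        topo = build_beta_topology(hbonds, st)
        for ladder in topo.ladders:
            assert len(ladder.paired_positions) >= 2
            near = 0
            for a, b in ladder.paired_positions:
                neighbours = {
                    frozenset(((a[0], a[1] + da, None), (b[0], b[1] + db, None)))
                    for da in (-1, 0, 1) for db in (-1, 0, 1)
                }
                if neighbours & bond_res:
                    near += 1
            assert near == len(ladder.paired_positions)


class TestBulgeDetector:
    def test_regular_sheet_has_no_bulges(self):
        st, _ = make_beta_sheet(SheetSpec(n_strands=4, strand_length=9))
        topo = build_beta_topology(compute_backbone_hbonds(st), st)
        assert detect_beta_bulges(topo, st) == []

    def test_engineered_bulge_found_exactly(self):
        st, truth = make_beta_sheet(SheetSpec(n_strands=2, strand_length=9,
                                              bulge_at=(0, 4)))
        topo = build_beta_topology(compute_backbone_hbonds(st), st)
        bulges = detect_beta_bulges(topo, st)
        assert len(bulges) == 1
        pair = tuple(k[:2] for k in bulges[0].bulge_pair)
        assert truth.bulge_inserted in pair
        assert all(p in truth.bulge_window for p in pair)
        assert bulges[0].opposite_residue[:2] in truth.bulge_opposite_window

    def test_randomized_bulge_placements(self):
        # exact localisation and nothing-else on randomized engineered sheets
        rng = np.random.default_rng(11)
        n_ok = 0
        trials = 40
        for _ in range(trials):
            L = int(rng.integers(6, 13))
            strand = int(rng.integers(0, 2))
            probe = SheetSpec(n_strands=2, strand_length=L)
            lo, hi = probe.valid_bulge_slots()
            k = int(rng.integers(lo, hi + 1))
            st, truth = make_beta_sheet(SheetSpec(n_strands=2, strand_length=L,
                                                  bulge_at=(strand, k)))
            topo = build_beta_topology(compute_backbone_hbonds(st), st)
            bulges = detect_beta_bulges(topo, st)
            if len(bulges) != 1:
                continue
            pair = tuple(x[:2] for x in bulges[0].bulge_pair)
            if (truth.bulge_inserted in pair
                    and all(p in truth.bulge_window for p in pair)
                    and bulges[0].opposite_residue[:2] in truth.bulge_opposite_window):
                n_ok += 1
        assert n_ok == trials

    def test_direction_up_with_helix_reference(self):
        # a helix placed on the +z side fixes the groove frame: the
        # engineered all-up bulge sidechains must read "up"
        st, truth = make_beta_sheet(SheetSpec(n_strands=2, strand_length=9,
                                              bulge_at=(0, 4)))
        helix = make_ideal_helix(HelixSpec(n_residues=10, kind="alpha"))
        shifted = helix.transformed(np.eye(3), np.array([0.0, 2.4, 8.0]))
        st.chains["H"] = [
            Residue("H", r.author_seqnum, None, r.resname,
                    [Atom(a.name, a.element, a.coords.copy()) for a in r.atoms])
            for r in shifted.chains["A"]
        ]
        topo = build_beta_topology(compute_backbone_hbonds(st), st)
        bulges = detect_beta_bulges(topo, st)
        assert len(bulges) == 1
        assert bulges[0].sidechain_direction == "up"


class TestCleftDetector:
    def test_toy_class_i_cleft_in_pb_only(self, toy_class_i_analysis):
        st, nmap, truth, domains, hbonds, ss, topo = toy_class_i_analysis
        assert truth.cleft_domain == "pb"
        assert detect_s2s3_cleft(topo, "pb", nmap).cleft_present is True
        assert detect_s2s3_cleft(topo, "pb", nmap).last_pair == (24, 36)
        assert detect_s2s3_cleft(topo, "pa", nmap).cleft_present is False

    def test_toy_class_ii_cleft_in_pa_only(self, toy_class_ii_analysis):
        st, nmap, truth, domains, hbonds, ss, topo = toy_class_ii_analysis
        assert truth.cleft_domain == "pa"
        assert detect_s2s3_cleft(topo, "pa", nmap).cleft_present is True
        assert detect_s2s3_cleft(topo, "pb", nmap).cleft_present is False
        assert detect_s2s3_cleft(topo, "pb", nmap).last_pair == (22, 38)

    def test_missing_strands_give_undetermined(self):
        st = make_ideal_helix(HelixSpec(n_residues=12, kind="alpha"))
        cfg = {"class_label": "MHC-I",
               "domains": {"pa": {"chain": "A", "range": [1, 12]}}}
        from pmhckit.numbering import build_numbering_map
        nmap, _ = build_numbering_map(st, cfg)
        topo = build_beta_topology(compute_backbone_hbonds(st), st, nmap=nmap)
        status = detect_s2s3_cleft(topo, "pa", nmap)
        assert status.cleft_present is None

    def test_non_p_domain_rejected(self, toy_class_i_analysis):
        st, nmap, *_ , topo = toy_class_i_analysis
        with pytest.raises(ValueError):
            detect_s2s3_cleft(topo, "ia", nmap)
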