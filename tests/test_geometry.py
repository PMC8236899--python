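"""Distances, dihedrals, peptide-register geometry and knob insertion."""

import numpy as np
import pytest

from pmhckit.geometry import (knob_insertion, measure_dihedral, measure_distance,
                              peptide_geometry_report, phi_psi)
from pmhckit.numbering import CanonicalResidueID, NumberingMap, assign_domains
from pmhckit.structures import Atom, Residue, Structure
from pmhckit.synthetic import (HELIX_DIHEDRALS, HelixSpec, ToyComplexSpec,
                               make_ideal_helix, make_toy_pmhc)

from conftest import random_rigid_transform


def peptide_structure(ca_positions, cb_offsets=None):
    """Minimal registered peptide with CA (and optional CB) atoms only."""
    st = Structure(id="pep")
    nmap = NumberingMap(class_label="MHC-I")
    st.chains["C"] = []
    for i, ca in enumerate(ca_positions):
        atoms = [Atom("N", "N", np.asarray(ca) + [-0.5, 0.8, 0]),
                 Atom("CA", "C", np.asarray(ca, float)),
                 Atom("C", "C", np.asarray(ca) + [0.6, 0.9, 0])]
        if cb_offsets is not None:
            atoms.append(Atom("CB", "C", np.asarray(ca) + cb_offsets[i]))
        st.chains["C"].append(Residue("C", i + 1, None, "ALA", atoms=atoms))
        nmap.add(("C", i + 1, None),
                 CanonicalResidueID("peptide", 1, register=i + 1))
    return st, nmap


class TestDistances:
    def test_self_distance_zero(self, toy_class_i):
        st, nmap, _ = toy_class_i
        p1 = CanonicalResidueID("peptide", 1, register=1)
        assert measure_distance(st, nmap, p1, p1).value == 0.0

    def test_toy_span_matches_construction(self, toy_class_i):
        st, nmap, truth = toy_class_i
        p1 = CanonicalResidueID("peptide", 1, register=1)
        p9 = CanonicalResidueID("peptide", 1, register=9)
        d = measure_distance(st, nmap, p1, p9)
        assert d.value == pytest.approx(truth.peptide_span, abs=1e-9)

    def test_triangle_inequality(self, toy_class_i):
        st, nmap, _ = toy_class_i
        regs = [CanonicalResidueID("peptide", 1, register=r) for r in (1, 5, 9)]
        d = lambda a, b: measure_distance(st, nmap, a, b).value
        assert d(regs[0], regs[2]) <= d(regs[0], regs[1]) + d(regs[1], regs[2]) + 1e-12

    def test_missing_atom_error_names_residue(self, toy_class_i):
        st, nmap, _ = toy_class_i
        p1 = CanonicalResidueID("peptide", 1, register=1)
        with pytest.raises(ValueError, match="OXT"):
            measure_distance(st, nmap, p1, p1, atom="OXT")


class TestDihedrals:
    def test_planar_cis_and_trans(self):
        p = [np.array([0.0, 1, 0]), np.array([0.0, 0, 0]), np.array([1.0, 0, 0])]
        cis = measure_dihedral(*p, np.array([1.0, 1, 0]))
        trans = measure_dihedral(*p, np.array([1.0, -1, 0]))
        assert cis.value == pytest.approx(0.0, abs=1e-9)
        assert abs(trans.value) == pytest.approx(180.0, abs=1e-9)

    def test_sign_convention_right_handed(self):
        p = [np.array([0.0, 1, 0]), np.array([0.0, 0, 0]), np.array([1.0, 0, 0])]
        up = measure_dihedral(*p, np.array([1.0, 0.5, 0.5]))
        down = measure_dihedral(*p, np.array([1.0, 0.5, -0.5]))
        assert up.value == pytest.approx(-down.value, abs=1e-9)

    @pytest.mark.parametrize("kind", ["alpha", "310", "pi"])
    def test_helix_generator_parameters_recovered(self, kind):
        st = make_ideal_helix(HelixSpec(n_residues=12, kind=kind))
        phi0, psi0 = HELIX_DIHEDRALS[kind]
        angles = phi_psi(st, "A")
        for key, (phi, psi) in list(angles.items())[2:-2]:
            assert phi == pytest.approx(phi0, abs=0.1)
            assert psi == pytest.approx(psi0, abs=0.1)

    def test_matches_independent_formula(self):
        # dual-formula oracle: projection-based arctan construction
        def oracle(p0, p1, p2, p3):
            b0 = p0 - p1
            b1 = p2 - p1
            b1 = b1 / np.linalg.norm(b1)
            b2 = p3 - p2
            v = b0 - (b0 @ b1) * b1
            w = b2 - (b2 @ b1) * b1
            x = v @ w
            y = np.cross(b1, v) @ w
            return np.rad2deg(np.arctan2(y, x))

        rng = np.random.default_rng(0)
        for _ in range(100):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                mine = measure_dihedral(*pts).value
            except ValueError:
                continue
            assert mine == pytest.approx(oracle(*pts), abs=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            measure_dihedral(np.zeros(3), np.array([1.0, 0, 0]),
                             np.array([2.0, 0, 0]), np.array([3.0, 1, 0]))


class TestPeptideGeometry:
    def test_straight_peptide_zero_bulge(self):
        cas = [[3.3 * i, 0, 0] for i in range(9)]
        st, nmap = peptide_structure(cas)
        rep = peptide_geometry_report(st, nmap)
        assert rep.bulge_height == pytest.approx(0.0, abs=1e-9)

    def test_displaced_ca_sets_bulge_height(self):
        cas = [[3.3 * i, 0, 0] for i in range(9)]
        cas[4] = [3.3 * 4, 0, 2.0]
        st, nmap = peptide_structure(cas)
        rep = peptide_geometry_report(st, nmap)
        assert rep.bulge_height == pytest.approx(2.0, abs=1e-9)

    def test_register_distances_straight_chain_closed_form(self):
        step = 3.3
        cas = [[step * i, 0, 0] for i in range(9)]
        st, nmap = peptide_structure(cas)
        rep = peptide_geometry_report(st, nmap)
        assert rep.register_distances["P1-P9"] == pytest.approx(8 * step)
        assert rep.register_distances["P2-P9"] == pytest.approx(7 * step)

    def test_toy_orientations_match_engineering(self, toy_class_i_analysis,
                                                toy_class_ii_analysis):
        for bundle in (toy_class_i_analysis, toy_class_ii_analysis):
            st, nmap, truth, domains, *_ = bundle
            rep = peptide_geometry_report(st, nmap, domains)
            for reg, want in truth.expected_orientations.items():
                assert rep.orientations[reg] == want

    def test_class_i_span_shorter_than_class_ii(self, toy_class_i_analysis,
                                                toy_class_ii_analysis):
        # the non-relaxed class I binding mode arcs the 9-mer core, so its
        # P1-P9 span contracts relative to the extended class II mode
        rep_i = peptide_geometry_report(*toy_class_i_analysis[:2],
                                        toy_class_i_analysis[3])
        rep_ii = peptide_geometry_report(*toy_class_ii_analysis[:2],
                                         toy_class_ii_analysis[3])
        assert rep_i.register_distances["P1-P9"] < rep_ii.register_distances["P1-P9"]
        assert rep_i.bulge_height > rep_ii.bulge_height

    def test_missing_register_partial_report(self):
        cas = [[3.3 * i, 0, 0] for i in range(4)]  # no P9
        st, nmap = peptide_structure(cas)
        rep = peptide_geometry_report(st, nmap)
        assert "P1-P9" not in rep.register_distances
        assert rep.warnings

    def test_rigid_invariance(self, toy_class_i):
        st, nmap, _ = toy_class_i
        domains = assign_domains(st, nmap)
        ref = peptide_geometry_report(st, nmap, domains)
        rng = np.random.default_rng(5)
        Q, t = random_rigid_transform(rng)
        moved = st.transformed(Q, t)
        domains2 = assign_domains(moved, nmap)
        rep = peptide_geometry_report(moved, nmap, domains2)
        for k, v in ref.register_distances.items():
            assert rep.register_distances[k] == pytest.approx(v, abs=1e-9)
        assert rep.bulge_height == pytest.approx(ref.bulge_height, abs=1e-9)
        assert rep.orientations == ref.orientations


class TestKnobInsertion:
    def test_toy_class_i_inserted(self, toy_class_i_analysis):
        st, nmap, truth, domains, *_ = toy_class_i_analysis
        out = knob_insertion(st, nmap, domains, n_points=240)
        assert out.inserted is truth.knob_inserted is True
        assert out.fractional_burial > 0.6

    def test_toy_class_ii_not_inserted(self, toy_class_ii_analysis):
        st, nmap, truth, domains, *_ = toy_class_ii_analysis
        out = knob_insertion(st, nmap, domains, n_points=240)
        assert out.inserted is truth.knob_inserted is False
        assert out.fractional_burial < 0.6

    def test_translated_away_burial_zero(self, toy_class_i):
        st, nmap, _ = toy_class_i
        moved = Structure(id=st.id, chains=dict(st.chains))
        far = [
            Residue(r.author_chain, r.author_seqnum, r.author_icode, r.resname,
                    [Atom(a.name, a.element, a.coords + np.array([0.0, 0, -50.0]))
                     for a in r.atoms])
            for r in st.chains["B"]
        ]
        moved.chains = {**st.chains, "B": far}
        domains = assign_domains(moved, nmap)
        out = knob_insertion(moved, nmap, domains, n_points=240)
        assert out.fractional_burial == pytest.approx(0.0, abs=1e-6)
        assert out.inserted is False

    def test_burial_monotone_under_retraction(self, toy_class_i):
        # pulling the ia domain away along -z never increases burial
        st, nmap, _ = toy_class_i
        burials = []
        for dz in (0.0, 2.0, 4.0, 8.0, 16.0):
            moved = Structure(id=st.id, chains=dict(st.chains))
            moved.chains["B"] = [
                Residue(r.author_chain, r.author_seqnum, r.author_icode, r.resname,
                        [Atom(a.name, a.element, a.coords + np.array([0.0, 0, -dz]))
                         for a in r.atoms])
                for r in st.chains["B"]
            ]
            domains = assign_domains(moved, nmap)
            out = knob_insertion(moved, nmap, domains, n_points=240)
            burials.append(out.fractional_burial)
        assert all(b1 >= b2 - 1e-6 for b1, b2 in zip(burials, burials[1:]))

    def test_glycine_knob_reported_undefined(self, toy_class_i):
        st, nmap, _ = toy_class_i
        stripped = Structure(id=st.id, chains=dict(st.chains))
        stripped.chains["B"] = [
            Residue(r.author_chain, r.author_seqnum, r.author_icode, "GLY",
                    [Atom(a.name, a.element, a.coords.copy())
                     for a in r.atoms if a.name in ("N", "CA", "C", "O")])
            for r in st.chains["B"]
        ]
        domains = assign_domains(stripped, nmap)
        with pytest.warns(UserWarning, match="burial undefined"):
            out = knob_insertion(stripped, nmap, domains, n_points=240)
        assert np.isnan(out.fractional_burial)
        assert out.inserted is False
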