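"""Contacts, polar contacts, disulfides, SASA and interface summaries."""

import numpy as np
import pytest

from pmhckit.interfaces import (VDW_RADII, compute_sasa, contact_residues,
                                detect_disulfides, interface_summary,
                                peptide_exposed_surface, polar_contacts)
from pmhckit.numbering import assign_domains
from pmhckit.structures import Atom, Residue, Structure

from conftest import random_rigid_transform


def single_atom_residue(chain, num, name, element, xyz, resname="ALA"):
    return Residue(chain, num, None, resname,
                   atoms=[Atom(name, element, np.asarray(xyz, float))])


class TestContacts:
    def test_cutoff_definition(self):
        a = [single_atom_residue("A", 1, "CA", "C", [0, 0, 0])]
        b39 = [single_atom_residue("B", 1, "CA", "C", [3.9, 0, 0])]
        b41 = [single_atom_residue("B", 1, "CA", "C", [4.1, 0, 0])]
        assert len(contact_residues(a, b39)) == 1
        assert len(contact_residues(a, b41)) == 0

    def test_zero_cutoff_gives_empty(self):
        a = [single_atom_residue("A", 1, "CA", "C", [0, 0, 0])]
        b = [single_atom_residue("B", 1, "CA", "C", [1.0, 0, 0])]
        assert contact_residues(a, b, cutoff=0.0) == []

    def test_overlapping_groups_rejected(self):
        a = [single_atom_residue("A", 1, "CA", "C", [0, 0, 0])]
        with pytest.raises(ValueError):
            contact_residues(a, a)

    def test_toy_groove_matches_bruteforce_oracle(self, toy_class_ii_analysis):
        st, nmap, truth, domains, *_ = toy_class_ii_analysis
        peptide = domains["peptide"]
        rest = domains["pab"] + domains["ia"] + domains["ib"]
        got = {(r.residue_a, r.residue_b) for r in contact_residues(peptide, rest)}
        assert got == truth.contacts

    def test_random_fixture_bruteforce_equivalence(self):
        # kd-tree contact search equals an O(n^2) scan on random clouds
        rng = np.random.default_rng(0)
        for trial in range(10):
            ga = [single_atom_residue("A", i + 1, "CA", "C",
                                      rng.uniform(0, 15, 3)) for i in range(25)]
            gb = [single_atom_residue("B", i + 1, "CA", "C",
                                      rng.uniform(0, 15, 3)) for i in range(25)]
            got = {(r.residue_a, r.residue_b) for r in contact_residues(ga, gb)}
            brute = set()
            for ra in ga:
                for rb in gb:
                    d = np.linalg.norm(ra.atoms[0].coords - rb.atoms[0].coords)
                    if d <= 4.0:
                        brute.add((ra.key, rb.key))
            assert got == brute

    def test_contact_set_monotone_in_cutoff(self, toy_class_ii_analysis):
        st, nmap, truth, domains, *_ = toy_class_ii_analysis
        peptide, rest = domains["peptide"], domains["pab"]
        prev = set()
        for cutoff in (3.0, 3.5, 4.0, 4.5, 5.0):
            cur = {(r.residue_a, r.residue_b)
                   for r in contact_residues(peptide, rest, cutoff=cutoff)}
            assert prev <= cur
            prev = cur


class TestPolarContacts:
    def test_polarity_filter(self):
        o = [single_atom_residue("A", 1, "O", "O", [0, 0, 0])]
        n = [single_atom_residue("B", 1, "N", "N", [2.9, 0, 0])]
        cb = [single_atom_residue("B", 2, "CB", "C", [2.9, 0, 0])]
        assert len(polar_contacts(o, n)) == 1
        assert len(polar_contacts(o, cb)) == 0

    def test_water_mediated_contact(self):
        a = [single_atom_residue("A", 1, "O", "O", [0, 0, 0])]
        b = [single_atom_residue("B", 1, "N", "N", [5.6, 0, 0])]
        water = [single_atom_residue("W", 100, "O", "O", [2.8, 0, 0], resname="HOH")]
        out = polar_contacts(a, b, waters=water)
        assert any(c.water_mediated for c in out)
        assert not polar_contacts(a, b)

    def test_polar_contacts_subset_of_contact_atoms(self, toy_class_i_analysis):
        st, nmap, truth, domains, *_ = toy_class_i_analysis
        peptide, pab = domains["peptide"], domains["pab"]
        polar = polar_contacts(peptide, pab)
        contact_pairs = {(r.residue_a, r.residue_b)
                         for r in contact_residues(peptide, pab)}
        for pc in polar:
            assert (pc.atom_a[0], pc.atom_b[0]) in contact_pairs


class TestDisulfides:
    def make_cys_pair(self, d):
        st = Structure(id="ss", chains={"A": [
            Residue("A", 1, None, "CYS", atoms=[Atom("SG", "S", np.zeros(3))]),
            Residue("A", 2, None, "CYS", atoms=[Atom("SG", "S", np.array([d, 0, 0]))]),
        ]})
        return st

    def test_canonical_bond_length_found(self):
        assert len(detect_disulfides(self.make_cys_pair(2.05))) == 1

    def test_distant_cysteines_not_bonded(self):
        assert detect_disulfides(self.make_cys_pair(4.0)) == []


class TestSasa:
    def test_isolated_atom_closed_form(self):
        # 4 pi (r + probe)^2 for a lone carbon
        res = [single_atom_residue("A", 1, "CA", "C", [0, 0, 0])]
        out = compute_sasa(res, probe=1.4, n_points=960)
        expected = 4 * np.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert out.total == pytest.approx(expected, rel=0.005)

    def test_fully_caged_atom_is_zero(self):
        centre = [single_atom_residue("A", 1, "CA", "C", [0, 0, 0])]
        cage = []
        k = 0
        for dx in (-2.0, 0, 2.0):
            for dy in (-2.0, 0, 2.0):
                for dz in (-2.0, 0, 2.0):
                    if dx == dy == dz == 0:
                        continue
                    k += 1
                    cage.append(single_atom_residue("B", k, "CA", "C", [dx, dy, dz]))
        out = compute_sasa(centre + cage, n_points=960)
        assert out.residue_area[("A", 1, None)] == pytest.approx(0.0, abs=1e-9)

    def test_two_sphere_analytic_formula(self):
        # analytic spherical-cap oracle for two identical spheres
        r = VDW_RADII["C"] + 1.4
        for d in (2.0, 3.5, 5.0):
            res = [single_atom_residue("A", 1, "CA", "C", [0, 0, 0]),
                   single_atom_residue("B", 1, "CA", "C", [d, 0, 0])]
            out = compute_sasa(res, n_points=960)
            cap_height = r - d / 2.0
            analytic = 2 * (4 * np.pi * r ** 2 - 2 * np.pi * r * cap_height)
            assert out.total == pytest.approx(analytic, rel=0.01)

    def test_convergence_with_point_count(self, toy_class_i_analysis):
        st, nmap, truth, domains, *_ = toy_class_i_analysis
        part = domains["peptide"]
        coarse = compute_sasa(part, n_points=960).total
        fine = compute_sasa(part, n_points=4000).total
        assert abs(fine - coarse) / fine < 0.02

    def test_against_independent_implementation(self):
        # biotite's Shrake-Rupley is an independent oracle; same radii table
        biotite_structure = pytest.importorskip("biotite.structure")
        import biotite.structure as struc
        rng = np.random.default_rng(1)
        xyz = rng.uniform(0, 10, size=(30, 3))
        residues = [single_atom_residue("A", i + 1, "CA", "C", xyz[i])
                    for i in range(30)]
        mine = compute_sasa(residues, n_points=2000).total
        arr = struc.AtomArray(30)
        arr.coord = xyz
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, 31)
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        ref = struc.sasa(arr, probe_radius=1.4, point_number=2000,
                         vdw_radii="Single").sum()
        # radii tables differ slightly; compare at matched radius via scaling
        assert mine == pytest.approx(float(ref), rel=0.05)

    def test_unknown_element_warns_and_defaults(self):
        res = [single_atom_residue("A", 1, "X1", "Q", [0, 0, 0])]
        with pytest.warns(UserWarning, match="unknown element"):
            out = compute_sasa(res, n_points=240)
        assert out.total > 0


class TestInterfaceSummary:
    def test_separated_parts_bury_nothing(self):
        a = [single_atom_residue("A", 1, "CA", "C", [0, 0, 0])]
        b = [single_atom_residue("B", 1, "CA", "C", [100.0, 0, 0])]
        summ = interface_summary(a, b)
        assert summ.buried_area == pytest.approx(0.0, abs=1e-9)
        assert summ.interface_residues_a == []
        assert summ.interface_residues_b == []

    def test_empty_part_rejected(self):
        a = [single_atom_residue("A", 1, "CA", "C", [0, 0, 0])]
        with pytest.raises(ValueError):
            interface_summary(a, [])

    def test_interface_residues_match_bruteforce_dsasa(self, toy_class_ii_analysis):
        st, nmap, truth, domains, *_ = toy_class_ii_analysis
        peptide, pab = domains["peptide"], domains["pab"]
        summ = interface_summary(peptide, pab, n_points=240)
        # brute-force oracle: per-residue isolated-vs-complex recomputation
        complex_sasa = compute_sasa(peptide + pab, n_points=240)
        alone = compute_sasa(peptide, n_points=240)
        expected = sorted(
            r.key for r in peptide
            if alone.residue_area[r.key] - complex_sasa.residue_area[r.key] > 0.1
        )
        assert summ.interface_residues_a == expected

    def test_buried_area_rigid_invariance(self, toy_class_i_analysis):
        # the sphere-point grid is fixed in space, so rotational invariance
        # holds only to quadrature accuracy; 4000 points keeps it below 0.5%
        st, nmap, truth, domains, *_ = toy_class_i_analysis
        ia, pab = domains["ia"], domains["pab"]
        ref = interface_summary(ia, pab, n_points=4000).buried_area
        rng = np.random.default_rng(2)
        for _ in range(3):
            Q, t = random_rigid_transform(rng)
            moved = st.transformed(Q, t)
            domains2 = assign_domains(moved, nmap)
            got = interface_summary(domains2["ia"], domains2["pab"],
                                    n_points=4000).buried_area
            assert got == pytest.approx(ref, rel=0.005)


class TestPeptideExposedSurface:
    def test_isolated_peptide_fully_exposed(self, toy_class_ii_analysis):
        st, nmap, truth, domains, *_ = toy_class_ii_analysis
        pep = domains["peptide"]
        exposed = peptide_exposed_surface(pep, [], n_points=240)
        assert exposed == pytest.approx(compute_sasa(pep, n_points=240).total)

    def test_enclosed_peptide_near_zero(self):
        pep = [single_atom_residue("P", 1, "CA", "C", [0, 0, 0])]
        shell = []
        k = 0
        for dx in (-2.0, 0, 2.0):
            for dy in (-2.0, 0, 2.0):
                for dz in (-2.0, 0, 2.0):
                    if dx == dy == dz == 0:
                        continue
                    k += 1
                    shell.append(single_atom_residue("S", k, "CA", "C", [dx, dy, dz]))
        assert peptide_exposed_surface(pep, shell, n_points=960) < 1e-9

    def test_consistency_with_interface_summary(self, toy_class_ii_analysis):
        # isolated ASA - exposed = 2 x symmetric buried area contributed by
        # the peptide side; checked through the summary's own numbers
        st, nmap, truth, domains, *_ = toy_class_ii_analysis
        pep = domains["peptide"]
        rest = domains["pab"] + domains["ia"] + domains["ib"]
        exposed = peptide_exposed_surface(pep, rest, n_points=240)
        iso = compute_sasa(pep, n_points=240).total
        summ = interface_summary(pep, rest, n_points=240)
        buried_pep_side = sum(max(v, 0.0) for v in summ.dsasa_a.values())
        assert iso - exposed == pytest.approx(buried_pep_side, rel=0.01)
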