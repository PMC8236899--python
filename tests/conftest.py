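import warnings

import numpy as np
import pytest

from pmhckit.numbering import assign_domains
from pmhckit.secondary import (assign_secondary_structure, build_beta_topology,
                               compute_backbone_hbonds)
from pmhckit.synthetic import ToyComplexSpec, make_toy_pmhc

warnings.filterwarnings("ignore", message=".*strands, expected.*")


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation and a bounded translation."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    Q = Q * np.sign(np.linalg.det(Q))
    t = rng.uniform(-20.0, 20.0, size=3)
    return Q, t


@pytest.fixture(scope="session")
def toy_class_i():
    st, nmap, truth = make_toy_pmhc(ToyComplexSpec(class_type="I"))
    return st, nmap, truth


@pytest.fixture(scope="session")
def toy_class_ii():
    st, nmap, truth = make_toy_pmhc(ToyComplexSpec(class_type="II", peptide_overhang=2))
    return st, nmap, truth


@pytest.fixture(scope="session")
def toy_class_i_analysis(toy_class_i):
    st, nmap, truth = toy_class_i
    domains = assign_domains(st, nmap)
    hbonds = compute_backbone_hbonds(st)
    ss = assign_secondary_structure(hbonds, st)
    topo = build_beta_topology(hbonds, st, ss, domains=domains, nmap=nmap)
    return st, nmap, truth, domains, hbonds, ss, topo


@pytest.fixture(scope="session")
def toy_class_ii_analysis(toy_class_ii):
    st, nmap, truth = toy_class_ii
    domains = assign_domains(st, nmap)
    hbonds = compute_backbone_hbonds(st)
    ss = assign_secondary_structure(hbonds, st)
    topo = build_beta_topology(hbonds, st, ss, domains=domains, nmap=nmap)
    return st, nmap, truth, domains, hbonds, ss, topo
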