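"""Shared fixtures: small designs, toy ground truths, simulated traces."""

import numpy as np
import pytest

from srmquant.design import DesignSpec, build_design
from srmquant.peptides import PeptideProteinMap
from srmquant.simulate import GroundTruth, simulate_traces


@pytest.fixture(scope="session")
def default_spec():
    return DesignSpec()


@pytest.fixture(scope="session")
def default_design(default_spec):
    return build_design(default_spec)


@pytest.fixture(scope="session")
def single_reading_design():
    spec = DesignSpec(
        n_dilutions=1,
        include_pool=False,
        aliquots_per_sample=1,
        digestions_per_aliquot=1,
        injections_per_digestion=1,
        n_day_couples=1,
    )
    table = build_design(spec)
    return table[~table["is_qc"]].reset_index(drop=True)


def make_toy_truth(
    y=3.0,
    g=1.0,
    kappa_star=2.0,
    n_transitions=3,
    gamma_n=1e8,
    gamma_star_n=1e8,
    xi=None,
    phi_star=None,
):
    """One protein / one peptide toy with near-noiseless defaults."""
    pm = PeptideProteinMap(
        ("pepA",),
        ("protA",),
        np.array([[1.0]]),
        np.array([[g]]),
        np.array([kappa_star]),
    )
    return GroundTruth(
        pep_map=pm,
        y=np.array([float(y)]),
        tau=np.array([12.0]),
        lam=np.array([0.1]),
        xi=[np.asarray(xi) if xi is not None else np.array([1.0, 0.8, 1.2])[:n_transitions]],
        phi_star=[
            np.asarray(phi_star) if phi_star is not None else np.ones(n_transitions)
        ],
        gamma_n=gamma_n,
        gamma_star_n=gamma_star_n,
        gamma_kappa=1e10,
    )


@pytest.fixture()
def toy_truth():
    return make_toy_truth()


@pytest.fixture()
def fine_grid():
    return np.round(np.arange(11.0, 13.0 + 1e-9, 0.01), 6)


@pytest.fixture()
def toy_traces(toy_truth, single_reading_design, fine_grid):
    return simulate_traces(single_reading_design, toy_truth, fine_grid, seed=0)
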