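import numpy as np
import pytest

from cuecombine import observer_sim as osim
from cuecombine import pipeline as pl
from cuecombine import psychometric_fit as pf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def matched_observer():
    """MLE observer with matched reliabilities, realistic lapse and drift."""
    return osim.ObserverSpec(
        sigma_A=2.0, sigma_V=2.0, lapse=0.02, eta=0.1, policy="mle", seed=77
    )


@pytest.fixture(scope="session")
def main_design(matched_observer):
    return osim.make_design(matched_observer.jnd_A, 40)


@pytest.fixture(scope="session")
def matched_counts(matched_observer, main_design):
    return osim.simulate_counts(matched_observer, main_design)


@pytest.fixture(scope="session")
def joint_fit(matched_counts):
    return pf.fit_joint(matched_counts)


def make_exact_counts(design, params_by_condition, n_per_cell=2000):
    """Noise-free counts: k = round(n * psi) at the design locations."""
    counts = []
    for cond in pf.CONDITIONS:
        p = params_by_condition[cond]
        x = np.array(design.probe_locations)
        n = np.full(len(x), n_per_cell)
        k = np.rint(n * np.asarray(pf.psi(x, p))).astype(int)
        counts.append(pf.ConditionCounts(condition=cond, x=x, n=n, k=k))
    return counts


@pytest.fixture(scope="session")
def smoke_config():
    """Small but complete cohort configuration for end-to-end runs."""
    return pl.CohortConfig(
        n_target=2,
        seed=424242,
        sigma_A_range=(1.8, 2.2),
        bias_range=(-0.1, 0.1),
        lapse_range=(0.0, 0.01),
        eta_range=(0.02, 0.05),
        n_per_cell_main=16,
        n_per_cell_screen=16,
        n_boot=120,
        n_boot_screen=120,
        n_restarts=4,
        likelihood="betabinomial",
    )


@pytest.fixture(scope="session")
def smoke_reports(smoke_config, tmp_path_factory):
    """Two identically configured cohort runs, with written artifacts."""
    out_a = tmp_path_factory.mktemp("cohort_a")
    out_b = tmp_path_factory.mktemp("cohort_b")
    rep_a = pl.run_replication(smoke_config, outdir=out_a)
    rep_b = pl.run_replication(smoke_config, outdir=out_b)
    return (rep_a, out_a), (rep_b, out_b)
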