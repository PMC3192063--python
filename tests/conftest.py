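import pytest

import wntclock as wc


@pytest.fixture(scope="session")
def ref_params():
    return wc.reference_parameters()


@pytest.fixture(scope="session")
def ref_traj(ref_params):
    """Reference trajectory: 6000 min from the default initial state."""
    return wc.integrate(ref_params, duration=6000.0)


@pytest.fixture(scope="session")
def ref_stats_D(ref_traj):
    return wc.oscillation_stats(ref_traj, species="D", transient=2000.0)


@pytest.fixture(scope="session")
def front_copy(ref_params):
    """Synchronized elongation run: copy-neighbour, fold-2 Gaussian
    gradient, 180 cells budding every 10 min."""
    config = wc.ElongationConfig(
        R=10.0,
        T_transit=1200.0,
        n_cells=180,
        sync="copy_neighbor",
        seed=0,
        schedule=wc.gaussian_schedule(fold=2.0, transit=1200.0),
    )
    return wc.run_elongation(ref_params, config)
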