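import pytest

from socesim import (
    load_parameters,
    run_ryr_activation_experiment,
    run_steady_state_experiment,
    run_tg_soce_experiment,
)


@pytest.fixture()
def params():
    """Fresh default parameter set (mutable per test)."""
    return load_parameters()


@pytest.fixture(scope="session")
def tg_summary():
    """The thapsigargin/Ca-readdition/2-APB protocol run, shared across tests."""
    return run_tg_soce_experiment()


@pytest.fixture(scope="session")
def ss_summary():
    """Relaxation to the resting state at 1.8 mM external calcium."""
    return run_steady_state_experiment()


@pytest.fixture(scope="session")
def ryr_summary():
    """The tenfold-RyR-activation experiment from the resting state."""
    return run_ryr_activation_experiment()


@pytest.fixture(scope="session")
def d_diff_sweep():
    """TG runs over halved/default/doubled junction-to-cytosol diffusion distance."""
    from socesim import run_parameter_sweep

    return run_parameter_sweep(
        load_parameters(),
        "geometry.diffusion_distance",
        [0.175, 0.35, 0.70],
        "tg-soce",
        t_end=431.0,
    )
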