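import numpy as np
import pandas as pd
import pytest

from zinbpanel import PanelDataset, SimulationConfig, generate_panel


@pytest.fixture(scope="session")
def small_sim():
    """Small reference-truth simulated panel shared across tests."""
    return generate_panel(SimulationConfig(n_sites=8, horizon_hours=400, seed=42))


@pytest.fixture(scope="session")
def small_panel(small_sim):
    return small_sim.panel


@pytest.fixture(scope="session")
def fit_sim():
    """Compact, well-identified ZINB-RE scenario for estimation tests:
    few covariates and a higher event rate so all parameters are informed."""
    import zinbpanel as zp

    truth = zp.ZinbReParams(
        beta_nb=np.array([-4.0, 0.08, -0.5, 0.3]),
        beta_z=np.array([0.5, -0.6, 0.35]),
        alpha=1.0,
        phi_sigma=0.4,
        phi_psi=0.0,
    )
    cfg = SimulationConfig(
        n_sites=30,
        horizon_hours=300,
        count_design=["speed_gap", "wet", "n_lanes"],
        zero_design=["volume", "night"],
        truth=truth,
        seed=9,
    )
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def fit_panel(fit_sim):
    return fit_sim.panel


@pytest.fixture
def tiny_panel():
    """Hand-built 3-site panel with one continuous and one indicator covariate."""
    rng = np.random.default_rng(7)
    n = 60
    df = pd.DataFrame(
        {
            "site_id": np.repeat(["a", "b", "c"], n // 3),
            "time_id": np.tile(np.arange(n // 3), 3),
            "count": rng.poisson(0.5, n),
            "x": rng.normal(size=n).round(3),
            "d": rng.integers(0, 2, n).astype(float),
        }
    )
    return PanelDataset(df, ["x", "d"], ["x"])


def intercept_only_panel(counts, n_sites=1):
    """Panel with no covariates from a vector of counts."""
    counts = np.asarray(counts)
    n = len(counts)
    sites = np.arange(n) % n_sites
    order = np.argsort(sites, kind="stable")
    df = pd.DataFrame(
        {
            "site_id": sites[order],
            "time_id": np.concatenate(
                [np.arange(np.sum(sites == s)) for s in range(n_sites)]
            ),
            "count": counts[order],
        }
    )
    return PanelDataset(df, [], [])
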