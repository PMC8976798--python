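import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fracrisk import datasets
from fracrisk.hazard import HazardGrid, LifeTable
from fracrisk.incidence import IncidenceModel
from fracrisk.mof import default_ratio_table
from fracrisk.probability import FractureRiskModel
from fracrisk.synthetic import GeneratorConfig, generate_lifetable


@pytest.fixture(scope="session")
def survey_results():
    """Incidence fit of the bundled two-year survey aggregates."""
    return IncidenceModel(
        datasets.survey_counts(), datasets.survey_population()
    ).fit()


@pytest.fixture(scope="session")
def life_tables():
    cfg = GeneratorConfig(seed=0)
    return {s: generate_lifetable(cfg, s) for s in ("female", "male")}


@pytest.fixture(scope="session")
def risk_results(survey_results, life_tables):
    """Fitted fracture-risk model with hip and MOF grids for both sexes."""
    model = FractureRiskModel(
        survey_results, life_tables, mof_ratios=default_ratio_table()
    )
    return model.fit()


def random_hazard_grid(rng, n_cells=60, step=0.25, start_age=50.0):
    """Random piecewise-constant hazard grid for engine cross-checks."""
    h_frac = rng.uniform(0, 0.05, n_cells)
    h_death = rng.uniform(0, 0.2, n_cells)
    # sprinkle exact-zero cells to exercise the 0/0 guard
    h_frac[rng.random(n_cells) < 0.1] = 0.0
    h_death[rng.random(n_cells) < 0.1] = 0.0
    return HazardGrid("female", start_age, step, h_frac, h_death)


def riemann_cumulative_incidence(grid: HazardGrid, start_age, horizon, dt=1e-4):
    """Independent fine-grid midpoint-Riemann oracle for the cumulative
    incidence function: P = ∫ f(t)·exp(−H(t))·dt with the integrated total
    hazard H evaluated exactly from the piecewise structure."""
    end = start_age + horizon
    clipped = np.clip(grid.edges, start_age, end)
    widths = np.diff(clipped)
    tot = grid.h_frac + grid.h_death
    cum = np.concatenate([[0.0], np.cumsum(tot * widths)])  # ∫(f+d) to cell end
    total = 0.0
    for i in np.nonzero(widths > 0)[0]:
        w = widths[i]
        m = max(1, int(np.ceil(w / dt)))
        sub = w / m
        # midpoints within the cell; H is linear inside the cell
        offs = sub * (np.arange(m) + 0.5)
        H = cum[i] + tot[i] * offs
        total += float(np.sum(grid.h_frac[i] * np.exp(-H) * sub))
    return total
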