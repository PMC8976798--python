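"""Fracture probability under competing mortality.

The core quantity is the cumulative incidence function of a first fracture
under competing death: with cause-specific piecewise-constant hazards f_i
(fracture) and d_i (death) on cells of width Δ_i,

    P(fracture first by T) = Σ_i  f_i/(f_i+d_i) · S_i · (1 − e^{−(f_i+d_i)Δ_i}),
    S_i = exp(−Σ_{j<i} (f_j+d_j) Δ_j),

which is exact for piecewise-constant hazards (no quadrature error).  The
same per-cell decomposition yields P(death first) and the event-free
survivor, so the three parts sum to one identically.

``FractureRiskModel`` assembles the hazards from a fitted incidence table,
sex-specific life tables and (optionally) MOF:hip ratios; ``fit()`` returns
a ``FractureRiskResults`` exposing 10-year, arbitrary-horizon and remaining
lifetime probabilities.  Clinical risk factors enter only as user-supplied
hazard multipliers (``rr_frac``, ``rr_death``); the calibrated risk-factor
weights of the FRAX tool itself are proprietary and out of scope, so the
default prior-fracture illustration ``rr_frac = 1.8`` is illustrative only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hazard import (
    DEFAULT_GRID_STEP,
    DEFAULT_HAZARD_CAP,
    DEFAULT_MIN_AGE,
    DEFAULT_TERMINAL_AGE,
    HazardGrid,
    LifeTable,
    apply_relative_risk,
    death_hazard_from_lifetable,
    fracture_hazard_from_bands,
)
from .mof import RatioTable, impute_mof_hazard

__all__ = [
    "ProbabilityResult",
    "cumulative_incidence",
    "competing_decomposition",
    "ten_year_probability",
    "lifetime_probability",
    "probability_curve",
    "FractureRiskModel",
    "FractureRiskResults",
]

ASSESSMENT_RANGE = (40.0, 90.0)


@dataclass(frozen=True)
class ProbabilityResult:
    sex: str
    assessment_age: float
    horizon: float | str  # years, or "lifetime"
    outcome: str          # "hip" or "mof"
    probability: float
    rr_frac: float = 1.0
    rr_death: float = 1.0


def _cell_quantities(grid: HazardGrid, start_age: float, horizon: float):
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    end = start_age + horizon
    eps = 1e-9
    if start_age < grid.start_age - eps:
        raise ValueError(
            f"requested span starts at {start_age} but the grid begins at "
            f"{grid.start_age}: missing [{start_age}, {grid.start_age})"
        )
    if end > grid.end_age + eps:
        raise ValueError(
            f"requested span ends at {end} but the grid stops at "
            f"{grid.end_age}: missing [{grid.end_age}, {end})"
        )
    clipped = np.clip(grid.edges, start_age, end)
    w = np.diff(clipped)
    mask = w > 0
    return grid.h_frac[mask], grid.h_death[mask], w[mask]


def competing_decomposition(
    grid: HazardGrid, start_age: float, horizon: float
) -> tuple[float, float, float]:
    """(P fracture first, P death first fracture-free, P event-free) over
    [start_age, start_age+horizon).  Exact per-cell closed form; the three
    parts sum to 1."""
    f, d, w = _cell_quantities(grid, start_age, horizon)
    tot = f + d
    decr = np.exp(-tot * w)
    surv = np.concatenate([[1.0], np.cumprod(decr)])
    with np.errstate(divide="ignore", invalid="ignore"):
        f_share = np.where(tot > 0, f / np.where(tot > 0, tot, 1.0), 0.0)
        d_share = np.where(tot > 0, d / np.where(tot > 0, tot, 1.0), 0.0)
    jump = surv[:-1] * (1 - decr)
    return float(np.sum(f_share * jump)), float(np.sum(d_share * jump)), float(surv[-1])


def cumulative_incidence(grid: HazardGrid, start_age: float, horizon: float) -> float:
    """Probability that fracture occurs first within the horizon."""
    return competing_decomposition(grid, start_age, horizon)[0]


def _check_assessment_age(age: float) -> None:
    lo, hi = ASSESSMENT_RANGE
    if not lo <= age <= hi:
        raise ValueError(f"assessment age {age} outside [{lo}, {hi}]")


def ten_year_probability(
    grid: HazardGrid,
    age: float,
    rr_frac: float = 1.0,
    rr_death: float = 1.0,
    outcome: str = "hip",
) -> ProbabilityResult:
    """10-year first-fracture probability at an assessment age (40–90)."""
    _check_assessment_age(age)
    g = apply_relative_risk(grid, rr_frac, rr_death)
    p = cumulative_incidence(g, age, 10.0)
    return ProbabilityResult(grid.sex, age, 10.0, outcome, p, rr_frac, rr_death)


def lifetime_probability(
    grid: HazardGrid,
    start_age: float = 50.0,
    rr_frac: float = 1.0,
    rr_death: float = 1.0,
    outcome: str = "hip",
) -> ProbabilityResult:
    """Remaining lifetime first-fracture probability from ``start_age`` to
    the end of the grid (terminal age)."""
    g = apply_relative_risk(grid, rr_frac, rr_death)
    p = cumulative_incidence(g, start_age, g.end_age - start_age)
    return ProbabilityResult(grid.sex, start_age, "lifetime", outcome, p, rr_frac, rr_death)


def probability_curve(
    grid: HazardGrid,
    ages,
    horizon: float = 10.0,
    rr_frac: float = 1.0,
    rr_death: float = 1.0,
    outcome: str = "hip",
) -> list[ProbabilityResult]:
    """Vectorised fixed-horizon probabilities over assessment ages."""
    g = apply_relative_risk(grid, rr_frac, rr_death)
    out = []
    for age in np.asarray(ages, float):
        _check_assessment_age(age)
        p = cumulative_incidence(g, age, horizon)
        out.append(ProbabilityResult(grid.sex, float(age), horizon, outcome, p, rr_frac, rr_death))
    return out


def curve_frame(results: list[ProbabilityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.sex, r.assessment_age, r.outcome, r.horizon, r.rr_frac, r.rr_death, r.probability)
            for r in results
        ],
        columns=["sex", "age", "outcome", "horizon", "rr_frac", "rr_death", "probability"],
    )


class FractureRiskModel:
    """FRAX-style country model built from incidence and mortality.

    Parameters
    ----------
    incidence : IncidenceResults or DataFrame with columns sex, band_start,
        band_end, rate (per 100,000 p-y), optionally person_years.
    life_tables : mapping sex -> LifeTable.
    mof_ratios : optional RatioTable; if given, MOF probabilities become
        available alongside hip.
    grid_step : grid resolution in years (default 1/12).
    min_age, terminal_age : grid span; assessments allowed on 40–90,
        lifetime integrals run to terminal_age.
    hazard_cap : ceiling on the extrapolated fracture hazard, per year.
    """

    def __init__(
        self,
        incidence,
        life_tables: dict[str, LifeTable],
        mof_ratios: RatioTable | None = None,
        grid_step: float = DEFAULT_GRID_STEP,
        min_age: float = DEFAULT_MIN_AGE,
        terminal_age: float = DEFAULT_TERMINAL_AGE,
        hazard_cap: float = DEFAULT_HAZARD_CAP,
    ) -> None:
        table = getattr(incidence, "table", incidence)
        if "rate" not in table.columns:
            raise ValueError("incidence table must carry a 'rate' column (fit the model first)")
        self.incidence_table = table
        self.life_tables = dict(life_tables)
        self.mof_ratios = mof_ratios
        self.grid_step = float(grid_step)
        self.min_age = float(min_age)
        self.terminal_age = float(terminal_age)
        self.hazard_cap = float(hazard_cap)
        self.sexes = sorted(set(table["sex"]))
        missing = [s for s in self.sexes if s not in self.life_tables]
        if missing:
            raise ValueError(f"life table missing for sex(es): {missing}")

    def fit(self) -> "FractureRiskResults":
        grids: dict[tuple[str, str], HazardGrid] = {}
        for sex in self.sexes:
            hip = fracture_hazard_from_bands(
                self.incidence_table, sex,
                grid_step=self.grid_step, min_age=self.min_age,
                terminal_age=self.terminal_age, cap=self.hazard_cap,
            )
            hip = death_hazard_from_lifetable(self.life_tables[sex], hip)
            grids[("hip", sex)] = hip
            if self.mof_ratios is not None:
                grids[("mof", sex)] = impute_mof_hazard(hip, self.mof_ratios)
        return FractureRiskResults(self, grids)


class FractureRiskResults:
    """Fitted hazard grids with probability accessors."""

    def __init__(self, model: FractureRiskModel, grids: dict) -> None:
        self.model = model
        self.grids = grids

    def grid(self, sex: str, outcome: str = "hip") -> HazardGrid:
        try:
            return self.grids[(outcome, sex)]
        except KeyError:
            raise KeyError(
                f"no fitted grid for outcome {outcome!r}, sex {sex!r}"
                + (" (fit with mof_ratios for MOF)" if outcome == "mof" else "")
            ) from None

    def ten_year_probability(
        self, sex: str, age: float, outcome: str = "hip",
        rr_frac: float = 1.0, rr_death: float = 1.0,
    ) -> ProbabilityResult:
        return ten_year_probability(
            self.grid(sex, outcome), age, rr_frac, rr_death, outcome=outcome
        )

    def lifetime_probability(
        self, sex: str, start_age: float = 50.0, outcome: str = "hip",
        rr_frac: float = 1.0, rr_death: float = 1.0,
    ) -> ProbabilityResult:
        return lifetime_probability(
            self.grid(sex, outcome), start_age, rr_frac, rr_death, outcome=outcome
        )

    def probability_curve(
        self, sex: str, ages, outcome: str = "hip", horizon: float = 10.0,
        rr_frac: float = 1.0, rr_death: float = 1.0,
    ) -> pd.DataFrame:
        return curve_frame(
            probability_curve(
                self.grid(sex, outcome), ages, horizon, rr_frac, rr_death, outcome=outcome
            )
        )

    def summary(self, ages=(50, 60, 70, 80, 90)) -> str:
        outcomes = sorted({o for o, _ in self.grids})
        lines = ["10-year fracture probability (%) by assessment age", ""]
        header = "sex     outcome " + "".join(f"{a:>8}" for a in ages)
        lines.append(header)
        for (outcome, sex), _ in sorted(self.grids.items()):
            probs = [
                self.ten_year_probability(sex, a, outcome).probability * 100
                for a in ages
            ]
            lines.append(
                f"{sex:<7} {outcome:<7} " + "".join(f"{p:8.2f}" for p in probs)
            )
        lines.append("")
        lines.append("Remaining lifetime hip-fracture probability from age 50 (%)")
        for sex in self.model.sexes:
            p = self.lifetime_probability(sex, 50.0, "hip").probability * 100
            lines.append(f"  {sex}: {p:.1f}")
        return "\n".join(lines)

    def plot_curve(self, sex: str, ages, outcome: str = "hip", horizon: float = 10.0,
                   rr_frac: float = 1.0, ax=None):
        """Plot a probability-by-age curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        df = self.probability_curve(sex, ages, outcome, horizon, rr_frac)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(df["age"], df["probability"] * 100, marker="o")
        ax.set_xlabel("age (years)")
        ax.set_ylabel(f"{horizon:g}-year {outcome} fracture probability (%)")
        ax.set_title(f"{sex}, rr_frac={rr_frac:g}")
        return ax
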