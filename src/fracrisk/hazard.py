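"""Continuous fracture and death hazards from banded data.

Banded incidence rates are anchored at band midpoints and joined by
log-linear (exponential) interpolation — hip-fracture incidence is close to
exponential in age, so straight lines in log-rate are the natural smoother.
Below the first midpoint the hazard is held constant; above the last it is
extrapolated from the last two anchors and capped at a ceiling hazard.
Life-table death probabilities convert to hazards via h = −ln(1−q), held
constant within each year of age.  Both hazards live on a common fine age
grid (default step 1/12 year) as piecewise-constant functions, which keeps
all downstream probability integrals closed-form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .incidence import PER

__all__ = [
    "LifeTable",
    "HazardGrid",
    "band_rate_interpolator",
    "fracture_hazard_from_bands",
    "death_hazard_from_lifetable",
    "apply_relative_risk",
]

DEFAULT_GRID_STEP = 1 / 12
DEFAULT_TERMINAL_AGE = 105.0
DEFAULT_MIN_AGE = 40.0
DEFAULT_HAZARD_CAP = 0.1  # per year


@dataclass(frozen=True)
class LifeTable:
    """Sex-specific life table on single years of age.

    ``q`` holds annual death probabilities; alternatively construct from
    central death rates with :meth:`from_central_rates`.
    """

    sex: str
    ages: np.ndarray  # contiguous integer ages
    q: np.ndarray     # annual death probability, 0 <= q < 1

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages)
        q = np.asarray(self.q)
        if ages.shape != q.shape or ages.ndim != 1 or len(ages) == 0:
            raise ValueError("ages and q must be equal-length 1-d arrays")
        if np.any(np.diff(ages) != 1):
            raise ValueError("life-table ages must be contiguous single years")
        if np.any((q < 0) | (q >= 1)):
            raise ValueError("death probabilities must satisfy 0 <= q < 1")
        object.__setattr__(self, "ages", ages.astype(int))
        object.__setattr__(self, "q", q.astype(float))

    @property
    def terminal_age(self) -> int:
        return int(self.ages[-1]) + 1

    def hazard(self) -> np.ndarray:
        """Constant within-year death hazard per year, −ln(1−q)."""
        return -np.log1p(-self.q)

    def survival(self) -> np.ndarray:
        """Survival from the first tabulated age to the start of each year
        (length len(ages)+1)."""
        return np.concatenate([[1.0], np.cumprod(1 - self.q)])

    @classmethod
    def from_central_rates(cls, sex: str, ages, m) -> "LifeTable":
        """Build from central death rates, q = 1 − exp(−m)."""
        m = np.asarray(m, float)
        if np.any(m < 0):
            raise ValueError("central death rates must be non-negative")
        return cls(sex, np.asarray(ages), -np.expm1(-m))

    @classmethod
    def from_csv(cls, path, sex: str | None = None) -> "dict[str, LifeTable] | LifeTable":
        """Read ``sex,age,q`` (or ``sex,age,m``) CSV; returns a dict keyed by
        sex, or a single table if ``sex`` is given."""
        df = pd.read_csv(path)
        out = {}
        for s, grp in df.groupby("sex"):
            grp = grp.sort_values("age")
            if "q" in grp.columns:
                out[s] = cls(s, grp["age"].to_numpy(), grp["q"].to_numpy())
            elif "m" in grp.columns:
                out[s] = cls.from_central_rates(s, grp["age"].to_numpy(), grp["m"].to_numpy())
            else:
                raise ValueError("life-table CSV needs a 'q' or 'm' column")
        if sex is not None:
            return out[sex]
        return out

    def to_csv(self, path) -> None:
        pd.DataFrame({"sex": self.sex, "age": self.ages, "q": self.q}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class HazardGrid:
    """Piecewise-constant fracture and death hazards on a fine age grid.

    Cell ``i`` covers ``[start_age + i·step, start_age + (i+1)·step)``;
    hazards are per-year rates, constant within a cell.
    """

    sex: str
    start_age: float
    step: float
    h_frac: np.ndarray
    h_death: np.ndarray

    def __post_init__(self) -> None:
        hf = np.asarray(self.h_frac, float)
        hd = np.asarray(self.h_death, float)
        if hf.shape != hd.shape or hf.ndim != 1:
            raise ValueError("h_frac and h_death must be equal-length 1-d arrays")
        if np.any(hf < 0) or np.any(hd < 0):
            raise ValueError("hazards must be non-negative")
        object.__setattr__(self, "h_frac", hf)
        object.__setattr__(self, "h_death", hd)

    @property
    def n_cells(self) -> int:
        return len(self.h_frac)

    @property
    def end_age(self) -> float:
        return self.start_age + self.n_cells * self.step

    @property
    def edges(self) -> np.ndarray:
        return self.start_age + self.step * np.arange(self.n_cells + 1)

    @property
    def midpoints(self) -> np.ndarray:
        return self.start_age + self.step * (np.arange(self.n_cells) + 0.5)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sex": self.sex,
            "age": self.edges[:-1],
            "h_frac": self.h_frac,
            "h_death": self.h_death,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def band_rate_interpolator(
    band_starts: np.ndarray,
    band_ends: np.ndarray,
    rates: np.ndarray,
    person_years: np.ndarray | None = None,
    cap: float = DEFAULT_HAZARD_CAP,
):
    """Return a vectorised function age → hazard per year.

    Rates (per 100,000 p-y) are anchored at band midpoints ((start+end+1)/2
    for a closed band of integer ages) and interpolated log-linearly.  The
    hazard is constant below the first midpoint; above the last midpoint the
    slope of the last two anchors is extrapolated, capped at ``cap``.  Bands
    with zero events are floored at the rate implied by half an event
    (0.5/PY) so logs are defined; without person-years a floor of half the
    smallest positive rate is used.
    """
    starts = np.asarray(band_starts, float)
    ends = np.asarray(band_ends, float)
    rates = np.asarray(rates, float).copy()
    order = np.argsort(starts)
    starts, ends, rates = starts[order], ends[order], rates[order]
    if len(starts) < 2:
        raise ValueError("need at least two bands to interpolate")
    if np.all(rates <= 0):
        raise ValueError("cannot build hazard from zero incidence")
    zero = rates <= 0
    if zero.any():
        if person_years is not None:
            py = np.asarray(person_years, float)[order]
            rates[zero] = 0.5 / py[zero] * PER
        else:
            rates[zero] = rates[~zero].min() / 2
    mids = (starts + ends + 1) / 2
    log_rates = np.log(rates)
    slope_hi = (log_rates[-1] - log_rates[-2]) / (mids[-1] - mids[-2])

    def hazard(age):
        age = np.asarray(age, float)
        lr = np.interp(age, mids, log_rates)
        above = age > mids[-1]
        if np.any(above):
            lr = np.where(above, log_rates[-1] + slope_hi * (age - mids[-1]), lr)
        return np.minimum(np.exp(lr) / PER, cap)

    return hazard


def fracture_hazard_from_bands(
    table: pd.DataFrame,
    sex: str,
    grid_step: float = DEFAULT_GRID_STEP,
    min_age: float = DEFAULT_MIN_AGE,
    terminal_age: float = DEFAULT_TERMINAL_AGE,
    cap: float = DEFAULT_HAZARD_CAP,
) -> HazardGrid:
    """Build the fracture-hazard part of a grid from a fitted incidence
    table (columns sex, band_start, band_end, rate, optionally
    person_years).  The death hazard is initialised to zero."""
    sub = table[table["sex"] == sex]
    if len(sub) < 2:
        raise ValueError(f"need at least two bands for sex {sex!r}")
    py = sub["person_years"].to_numpy() if "person_years" in sub.columns else None
    fn = band_rate_interpolator(
        sub["band_start"].to_numpy(), sub["band_end"].to_numpy(),
        sub["rate"].to_numpy(), person_years=py, cap=cap,
    )
    n = int(round((terminal_age - min_age) / grid_step))
    mids = min_age + grid_step * (np.arange(n) + 0.5)
    h_frac = fn(mids)
    return HazardGrid(sex, float(min_age), float(grid_step), h_frac, np.zeros(n))


def death_hazard_from_lifetable(
    lt: LifeTable,
    grid: HazardGrid,
) -> HazardGrid:
    """Fill a grid's death hazard from a life table.

    Within year of age ``a`` the hazard is −ln(1−q_a), so survival across a
    whole year reproduces 1−q exactly.  Ages outside the tabulated range
    take the nearest tabulated year's hazard.
    """
    h_year = lt.hazard()
    years = np.clip(
        np.floor(grid.midpoints).astype(int), lt.ages[0], lt.ages[-1]
    )
    h_death = h_year[years - lt.ages[0]]
    return replace(grid, h_death=h_death)


def apply_relative_risk(
    grid: HazardGrid, rr_frac: float = 1.0, rr_death: float = 1.0
) -> HazardGrid:
    """Scale hazards pointwise; rr = 1 is the identity."""
    if not (np.isfinite(rr_frac) and np.isfinite(rr_death)):
        raise ValueError("relative risks must be finite")
    if rr_frac < 0 or rr_death < 0:
        raise ValueError("relative risks must be non-negative")
    if rr_frac == 1.0 and rr_death == 1.0:
        return grid
    return replace(grid, h_frac=grid.h_frac * rr_frac, h_death=grid.h_death * rr_death)
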