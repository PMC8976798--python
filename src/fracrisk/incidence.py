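"""Age/sex-specific incidence with exact Poisson confidence intervals.

The estimand is the annual incidence of first low-energy hip fracture per
100,000 person-years within a (sex, 5-year age band) cell.  Person-years are
population × observation years (static-population assumption, appropriate for
a short survey window).  Interval estimates are Garwood exact bounds built
from chi-square quantiles of the Poisson count distribution, which are
conservative (coverage ≥ nominal) and well defined at zero events.

The modelling surface follows the Model/Results idiom::

    model = IncidenceModel(counts, population, years_observed=2.0)
    res = model.fit()
    res.table          # per-cell rates with 95% CIs
    res.crude_rates    # per-sex crude rates
    res.summary()      # formatted report
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PER = 1e5  # rates are reported per 100,000 person-years

__all__ = [
    "AgeBand",
    "compute_rate",
    "display_rate",
    "exact_poisson_ci",
    "rate_ratio_test",
    "IncidenceModel",
    "IncidenceResults",
]


@dataclass(frozen=True)
class AgeBand:
    """A 5-year age band; ``end`` is inclusive, ``open_ended`` marks the
    terminal band (labelled with a nominal end but accepting all older ages).
    """

    start: int
    end: int
    open_ended: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"band start {self.start} must precede end {self.end}")

    @property
    def midpoint(self) -> float:
        # closed band [a, b] of integer ages covers [a, b+1) in exact age
        return (self.start + self.end + 1) / 2

    def contains(self, age: float) -> bool:
        if self.open_ended:
            return age >= self.start
        return self.start <= age <= self.end

    @property
    def label(self) -> str:
        return f"{self.start}–{self.end}" + ("+" if self.open_ended else "")


def default_bands(starts=(45, 50, 55, 60, 65, 70, 75, 80)) -> list[AgeBand]:
    """Contiguous 5-year bands; the last one is open-ended."""
    bands = [AgeBand(s, s + 4) for s in starts[:-1]]
    bands.append(AgeBand(starts[-1], starts[-1] + 4, open_ended=True))
    return bands


def compute_rate(events: float, population: float, years_observed: float) -> float:
    """Annual incidence per 100,000 person-years (unrounded)."""
    if population <= 0:
        raise ValueError("population must be positive")
    if years_observed <= 0:
        raise ValueError("years_observed must be positive")
    if events < 0:
        raise ValueError("events must be non-negative")
    return events / (population * years_observed) * PER


def display_rate(rate: float) -> float:
    """Publication rounding: rates ≥ 10 to the nearest integer, smaller
    rates to one decimal place."""
    return float(round(rate)) if rate >= 10 else round(rate, 1)


def exact_poisson_ci(
    events: int, person_years: float, level: float = 0.95
) -> tuple[float, float]:
    """Garwood exact confidence interval for a Poisson rate, per 100,000.

    Bounds for the Poisson mean are chi-square quantiles,
    ``[χ²(α/2, 2k)/2, χ²(1−α/2, 2k+2)/2]``, divided by person-years.  At
    ``events == 0`` the lower bound is 0.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if events < 0:
        raise ValueError("events must be non-negative")
    alpha = 1 - level
    low = 0.0 if events == 0 else stats.chi2.ppf(alpha / 2, 2 * events) / 2
    high = stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2
    return low / person_years * PER, high / person_years * PER


def rate_ratio_test(
    events_a: int, py_a: float, events_b: int, py_b: float
) -> float:
    """Exact conditional test that two Poisson rates are equal.

    Conditions on the total count: under the null, ``events_a`` is binomial
    with ``n = events_a + events_b`` and success probability
    ``py_a / (py_a + py_b)``.  The two-sided p-value doubles the smaller
    tail (each tail includes the observed value) and is capped at 1.
    """
    if py_a <= 0 or py_b <= 0:
        raise ValueError("person-years must be positive")
    n = events_a + events_b
    if n <= 0:
        raise ValueError("need at least one event")
    p0 = py_a / (py_a + py_b)
    lower = stats.binom.cdf(events_a, n, p0)
    upper = stats.binom.sf(events_a - 1, n, p0)
    return float(min(1.0, 2 * min(lower, upper)))


class IncidenceModel:
    """Poisson incidence model for banded count data.

    Parameters
    ----------
    counts : DataFrame with columns sex, band_start, band_end, events
    population : DataFrame with columns sex, band_start, band_end, population
    years_observed : survey duration in years (person-years = population ×
        years_observed; the population is treated as static over the window)
    level : confidence level for the exact intervals
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        population: pd.DataFrame,
        years_observed: float = 2.0,
        level: float = 0.95,
    ) -> None:
        if years_observed <= 0:
            raise ValueError("years_observed must be positive")
        if not 0 < level < 1:
            raise ValueError("level must lie in (0, 1)")
        keys = ["sex", "band_start", "band_end"]
        data = population.merge(counts, on=keys, how="left")
        data["events"] = data["events"].fillna(0).astype(int)
        if (data["population"] <= 0).any():
            raise ValueError("all band populations must be positive")
        self.data = data.sort_values(["sex", "band_start"]).reset_index(drop=True)
        self.years_observed = float(years_observed)
        self.level = float(level)

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, years_observed: float = 2.0, level: float = 0.95
    ) -> "IncidenceModel":
        """Build from a single merged frame carrying both events and
        population columns."""
        keys = ["sex", "band_start", "band_end"]
        return cls(
            table[keys + ["events"]],
            table[keys + ["population"]],
            years_observed=years_observed,
            level=level,
        )

    def fit(self) -> "IncidenceResults":
        df = self.data.copy()
        py = df["population"].to_numpy(float) * self.years_observed
        events = df["events"].to_numpy(int)
        df["person_years"] = py
        df["rate"] = events / py * PER
        ci = np.array(
            [exact_poisson_ci(int(k), t, self.level) for k, t in zip(events, py)]
        )
        df["ci_low"], df["ci_high"] = ci[:, 0], ci[:, 1]
        return IncidenceResults(self, df)


class IncidenceResults:
    """Fitted incidence table with crude rates and between-sex comparisons."""

    def __init__(self, model: IncidenceModel, table: pd.DataFrame) -> None:
        self.model = model
        self.table = table

    # -- aggregates -----------------------------------------------------

    @property
    def crude_rates(self) -> dict[str, float]:
        """Crude annual incidence per 100,000 by sex (total events over
        total person-years, no age standardisation)."""
        out = {}
        for sex, grp in self.table.groupby("sex"):
            out[sex] = grp["events"].sum() / grp["person_years"].sum() * PER
        return out

    @property
    def female_male_ratio(self) -> float | None:
        crude = self.crude_rates
        if crude.get("male", 0) == 0:
            return None
        return crude["female"] / crude["male"]

    def sex_comparison(self) -> pd.DataFrame:
        """Per-band exact conditional test of female vs male rates."""
        keys = ["band_start", "band_end"]
        f = self.table[self.table["sex"] == "female"].set_index(keys)
        m = self.table[self.table["sex"] == "male"].set_index(keys)
        rows = []
        for idx in f.index:
            ef, pf = int(f.loc[idx, "events"]), f.loc[idx, "person_years"]
            em, pm = int(m.loc[idx, "events"]), m.loc[idx, "person_years"]
            if ef + em == 0:
                p = np.nan
            else:
                p = rate_ratio_test(ef, pf, em, pm)
            rows.append((*idx, ef, em, p))
        return pd.DataFrame(
            rows, columns=["band_start", "band_end", "events_female", "events_male", "p_value"]
        )

    # -- presentation ---------------------------------------------------

    def display_table(self) -> pd.DataFrame:
        """Publication-style rounded table (rates ≥10 integer, <10 one
        decimal)."""
        df = self.table.copy()
        for col in ("rate", "ci_low", "ci_high"):
            df[col] = df[col].map(display_rate)
        return df

    def to_csv(self, path) -> None:
        cols = [
            "sex", "band_start", "band_end", "population", "events",
            "rate", "ci_low", "ci_high",
        ]
        self.table[cols].to_csv(path, index=False)

    def summary(self) -> str:
        lines = [
            "Hip fracture incidence (per 100,000 person-years, "
            f"{int(self.model.level * 100)}% exact CI)",
            "",
        ]
        disp = self.display_table()
        for sex, grp in disp.groupby("sex"):
            lines.append(sex.capitalize())
            for _, r in grp.iterrows():
                band = f"{int(r.band_start)}–{int(r.band_end)}"
                lines.append(
                    f"  {band:>7}  pop {int(r.population):>8,}  "
                    f"events {int(r.events):>4}  rate {r.rate:>6g}  "
                    f"CI {r.ci_low:g}–{r.ci_high:g}"
                )
        crude = self.crude_rates
        lines.append("")
        for sex in sorted(crude):
            lines.append(f"Crude rate ({sex}): {crude[sex]:.1f} per 100,000")
        ratio = self.female_male_ratio
        if ratio is not None:
            lines.append(f"Female/male crude ratio: {ratio:.1f}")
        else:
            lines.append("Female/male crude ratio: undefined (male crude rate 0)")
        return "\n".join(lines)
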