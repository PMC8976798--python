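"""National burden projection from fixed age/sex-specific incidence.

Expected annual fracture counts are rates applied to population pyramids:
count(year, sex) = Σ_bands rate_band × population_band / 1e5, over bands at
or above a minimum age, holding the age- and sex-specific incidence
constant across calendar years.  Pyramid bands older than the last
incidence band receive the open-ended terminal band's rate (the oldest ages
drive long-horizon growth, so dropping them would bias projections down).
An optional scalar multiplier supports simple secular-trend scenarios.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["read_pyramids", "project_counts"]

PYRAMID_COLUMNS = ["year", "sex", "band_start", "band_end", "population"]


def read_pyramids(path) -> pd.DataFrame:
    """Read population pyramids CSV (year,sex,band_start,band_end,population)."""
    df = pd.read_csv(path)
    missing = [c for c in PYRAMID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pyramid CSV missing columns: {missing}")
    if (df["population"] < 0).any():
        raise ValueError("populations must be non-negative")
    return df


def project_counts(
    incidence,
    pyramids: pd.DataFrame,
    min_age: int = 50,
    rate_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Expected annual fracture counts by (year, sex), with totals.

    Parameters
    ----------
    incidence : IncidenceResults or DataFrame with sex, band_start,
        band_end, rate (per 100,000 person-years).
    pyramids : long frame of year,sex,band_start,band_end,population.
    min_age : lowest band start included (default 50).
    rate_multiplier : scalar applied to every rate (secular-trend scenario).

    Returns a frame with rows per (year, sex) plus a ``total`` row per year;
    a ``fold_change`` column reports each total against the first year's.
    """
    table = getattr(incidence, "table", incidence)
    rates = table.set_index(["sex", "band_start"])["rate"] * rate_multiplier
    last_start = {
        sex: grp["band_start"].max() for sex, grp in table.groupby("sex")
    }

    pyr = pyramids[pyramids["band_start"] >= min_age].copy()

    def band_rate(row):
        sex = row["sex"]
        start = row["band_start"]
        if (sex, start) in rates.index:
            return rates[(sex, start)]
        if sex in last_start and start > last_start[sex]:
            # open-ended terminal band rate for ages beyond the survey bands
            return rates[(sex, last_start[sex])]
        raise ValueError(
            f"no incidence band matching pyramid band (sex={sex!r}, "
            f"band_start={start})"
        )

    pyr["expected_count"] = pyr.apply(band_rate, axis=1) * pyr["population"] / 1e5
    by_sex = (
        pyr.groupby(["year", "sex"], as_index=False)["expected_count"].sum()
    )
    totals = (
        by_sex.groupby("year", as_index=False)["expected_count"].sum()
        .assign(sex="total")
    )
    out = pd.concat([by_sex, totals], ignore_index=True).sort_values(
        ["year", "sex"]
    ).reset_index(drop=True)
    first_year = out["year"].min()
    base = out[out["year"] == first_year].set_index("sex")["expected_count"]
    out["fold_change"] = [
        row.expected_count / base[row.sex] if base.get(row.sex, 0) > 0 else float("nan")
        for row in out.itertuples()
    ]
    out["expected_count_rounded"] = out["expected_count"].round().astype(int)
    return out
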