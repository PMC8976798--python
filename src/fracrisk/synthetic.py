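"""Synthetic inputs with known ground truth.

Emulates a two-year multi-hospital hip-fracture survey so every pipeline
stage can be exercised and verified offline:

* a registry line-listing whose eligible records are Poisson draws per
  (sex, band) with mean rate × population × years, plus contaminant records
  (high-trauma, pathological, non-citizen, under-age, duplicate) drawn from
  the same age/sex structure so filters cannot succeed on demographics
  alone; every record carries a ground-truth eligibility label;
* Gompertz life tables, q(age) = 1 − exp(−a·e^{b·age});
* population pyramids growing geometrically per band.

Defaults mirror the published 2017–2018 Saudi survey structure (catchment
populations and observed band rates) so the generator's estimand matches
the incidence module's.  Ages are uniform within their band — the survey
reports only banded data, so no finer age structure is claimed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .hazard import LifeTable
from .registry import COLUMNS

__all__ = [
    "GeneratorConfig",
    "generate_registry",
    "generate_lifetable",
    "generate_pyramids",
    "simulate_all",
]

ICD_CODES = ["S72.0", "S72.1", "S72.2"]
# observed fracture-site split: femoral neck / pertrochanteric / subtrochanteric
ICD_PROBS = [0.43, 0.47, 0.10]

#: Gompertz defaults emulating a population whose mortality rises steeply
#: after 70: hazard h(age) = a·e^{b·age} with h(70) = 0.025 (women) and
#: 0.035 (men), doubling roughly every 4.6 years.  The log-slope 0.15/yr
#: deliberately exceeds the fracture hazard's (~0.08/yr in the bundled
#: survey rates) so the competing effect of mortality dominates at old age.
_B = 0.15
DEFAULT_GOMPERTZ = {
    "female": (0.025 * np.exp(-_B * 70), _B),
    "male": (0.035 * np.exp(-_B * 70), _B),
}

#: Per-band annual growth factors for the default pyramids: older bands grow
#: faster, emulating rapid population ageing.
DEFAULT_GROWTH = {45: 1.020, 50: 1.025, 55: 1.030, 60: 1.035,
                  65: 1.040, 70: 1.045, 75: 1.050, 80: 1.055}


def _default_true_rates() -> pd.DataFrame:
    t = datasets.survey_table()
    t["rate"] = t["events"] / (t["population"] * datasets.SURVEY_YEARS) * 1e5
    return t[["sex", "band_start", "band_end", "rate"]]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic survey.

    ``contamination`` maps contaminant kind to its proportion of the
    expected eligible count; ``true_rates`` / ``catchment_population`` are
    per (sex, band) frames as produced by the bundled survey defaults.
    """

    seed: int = 0
    true_rates: pd.DataFrame = field(default_factory=_default_true_rates)
    catchment_population: pd.DataFrame = field(
        default_factory=datasets.survey_population
    )
    years: float = datasets.SURVEY_YEARS
    survey_start: dt.date = dt.date(2017, 1, 1)
    survey_end: dt.date = dt.date(2018, 12, 31)
    contamination: dict = field(default_factory=lambda: {
        "high_trauma": 0.08, "pathological": 0.04, "non_citizen": 0.04,
        "under_age": 0.02, "duplicate": 0.02,
    })
    lifetable_params: dict = field(default_factory=lambda: dict(DEFAULT_GOMPERTZ))
    lifetable_ages: tuple = (40, 104)
    pyramid_growth: dict = field(default_factory=lambda: dict(DEFAULT_GROWTH))
    pyramid_base_year: int = 2015
    #: national scale-up of the catchment population for pyramid defaults
    pyramid_scale: float = 1 / datasets.CATCHMENT_FRACTION

    def __post_init__(self) -> None:
        for kind, p in self.contamination.items():
            if not 0 <= p <= 1:
                raise ValueError(f"contamination[{kind!r}] must be in [0, 1]")
        if (self.true_rates["rate"] < 0).any():
            raise ValueError("true rates must be non-negative")
        if self.years <= 0:
            raise ValueError("survey duration must be positive")


def _band_width(start: int, end: int, open_ended: bool) -> tuple[int, int]:
    # draw ages for the open-ended band from a 10-year span; the survey's
    # oldest observed ages ran to about 90
    return (start, start + 9) if open_ended else (start, end)


def generate_registry(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a line-listing and its ground-truth labels.

    Returns ``(records, labels)``; ``labels`` has one row per record with
    columns ``record_id, eligible, reason, sex, band_start`` where
    ``reason`` is the planted violation ('' for eligible records).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    spec = cfg.true_rates.merge(
        cfg.catchment_population, on=["sex", "band_start", "band_end"]
    )
    last_start = spec["band_start"].max()
    window_days = (cfg.survey_end - cfg.survey_start).days + 1

    rows: list[dict] = []
    labels: list[tuple] = []

    def add_record(sex, band_start, band_end, *, reason="", age=None,
                   mechanism="low_energy", pathological=False, citizen=True):
        lo, hi = _band_width(band_start, band_end, band_start == last_start)
        if age is None:
            age = int(rng.integers(lo, hi + 1))
        rid = f"P{len(rows):06d}"
        date = cfg.survey_start + dt.timedelta(days=int(rng.integers(window_days)))
        rows.append({
            "patient_id": rid,
            "age": age,
            "sex": sex,
            "admission_date": date,
            "icd10": ICD_CODES[rng.choice(len(ICD_CODES), p=ICD_PROBS)],
            "mechanism": mechanism,
            "pathological": pathological,
            "citizen": citizen,
            "hospital_id": f"H{int(rng.integers(1, 16)):02d}",
        })
        labels.append((rid, reason == "", reason, sex, band_start))

    n_eligible = 0
    for r in spec.itertuples():
        mean = r.rate * r.population * cfg.years / 1e5
        n = int(rng.poisson(mean))
        n_eligible += n
        for _ in range(n):
            add_record(r.sex, r.band_start, r.band_end)

    # contaminants share the eligible age/sex structure
    weights = (spec["rate"] * spec["population"]).to_numpy(float)
    weights = weights / weights.sum() if weights.sum() > 0 else None

    def draw_cell():
        i = rng.choice(len(spec), p=weights)
        r = spec.iloc[i]
        return r["sex"], int(r["band_start"]), int(r["band_end"])

    for kind, prop in cfg.contamination.items():
        n = int(rng.poisson(prop * n_eligible))
        for _ in range(n):
            sex, bs, be = draw_cell()
            if kind == "high_trauma":
                mech = ["road_traffic", "other_major_trauma"][int(rng.integers(2))]
                add_record(sex, bs, be, reason="high_trauma", mechanism=mech)
            elif kind == "pathological":
                add_record(sex, bs, be, reason="pathological", pathological=True)
            elif kind == "non_citizen":
                add_record(sex, bs, be, reason="non_citizen", citizen=False)
            elif kind == "under_age":
                age = int(rng.integers(20, spec["band_start"].min()))
                add_record(sex, bs, be, reason="under_age", age=age)
            elif kind == "duplicate":
                if n_eligible == 0:
                    continue
                src = rows[int(rng.integers(n_eligible))]
                dup = dict(src)
                # later readmission for the same fracture site
                days_left = (cfg.survey_end - src["admission_date"]).days
                dup["admission_date"] = src["admission_date"] + dt.timedelta(
                    days=int(rng.integers(1, max(2, days_left + 1)))
                )
                dup["admission_date"] = min(dup["admission_date"], cfg.survey_end)
                dup["hospital_id"] = f"H{int(rng.integers(1, 16)):02d}"
                rows.append(dup)
                labels.append((dup["patient_id"], False, "duplicate",
                               dup["sex"], None))
            else:
                raise ValueError(f"unknown contaminant kind {kind!r}")

    records = pd.DataFrame(rows, columns=COLUMNS)
    label_df = pd.DataFrame(
        labels, columns=["record_id", "eligible", "reason", "sex", "band_start"]
    )
    # shuffle so row order carries no information
    perm = rng.permutation(len(records))
    return (
        records.iloc[perm].reset_index(drop=True),
        label_df.iloc[perm].reset_index(drop=True),
    )


def generate_lifetable(cfg: GeneratorConfig, sex: str) -> LifeTable:
    """Gompertz life table: q(age) = 1 − exp(−a·e^{b·age})."""
    a, b = cfg.lifetable_params[sex]
    if a <= 0 or b < 0:
        raise ValueError("Gompertz parameters must be positive")
    lo, hi = cfg.lifetable_ages
    ages = np.arange(lo, hi + 1)
    q = -np.expm1(-a * np.exp(b * ages))
    if np.any(q[ages < 60] >= 1):
        raise ValueError("Gompertz parameters give q >= 1 before age 60")
    q = np.clip(q, 0, 1 - 1e-12)
    return LifeTable(sex, ages, q)


def generate_pyramids(cfg: GeneratorConfig, years: list[int]) -> pd.DataFrame:
    """Deterministic geometric growth per band from the base pyramid."""
    base = cfg.catchment_population.copy()
    base["population"] = base["population"] * cfg.pyramid_scale
    out = []
    for year in years:
        dt_years = year - cfg.pyramid_base_year
        for r in base.itertuples():
            g = cfg.pyramid_growth.get(int(r.band_start), 1.0)
            if g <= 0:
                raise ValueError("growth factors must be positive")
            out.append((
                year, r.sex, r.band_start, r.band_end,
                r.population * g ** dt_years,
            ))
    return pd.DataFrame(
        out, columns=["year", "sex", "band_start", "band_end", "population"]
    )


def simulate_all(cfg: GeneratorConfig, outdir) -> dict:
    """Materialise a complete fixture directory of pipeline inputs."""
    from pathlib import Path

    from .mof import default_ratio_table
    from .registry import write_linelisting

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, labels = generate_registry(cfg)
    write_linelisting(records, outdir / "registry.csv")
    labels.to_csv(outdir / "registry_labels.csv", index=False)
    lt_frames = []
    for sex in ("female", "male"):
        lt = generate_lifetable(cfg, sex)
        lt_frames.append(pd.DataFrame({"sex": sex, "age": lt.ages, "q": lt.q}))
    pd.concat(lt_frames).to_csv(outdir / "lifetable.csv", index=False)
    pyramids = generate_pyramids(cfg, [2015, 2020, 2030, 2040, 2050])
    pyramids.to_csv(outdir / "pyramids.csv", index=False)
    cfg.catchment_population.to_csv(outdir / "population.csv", index=False)
    default_ratio_table().to_csv(outdir / "mof_ratios.csv")
    return {
        "registry": outdir / "registry.csv",
        "labels": outdir / "registry_labels.csv",
        "lifetable": outdir / "lifetable.csv",
        "pyramids": outdir / "pyramids.csv",
        "population": outdir / "population.csv",
        "mof_ratios": outdir / "mof_ratios.csv",
    }
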