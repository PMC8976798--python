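"""Bundled reference inputs.

The package ships the published 2017–2018 Saudi multi-centre hip-fracture
survey aggregates (catchment population at risk and low-energy hip-fracture
counts by sex and 5-year age band) so that the incidence pipeline can be run
without any external files.  The survey covered 15 hospitals over two years
with an estimated 12.82% national catchment; counts are first low-energy hip
fractures (ICD-10 S72.0–S72.2) in Saudi citizens aged 45+.
"""

from __future__ import annotations

import pandas as pd

#: Survey observation time in years.
SURVEY_YEARS = 2.0

#: Estimated share of the national 45+ population covered by the surveyed
#: hospitals' catchment.
CATCHMENT_FRACTION = 0.1282

_BAND_STARTS = [45, 50, 55, 60, 65, 70, 75, 80]

# population at risk (persons, 2017) and fracture counts (2017/2018)
_MALE_POP = [71733, 57212, 44624, 32327, 19670, 14356, 9358, 11173]
_FEMALE_POP = [67888, 54091, 40987, 30246, 20869, 14739, 9552, 11967]
_MALE_EVENTS = [4, 21, 19, 24, 31, 46, 58, 93]
_FEMALE_EVENTS = [3, 18, 32, 33, 48, 65, 72, 117]


def survey_counts() -> pd.DataFrame:
    """Fracture counts by sex and 5-year band.

    Returns a DataFrame with columns ``sex`` ('male'/'female'),
    ``band_start``, ``band_end`` (inclusive; the last band is open-ended and
    carries ``band_end`` 84 by convention) and ``events``.
    """
    rows = []
    for sex, events in (("male", _MALE_EVENTS), ("female", _FEMALE_EVENTS)):
        for start, n in zip(_BAND_STARTS, events):
            rows.append((sex, start, start + 4, n))
    return pd.DataFrame(rows, columns=["sex", "band_start", "band_end", "events"])


def survey_population() -> pd.DataFrame:
    """Catchment population at risk by sex and 5-year band (persons)."""
    rows = []
    for sex, pops in (("male", _MALE_POP), ("female", _FEMALE_POP)):
        for start, n in zip(_BAND_STARTS, pops):
            rows.append((sex, start, start + 4, n))
    return pd.DataFrame(rows, columns=["sex", "band_start", "band_end", "population"])


def survey_table() -> pd.DataFrame:
    """Counts and population merged into one frame."""
    return survey_counts().merge(
        survey_population(), on=["sex", "band_start", "band_end"]
    )
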