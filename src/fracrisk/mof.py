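"""Major-osteoporotic-fracture (MOF) hazard imputed from hip hazard.

Where direct incidence for clinical spine, forearm and humerus fractures is
unavailable, the composite first-MOF hazard is imputed by multiplying the
hip hazard by an age- and sex-specific MOF:hip incidence ratio, following
the common practice of borrowing the Swedish (Malmö) fracture pattern.  The
published Malmö ratio values are not reproduced here: the bundled default
table is an illustrative synthetic one with the characteristic shape (large
ratios at 50, declining towards ~1.5 in the oldest ages, higher in women),
and any user table can be supplied as CSV (``sex,age,ratio``).

Ratios apply to hazards (not probabilities) and are interpolated linearly
between age anchors, constant beyond the ends.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .hazard import HazardGrid

__all__ = ["RatioTable", "default_ratio_table", "impute_mof_hazard"]


@dataclass(frozen=True)
class RatioTable:
    """MOF-to-hip incidence ratios at age anchors, per sex."""

    anchors: dict  # sex -> (ages ndarray, ratios ndarray)

    def __post_init__(self) -> None:
        checked = {}
        for sex, (ages, ratios) in self.anchors.items():
            ages = np.asarray(ages, float)
            ratios = np.asarray(ratios, float)
            if ages.shape != ratios.shape or ages.ndim != 1:
                raise ValueError("ages and ratios must be equal-length 1-d arrays")
            if np.any(np.diff(ages) <= 0):
                raise ValueError("age anchors must be strictly increasing")
            if np.any(ratios <= 0):
                raise ValueError("ratios must be positive")
            checked[sex] = (ages, ratios)
        object.__setattr__(self, "anchors", checked)

    def ratio(self, sex: str, age) -> np.ndarray:
        """Linear interpolation between anchors; constant beyond the ends."""
        if sex not in self.anchors:
            raise KeyError(f"no MOF:hip ratios for sex {sex!r}")
        ages, ratios = self.anchors[sex]
        return np.interp(np.asarray(age, float), ages, ratios)

    @classmethod
    def from_csv(cls, path) -> "RatioTable":
        df = pd.read_csv(path)
        anchors = {
            sex: (grp.sort_values("age")["age"].to_numpy(),
                  grp.sort_values("age")["ratio"].to_numpy())
            for sex, grp in df.groupby("sex")
        }
        return cls(anchors)

    def to_csv(self, path) -> None:
        rows = [
            (sex, a, r)
            for sex, (ages, ratios) in self.anchors.items()
            for a, r in zip(ages, ratios)
        ]
        pd.DataFrame(rows, columns=["sex", "age", "ratio"]).to_csv(path, index=False)


def default_ratio_table() -> RatioTable:
    """Illustrative synthetic MOF:hip ratio table.

    Shaped like published Western ratio patterns (forearm and spine dominate
    at younger ages, hip at the oldest) but NOT the published Malmö values;
    replace via CSV for production use.
    """
    ages = np.array([50, 55, 60, 65, 70, 75, 80, 85], float)
    return RatioTable({
        "female": (ages, np.array([7.0, 6.0, 5.0, 4.0, 3.0, 2.2, 1.8, 1.5])),
        "male": (ages, np.array([4.5, 4.0, 3.3, 2.8, 2.3, 1.9, 1.6, 1.4])),
    })


def impute_mof_hazard(hip: HazardGrid, ratios: RatioTable) -> HazardGrid:
    """Pointwise h_mof(age) = h_hip(age) × ratio(age, sex) on the hip grid.

    The output grid shares ages and step with the input; the death hazard is
    carried through unchanged.
    """
    r = ratios.ratio(hip.sex, hip.midpoints)
    return replace(hip, h_frac=hip.h_frac * r)
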