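"""Paleotemperature curves: age vs. temperature with linear interpolation.

A curve is a set of (age, temperature) samples with ages in Ma before
present, strictly increasing. Queries between samples are linearly
interpolated; queries outside the sampled range are clamped to the
endpoint values, so T(t) is defined on all of [0, inf).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PaleoCurve:
    """Piecewise-linear paleotemperature history T(t).

    Parameters
    ----------
    ages:
        Sample ages in Ma before present, strictly increasing.
    temps:
        Temperatures in deg C at the sample ages.
    """

    ages: np.ndarray
    temps: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        if ages.ndim != 1 or ages.shape != temps.shape:
            raise ValueError("ages and temps must be 1-D arrays of equal length")
        if ages.size < 2:
            raise ValueError("a paleotemperature curve needs at least 2 samples")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("curve ages must be strictly increasing")
        if not (np.all(np.isfinite(ages)) and np.all(np.isfinite(temps))):
            raise ValueError("curve samples must be finite")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "temps", temps)

    def at(self, t):
        """Temperature at age ``t`` (Ma before present); clamped, vectorized."""
        return np.interp(t, self.ages, self.temps)

    def __call__(self, t):
        return self.at(t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_ma": self.ages, "temp_c": self.temps})

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PaleoCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(df["age_ma"].to_numpy(), df["temp_c"].to_numpy())


def make_paleo_curve(
    t0_temp: float, slope: float, t_max: float, n_points: int = 101
) -> PaleoCurve:
    """Linear-trend curve T(t) = t0_temp + slope * t sampled on [0, t_max].

    With slope > 0 the past is warmer than the present, i.e. a world that
    cooled toward the present (a Cenozoic-style trend).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    ages = np.linspace(0.0, float(t_max), int(n_points))
    return PaleoCurve(ages, t0_temp + slope * ages)
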