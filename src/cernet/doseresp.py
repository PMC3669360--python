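"""IC50 estimation from relative survival curves and the resistance index.

A drug-sensitivity assay measures viability (fraction of untreated
control) over an increasing concentration series, e.g. cisplatin from
0.5 to 128 mg/L. IC50 is the concentration producing 50% growth
inhibition. Two estimators are offered:

* ``interpolation`` (default) — log2-linear interpolation between the two
  tested concentrations bracketing viability 0.5; assumption-free.
* ``four_param_logistic`` — least-squares fit of
  v(c) = bottom + (top - bottom) / (1 + (c/ec50)^hill); the IC50 is the
  concentration at the response midway between fitted top and bottom,
  i.e. the fitted ec50.

The fold-resistance index is the ratio of the resistant line's IC50 to
the parental line's, reported to one decimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class DoseResponseCurve:
    """Mean relative survival over a strictly increasing dose series."""

    concentrations: np.ndarray
    viabilities: np.ndarray
    replicates: pd.DataFrame | None = None  # optional dose x replicate table
    label: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viabilities = np.asarray(self.viabilities, dtype=float)
        if self.concentrations.size != self.viabilities.size:
            raise ValueError("concentration and viability lengths differ")
        if self.concentrations.size < 2:
            raise ValueError("need >= 2 concentrations")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.viabilities < 0) or np.any(self.viabilities > 1.5):
            raise ValueError("viabilities outside [0, 1.5]")


def _four_param_logistic(c, top, bottom, ec50, hill):
    return bottom + (top - bottom) / (1.0 + (c / ec50) ** hill)


def estimate_ic50(curve: DoseResponseCurve, method: str = "interpolation") -> float:
    """Concentration at 50% inhibition, by interpolation or a 4PL fit."""
    c, v = curve.concentrations, curve.viabilities
    if c.size < 3:
        raise ValueError("need >= 3 concentrations to estimate an IC50")
    if np.any(np.diff(v) > 0.05):
        warnings.warn("mean response is non-monotone beyond tolerance")

    if method == "interpolation":
        exact = np.nonzero(v == 0.5)[0]
        if exact.size:
            return float(c[exact[0]])
        for i in range(c.size - 1):
            v1, v2 = v[i], v[i + 1]
            if (v1 - 0.5) * (v2 - 0.5) < 0:
                lc1, lc2 = np.log2(c[i]), np.log2(c[i + 1])
                frac = (v1 - 0.5) / (v1 - v2)
                return float(2.0 ** (lc1 + frac * (lc2 - lc1)))
        raise ValueError("viability never crosses 0.5 within the tested range")

    if method == "four_param_logistic":
        p0 = [float(v.max()), float(v.min()), float(np.exp(np.mean(np.log(c)))), 1.0]
        bounds = ([0.0, 0.0, c.min() / 100.0, 0.1], [1.5, 1.5, c.max() * 100.0, 10.0])
        try:
            popt, _ = curve_fit(
                _four_param_logistic, c, v, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError as exc:
            raise RuntimeError("4PL fit failed to converge") from exc
        return float(popt[2])

    raise ValueError(f"unknown method {method!r}")


def resistance_index(ic50_resistant: float, ic50_parental: float) -> float:
    """Fold resistance = IC50(resistant) / IC50(parental), one decimal."""
    if ic50_parental <= 0 or ic50_resistant <= 0:
        raise ValueError("IC50 values must be positive")
    return round(ic50_resistant / ic50_parental, 1)


def read_viability_csv(path: str | Path, normalize: bool = True) -> dict[str, DoseResponseCurve]:
    """Long-format CSV with columns cell_line, concentration, viability.

    Replicate measurements repeat (cell_line, concentration) rows and are
    averaged. A concentration-0 row, when present, is the untreated
    control: all viabilities are divided by its mean and the row dropped.
    """
    table = pd.read_csv(path)
    required = {"cell_line", "concentration", "viability"}
    if not required.issubset(table.columns):
        raise ValueError(f"viability CSV needs columns {sorted(required)}")
    curves: dict[str, DoseResponseCurve] = {}
    for line, sub in table.groupby("cell_line"):
        means = (
            sub.groupby("concentration")["viability"].mean().sort_index()
        )
        if normalize and 0.0 in means.index:
            control = means.loc[0.0]
            means = means.drop(index=0.0) / control
        reps = sub.pivot_table(
            index="concentration", columns=sub.groupby(
                ["concentration"]).cumcount(), values="viability"
        )
        curves[str(line)] = DoseResponseCurve(
            concentrations=means.index.to_numpy(dtype=float),
            viabilities=np.clip(means.to_numpy(dtype=float), 0.0, 1.5),
            replicates=reps,
            label=str(line),
        )
    return curves
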