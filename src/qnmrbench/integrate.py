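"""Region integration and concentration determination.

Two routes turn a peak area into a concentration:

* **internal referencing** against the in-sample TSP singlet,
  ``Cx = (Ix · Cs · Ns) / (Is · Nx)``, with Nx/Ns the proton counts behind
  the analyte and reference signals;
* **external calibration**: an ordinary least-squares line
  ``Ix = a·Cx + b`` over the five calibration solutions, inverted as
  ``Cx = (Ix − b)/a``.

Composite quantities mirror the benchmark's chemistry: the conserved
creatine+creatinine sum (one combined region), the lactate+threonine sum,
cysteine estimated as 2× cystine, and fructose by difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .spectrum import Spectrum1D, region_indices

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "integrate_region",
    "quantify_internal_tsp",
    "fit_calibration_curve",
    "quantify_external",
    "derive_composites",
]

#: A calibration curve below this R² (or with non-positive slope) is unusable.
R2_USABILITY_THRESHOLD = 0.95


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS fit of area vs concentration for one quantity."""

    metabolite: str
    a: float            # slope, area per µM
    b: float            # intercept, area
    r_squared: float
    n_points: int = 5
    usable: bool = True


@dataclass
class QuantResult:
    """Per-quantity, per-strategy replicate concentrations with flags."""

    metabolite: str
    strategy: str
    concentrations: list[Optional[float]] = field(default_factory=list)  # µM, per replicate
    quantifiable: bool = True
    negative_clamped: bool = False
    curve_unusable: bool = False

    @property
    def determined(self) -> bool:
        """False for ND quantities (no usable value)."""
        return (
            self.quantifiable
            and not self.curve_unusable
            and all(c is not None for c in self.concentrations)
        )

    def values(self) -> np.ndarray:
        if not self.determined:
            raise ValueError(f"{self.metabolite}/{self.strategy}: not determined")
        return np.asarray(self.concentrations, dtype=float)


def integrate_region(spectrum: Spectrum1D, region: tuple[float, float]) -> float:
    """Trapezoidal integral over the inclusive region, in area units (ppm·intensity).

    Negative areas are possible (baseline errors) and are not clamped here.
    """
    idx = region_indices(spectrum, *region)
    if idx.size < 2:
        return 0.0
    x = spectrum.ppm_axis[idx]
    y = spectrum.intensity[idx]
    # axis decreasing: integrate over |Δppm|
    return float(np.trapezoid(y, -x))


def quantify_internal_tsp(Ix: float, Nx: int, Is: float, Ns: int, Cs: float) -> float:
    """Concentration from internal referencing: Cx = (Ix·Cs·Ns)/(Is·Nx)."""
    if Is <= 0:
        raise ValueError("reference integral Is must be > 0")
    if Cs <= 0:
        raise ValueError("reference concentration Cs must be > 0")
    if Nx < 1 or Ns < 1:
        raise ValueError("proton counts must be >= 1")
    # evaluated as a ratio first so that Ix == Is gives Cs·Ns/Nx exactly
    return (Ix / Is) * (Cs * Ns) / Nx


def fit_calibration_curve(
    areas,
    concentrations,
    metabolite: str = "",
    r2_threshold: float = R2_USABILITY_THRESHOLD,
) -> CalibrationCurve:
    """OLS line (with intercept) of area vs concentration over 5 solutions.

    The curve is flagged unusable when the slope is non-positive or R² falls
    below ``r2_threshold`` — the numeric rule standing in for an operator
    discarding a visibly non-proportional curve.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.size != y.size:
        raise ValueError("areas and concentrations must pair up")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    a, b = np.polyfit(x, y, 1)
    fitted = a * x + b
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = float(np.clip(r2, 0.0, 1.0))
    usable = bool(a > 0) and bool(r2 >= r2_threshold)
    return CalibrationCurve(
        metabolite=metabolite, a=float(a), b=float(b), r_squared=r2,
        n_points=int(x.size), usable=usable,
    )


def quantify_external(Ix: float, curve: CalibrationCurve) -> tuple[float, bool]:
    """Invert the calibration line; negative results clamp to 0 with a flag.

    Returns ``(Cx, negative_clamped)``.
    """
    if not curve.usable:
        raise ValueError(f"{curve.metabolite}: calibration curve flagged unusable")
    cx = (Ix - curve.b) / curve.a
    if cx < 0:
        return 0.0, True
    return float(cx), False


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------

#: Composite sum quantities: name -> (constituents, combined region).
COMPOSITE_SUMS = {
    "creatine+creatinine": (("creatine", "creatinine"), (3.030, 3.060)),
    "lactic acid+threonine": (("lactic acid", "threonine"), (1.300, 1.345)),
}


def derive_composites(results: dict[str, QuantResult]) -> dict[str, QuantResult]:
    """Extend a per-quantity result set with the derived quantities.

    * ``cysteine_est`` = 2 × cystine (µM, dimer stoichiometry);
    * ``fructose_est`` = (glucose+fructose) − glucose, per replicate —
      difference results may be negative and keep their sign (flagged only).

    Sum composites (creatine+creatinine, lactate+threonine) are quantified
    upstream from one combined region each, not derived by adding two
    separate quantifications, and therefore are expected to already be
    present in ``results``.
    """
    out = dict(results)
    cystine = results.get("cystine")
    if cystine is not None and cystine.determined:
        out["cysteine_est"] = QuantResult(
            metabolite="cysteine_est",
            strategy=cystine.strategy,
            concentrations=[2.0 * c for c in cystine.values()],
        )
    both = results.get("glucose+fructose")
    gluc = results.get("glucose")
    if both is not None and gluc is not None and both.determined and gluc.determined:
        diff = both.values() - gluc.values()
        out["fructose_est"] = QuantResult(
            metabolite="fructose_est",
            strategy=both.strategy,
            concentrations=[float(d) for d in diff],
            negative_clamped=False,  # difference keeps its sign for diagnostics
        )
    return out
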