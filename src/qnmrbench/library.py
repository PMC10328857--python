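"""The synthetic-urine peak library.

Thirty-two metabolites (plus cystine, the dimerization product of cysteine,
and the TSP reference) are described as one or more multiplets: a centre
chemical shift, line offsets/weights, and the number of protons behind the
signal.  Each metabolite carries a default quantification region, its urine
concentration and a five-level calibration ladder.

Chemical shifts and multiplicities are plausible literature-style values for
buffered aqueous solutions near pH 7; they are shipped as an editable table
(:func:`library_to_frame` / :func:`library_from_frame`).  What the benchmark
actually exercises is the *overlap structure*, which is hard-coded:

* the acetic-acid singlet at 1.92 ppm sits inside the lysine multiplet span
  (1.87–1.97 ppm);
* lactate and threonine methyl doublets share the 1.300–1.345 ppm region;
* creatine (3.040 s) and creatinine (3.050 s) share the 3.03–3.06 ppm region
  and interconvert with a conserved sum;
* cysteine is fully dimerized to cystine in solution;
* the glucose doublet used for quantification lies at 4.64 ppm, inside the
  residual-water presaturation notch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .spectrum import DEFAULT_WINDOW

__all__ = [
    "Line",
    "Multiplet",
    "MetaboliteDef",
    "Library",
    "default_library",
    "perturb_regions",
    "library_to_frame",
    "library_from_frame",
]

#: Default line full width at half maximum: 1.2 Hz = 0.002 ppm at 600 MHz.
DEFAULT_FWHM = 0.002
#: Default Lorentzian fraction of the pseudo-Voigt lineshape.
DEFAULT_ETA = 0.8
#: Margin added beyond the outermost multiplet line when deriving a
#: quantification region (ppm).
REGION_MARGIN = 0.005
#: TSP reference concentration in every sample (µM).  Not a measured value;
#: the benchmark's conclusions are invariant to it.
TSP_CONCENTRATION = 500.0


@dataclass(frozen=True)
class Line:
    """One line of a multiplet: offset from the centre and intensity share."""

    offset: float  # ppm relative to multiplet centre
    weight: float  # fraction of the multiplet intensity


@dataclass
class Multiplet:
    center: float                  # ppm
    lines: list[Line]
    n_protons: int
    default_fwhm: float = DEFAULT_FWHM
    default_eta: float = DEFAULT_ETA

    def __post_init__(self) -> None:
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")
        if self.default_fwhm <= 0:
            raise ValueError("default_fwhm must be > 0")
        total = sum(line.weight for line in self.lines)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"line weights must sum to 1, got {total}")

    @property
    def line_positions(self) -> np.ndarray:
        return np.asarray([self.center + line.offset for line in self.lines])

    def span(self) -> tuple[float, float]:
        pos = self.line_positions
        return float(pos.min()), float(pos.max())

    def default_region(self, margin: float = REGION_MARGIN) -> tuple[float, float]:
        lo, hi = self.span()
        return lo - margin, hi + margin


@dataclass
class MetaboliteDef:
    name: str
    multiplets: list[Multiplet]
    quant_region: tuple[float, float]
    urine_concentration: float                  # µM
    calibration_concentrations: list[float]     # 5 values, µM
    preferred_multiplet: int = 0
    interconversion_partner: Optional[str] = None
    dimerizes_to: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.multiplets:
            raise ValueError(f"{self.name}: at least one multiplet required")
        if self.urine_concentration <= 0:
            raise ValueError(f"{self.name}: concentrations must be > 0")
        if len(self.calibration_concentrations) != 5:
            raise ValueError(f"{self.name}: exactly 5 calibration levels required")
        if any(c <= 0 for c in self.calibration_concentrations):
            raise ValueError(f"{self.name}: calibration concentrations must be > 0")
        lo, hi = self.quant_region
        if lo >= hi:
            raise ValueError(f"{self.name}: quant_region lo must be < hi")
        if not (0 <= self.preferred_multiplet < len(self.multiplets)):
            raise ValueError(f"{self.name}: preferred_multiplet out of range")

    @property
    def preferred(self) -> Multiplet:
        return self.multiplets[self.preferred_multiplet]


@dataclass
class Library:
    metabolites: list[MetaboliteDef]
    tsp: MetaboliteDef
    window: tuple[float, float] = DEFAULT_WINDOW  # (high, low) ppm

    def __post_init__(self) -> None:
        names = [m.name for m in self.metabolites]
        if len(set(names)) != len(names):
            raise ValueError("metabolite names must be unique")
        self.validate()

    def validate(self) -> None:
        hi, lo = self.window
        for m in [*self.metabolites, self.tsp]:
            rlo, rhi = m.quant_region
            if rlo >= rhi:
                raise ValueError(f"{m.name}: empty quantification region")
            if rlo < lo or rhi > hi:
                raise ValueError(f"{m.name}: region outside spectral window")

    def __getitem__(self, name: str) -> MetaboliteDef:
        if name == self.tsp.name:
            return self.tsp
        for m in self.metabolites:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.metabolites]

    def urine_truth(self) -> dict[str, float]:
        """Nominal (gravimetric) urine concentrations, µM."""
        return {m.name: m.urine_concentration for m in self.metabolites}

    def calibration_truth(self, level: int) -> dict[str, float]:
        """Nominal concentrations in calibration solution ``level`` (1-based)."""
        return {m.name: m.calibration_concentrations[level - 1] for m in self.metabolites}


# ---------------------------------------------------------------------------
# multiplet pattern helpers
# ---------------------------------------------------------------------------

def _singlet() -> list[Line]:
    return [Line(0.0, 1.0)]


def _doublet(j: float) -> list[Line]:
    return [Line(-j / 2, 0.5), Line(+j / 2, 0.5)]


def _triplet(j: float) -> list[Line]:
    return [Line(-j, 0.25), Line(0.0, 0.5), Line(+j, 0.25)]


def _multiplet5(half_span: float, weights=(0.1, 0.2, 0.4, 0.2, 0.1)) -> list[Line]:
    offs = np.linspace(-half_span, half_span, 5)
    return [Line(float(o), float(w)) for o, w in zip(offs, weights)]


def _multiplet6(half_span: float) -> list[Line]:
    offs = np.linspace(-half_span, half_span, 6)
    w = 1.0 / 6.0
    return [Line(float(o), w) for o in offs]


_J7 = 7.0 / 600.0   # a typical 7-Hz coupling at 600 MHz, in ppm
_J66 = 6.6 / 600.0


# ---------------------------------------------------------------------------
# the default synthetic urine
# ---------------------------------------------------------------------------

# name -> (urine µM, [(center, lines, nH), ...], preferred index)
# The first multiplet is the preferred (quantified) one unless stated.
_DEFAULT_TABLE: list[tuple[str, float, list[tuple[float, list[Line], int]], int]] = [
    ("1-methylhistidine",     900.0, [(3.700, _singlet(), 3)], 0),
    ("2-hydroxybutyric acid", 130.0, [(0.900, _triplet(_J7), 3)], 0),
    ("3-methylhistidine",     700.0, [(3.740, _singlet(), 3)], 0),
    ("acetic acid",           480.0, [(1.920, _singlet(), 3)], 0),
    ("alanine",               350.0, [(1.480, _doublet(_J7), 3)], 0),
    ("allantoin",            2200.0, [(5.400, _singlet(), 1)], 0),
    ("citric acid",          3500.0, [(2.610, [Line(-0.065, 0.25), Line(-0.039, 0.25),
                                               Line(0.039, 0.25), Line(0.065, 0.25)], 4)], 0),
    ("creatine",             4200.0, [(3.040, _singlet(), 3),
                                      (3.940, _singlet(), 2)], 0),
    ("creatinine",           7959.0, [(3.050, _singlet(), 3),
                                      (4.060, _singlet(), 2)], 0),
    ("dimethylamine",         340.0, [(2.720, _singlet(), 6)], 0),
    ("ethanolamine",          600.0, [(3.150, _triplet(_J66), 2)], 0),
    ("formic acid",           220.0, [(8.460, _singlet(), 1)], 0),
    ("fructose",               64.0, [(3.520, _multiplet5(0.030), 2)], 0),
    ("glucose",              4000.0, [(4.640, _doublet(8.0 / 600.0), 1),
                                      (3.440, _multiplet5(0.040,
                                               (0.15, 0.2, 0.3, 0.2, 0.15)), 5)], 0),
    ("glutamine",             450.0, [(2.450, _multiplet5(0.030), 2)], 0),
    ("glycerol",             1000.0, [(3.770, _multiplet5(0.008), 1),
                                      (3.555, _multiplet5(0.020), 4)], 0),
    ("glycine",              1100.0, [(3.590, _singlet(), 2)], 0),
    ("guanidoacetic acid",    620.0, [(3.800, _singlet(), 2)], 0),
    ("hippuric acid",        2100.0, [(7.830, _doublet(_J7), 2),
                                      (7.630, _triplet(_J7), 1),
                                      (7.550, _triplet(_J7), 2)], 0),
    ("histidine",             430.0, [(7.900, _singlet(), 1)], 0),
    ("indoxylsulfate",        800.0, [(7.700, _doublet(_J7), 1)], 0),
    ("isocitric acid",       1300.0, [(2.950, _multiplet5(0.020), 2)], 0),
    ("lactic acid",          1400.0, [(1.331, _doublet(_J7), 3),
                                      (4.110, _multiplet5(0.015), 1)], 0),
    ("lysine",                720.0, [(1.920, _multiplet6(0.050), 2),
                                      (3.010, _triplet(_J7), 2)], 0),
    ("myo-inositol",         1200.0, [(4.050, _triplet(_J7 * 0.8), 1),
                                      (3.630, _multiplet5(0.020), 4)], 0),
    ("phenylacetylglutamine", 920.0, [(7.400, _multiplet5(0.040), 5)], 0),
    ("pyroglutamic acid",    1500.0, [(4.300, _multiplet5(0.015), 1),
                                      (2.400, _multiplet5(0.030), 2)], 0),
    ("serine",                900.0, [(3.950, _triplet(_J66), 2)], 0),
    ("threonine",            1100.0, [(1.316, _doublet(_J66), 3),
                                      (4.250, _multiplet5(0.010), 1)], 0),
    ("trigonelline",          510.0, [(9.120, _singlet(), 1),
                                      (8.830, _multiplet5(0.010), 2)], 0),
    ("trimethylamine-N-oxide", 2400.0, [(3.250, _singlet(), 9)], 0),
    ("cysteine",              150.0, [(3.000, _doublet(_J66), 2)], 0),
    # dimerization product: nominal concentration is cysteine/2 (the
    # gravimetric cysteine arrives in solution fully dimerized).
    ("cystine",                75.0, [(3.390, _doublet(_J66), 2)], 0),
]

#: Regions shared by the documented overlap pairs (lo, hi) ppm.
SHARED_REGIONS = {
    "creatine": (3.030, 3.060),
    "creatinine": (3.030, 3.060),
    "lactic acid": (1.300, 1.345),
    "threonine": (1.300, 1.345),
}

#: Global calibration bounds, µM (0.1–12 mM).
CAL_MIN, CAL_MAX = 100.0, 12000.0


def _calibration_ladder(urine_um: float, perm: np.ndarray) -> list[float]:
    """Five-point geometric ladder around the urine level, permuted.

    The ladder spans 0.4×–5× the urine concentration, clipped to the global
    0.1–12 mM range.  Each metabolite's levels are assigned to the five
    calibration solutions in a metabolite-specific permutation so that
    co-resonant species are decorrelated across solutions.
    """
    lo = max(CAL_MIN, 0.4 * urine_um)
    hi = min(CAL_MAX, 5.0 * urine_um)
    if hi <= lo:  # very dilute metabolite: ladder hugs the global floor
        hi = lo * 3.0
    ladder = np.geomspace(lo, hi, 5)
    return [float(ladder[perm[i]]) for i in range(5)]


def default_library() -> Library:
    """The default 32-metabolite synthetic urine plus cystine and TSP."""
    rng = np.random.default_rng(20230707)  # fixed: the library is a constant
    metabolites: list[MetaboliteDef] = []
    for name, urine_um, mspecs, preferred in _DEFAULT_TABLE:
        multiplets = [Multiplet(center=c, lines=lines, n_protons=nh)
                      for c, lines, nh in mspecs]
        perm = rng.permutation(5)
        if name == "cystine":
            # cystine tracks the cysteine ladder (dimer of the weighed-in
            # cysteine): same permutation, half the concentration.
            cys = next(m for m in metabolites if m.name == "cysteine")
            cal = [c / 2.0 for c in cys.calibration_concentrations]
        else:
            cal = _calibration_ladder(urine_um, perm)
        region = SHARED_REGIONS.get(name) or multiplets[preferred].default_region()
        metabolites.append(
            MetaboliteDef(
                name=name,
                multiplets=multiplets,
                quant_region=region,
                urine_concentration=urine_um,
                calibration_concentrations=cal,
                preferred_multiplet=preferred,
            )
        )
    by_name = {m.name: m for m in metabolites}
    by_name["creatine"].interconversion_partner = "creatinine"
    by_name["creatinine"].interconversion_partner = "creatine"
    by_name["cysteine"].dimerizes_to = "cystine"

    # pin the global calibration range of the 32 weighed metabolites exactly
    # to 0.1–12 mM (cystine is a derived entry at half the cysteine ladder)
    weighed = [m for m in metabolites if m.name != "cystine"]
    all_cal = np.concatenate([m.calibration_concentrations for m in weighed])
    lowest = min(weighed, key=lambda m: min(m.calibration_concentrations))
    highest = max(weighed, key=lambda m: max(m.calibration_concentrations))
    _pin(lowest, min(all_cal), CAL_MIN)
    _pin(highest, max(all_cal), CAL_MAX)

    tsp = MetaboliteDef(
        name="TSP",
        multiplets=[Multiplet(center=0.0, lines=_singlet(), n_protons=9)],
        quant_region=(-0.015, 0.015),
        urine_concentration=TSP_CONCENTRATION,
        calibration_concentrations=[TSP_CONCENTRATION] * 5,
    )
    return Library(metabolites=metabolites, tsp=tsp)


def _pin(metabolite: MetaboliteDef, old: float, new: float) -> None:
    cal = metabolite.calibration_concentrations
    for i, c in enumerate(cal):
        if c == old:
            cal[i] = new
            return


# ---------------------------------------------------------------------------
# operator simulation
# ---------------------------------------------------------------------------

def perturb_regions(
    library: Library,
    operator_seed: int,
    boundary_sd: float = 0.003,
    alt_multiplet_prob: float = 0.15,
    max_retries: int = 100,
) -> Library:
    """Simulate an operator's independent choice of integration regions.

    Each quantification-region boundary is jittered with seeded Gaussian noise
    of standard deviation ``boundary_sd``; with probability
    ``alt_multiplet_prob`` the operator instead quantifies another multiplet of
    the same metabolite (region re-derived around its lines).  All library
    invariants are preserved.
    """
    if boundary_sd < 0:
        raise ValueError("boundary_sd must be >= 0")
    rng = np.random.default_rng(operator_seed)
    out = copy.deepcopy(library)
    hi_w, lo_w = out.window
    for m in out.metabolites:
        if len(m.multiplets) > 1 and rng.random() < alt_multiplet_prob:
            choices = [i for i in range(len(m.multiplets)) if i != m.preferred_multiplet]
            m.preferred_multiplet = int(rng.choice(choices))
            m.quant_region = m.preferred.default_region()
        lo, hi = m.quant_region
        for _ in range(max_retries):
            new_lo = lo + rng.normal(0.0, boundary_sd) if boundary_sd else lo
            new_hi = hi + rng.normal(0.0, boundary_sd) if boundary_sd else hi
            new_lo = max(new_lo, lo_w)
            new_hi = min(new_hi, hi_w)
            if new_lo < new_hi:
                m.quant_region = (new_lo, new_hi)
                break
        else:
            raise RuntimeError(f"{m.name}: could not draw a valid region")
    out.validate()
    return out


# ---------------------------------------------------------------------------
# serialization as an editable table
# ---------------------------------------------------------------------------

def library_to_frame(library: Library) -> pd.DataFrame:
    """One row per multiplet; offsets/weights as ';'-joined number lists."""
    rows = []
    for m in [*library.metabolites, library.tsp]:
        for i, mult in enumerate(m.multiplets):
            rows.append(
                {
                    "metabolite": m.name,
                    "multiplet_index": i,
                    "center_ppm": mult.center,
                    "line_offsets": ";".join(f"{l.offset:.17g}" for l in mult.lines),
                    "line_weights": ";".join(f"{l.weight:.17g}" for l in mult.lines),
                    "n_protons": mult.n_protons,
                    "fwhm_ppm": mult.default_fwhm,
                    "eta": mult.default_eta,
                    "preferred": int(i == m.preferred_multiplet),
                    "region_lo": m.quant_region[0],
                    "region_hi": m.quant_region[1],
                    "urine_uM": m.urine_concentration,
                    "calibration_uM": ";".join(
                        f"{c:.17g}" for c in m.calibration_concentrations
                    ),
                    "interconversion_partner": m.interconversion_partner or "",
                    "dimerizes_to": m.dimerizes_to or "",
                }
            )
    return pd.DataFrame(rows)


def library_from_frame(frame: pd.DataFrame) -> Library:
    metabolites: list[MetaboliteDef] = []
    tsp: Optional[MetaboliteDef] = None
    for name, group in frame.groupby("metabolite", sort=False):
        group = group.sort_values("multiplet_index")
        multiplets = []
        for _, row in group.iterrows():
            offsets = [float(v) for v in str(row["line_offsets"]).split(";")]
            weights = [float(v) for v in str(row["line_weights"]).split(";")]
            multiplets.append(
                Multiplet(
                    center=float(row["center_ppm"]),
                    lines=[Line(o, w) for o, w in zip(offsets, weights)],
                    n_protons=int(row["n_protons"]),
                    default_fwhm=float(row["fwhm_ppm"]),
                    default_eta=float(row["eta"]),
                )
            )
        first = group.iloc[0]
        preferred = int(group["preferred"].to_numpy().argmax())
        met = MetaboliteDef(
            name=str(name),
            multiplets=multiplets,
            quant_region=(float(first["region_lo"]), float(first["region_hi"])),
            urine_concentration=float(first["urine_uM"]),
            calibration_concentrations=[
                float(v) for v in str(first["calibration_uM"]).split(";")
            ],
            preferred_multiplet=preferred,
            interconversion_partner=str(first["interconversion_partner"]) or None,
            dimerizes_to=str(first["dimerizes_to"]) or None,
        )
        if met.name == "TSP":
            tsp = met
        else:
            metabolites.append(met)
    if tsp is None:
        raise ValueError("table lacks the TSP reference entry")
    return Library(metabolites=metabolites, tsp=tsp)
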