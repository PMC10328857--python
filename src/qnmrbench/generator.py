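"""Synthetic study generator.

Renders the full benchmark study directly in the absorption-mode frequency
domain: three urine replicates plus five calibration-solution spectra for
each of the two pulse sequences (zgpr and NOESYpr), with exact ground truth
attached.  Controlled artifacts emulate, phenomenologically, what acquisition
does to a real spectrum:

* additive Gaussian noise and a degree-<=3 polynomial baseline;
* a residual-water hump near 4.70 ppm;
* a Gaussian presaturation attenuation notch
  ``A(δ) = 1 − α·exp(−(δ−δw)²/(2σw²))`` multiplying every peak height —
  the mechanism behind the glucose bias of water presaturation;
* a global chemical-shift offset plus small per-peak jitter;
* per-peak zgpr/NOESYpr intensity ratios in [1.1, 1.3] (zgpr brighter),
  drawn once per study so they are shared by all spectra of a sequence;
* sample chemistry: creatine/creatinine interconversion with conserved sum,
  and cysteine fully dimerized to cystine.

All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .library import Library, Multiplet, default_library
from .spectrum import DEFAULT_POINTS, DEFAULT_WINDOW, Spectrum1D, SpectrumMeta, make_axis

__all__ = [
    "ArtifactConfig",
    "StudyDataset",
    "apply_chemistry",
    "simulate_spectrum",
    "simulate_study",
]

#: Weakest-multiplet signal-to-noise ratio the default noise level is set to.
TARGET_WEAKEST_SNR = 15.0
#: Lines are rendered within ±LINE_SUPPORT × fwhm of their centre.
LINE_SUPPORT = 300.0


@dataclass
class ArtifactConfig:
    """Dials of the phenomenological artifact model.

    ``response_factor`` converts concentration × proton count into peak
    height (intensity per µM·proton); its absolute value is arbitrary since
    every quantification route is ratio- or calibration-based.
    """

    noise_sd: float = 0.0                      # 0 -> derived from the library
    baseline_amplitude: float = 0.0            # 0 -> derived from noise level
    water_hump: tuple[float, float, float] = (4.70, 0.0, 0.010)  # center, amp, sd
    presat_alpha: float = 0.6                  # notch depth in [0, 1]
    presat_sigma: float = 0.15                 # notch width, ppm
    presat_center: float = 4.70                # ppm
    global_shift_sd: float = 0.003             # ppm
    per_peak_shift_sd: float = 0.0005          # ppm
    noesy_ratio_range: tuple[float, float] = (1.1, 1.3)
    creatine_fraction_range: tuple[float, float] = (0.1, 0.9)
    response_factor: float = 1e-3              # intensity per (µM · proton)
    window: tuple[float, float] = DEFAULT_WINDOW
    n_points: int = DEFAULT_POINTS

    def __post_init__(self) -> None:
        if not 0.0 <= self.presat_alpha <= 1.0:
            raise ValueError("presat_alpha must be in [0, 1]")
        if self.noise_sd < 0 or self.global_shift_sd < 0 or self.per_peak_shift_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        lo, hi = self.noesy_ratio_range
        if lo < 1.0 or hi < lo:
            raise ValueError("noesy_ratio_range must lie within [1, inf)")
        flo, fhi = self.creatine_fraction_range
        if not (0.0 <= flo <= fhi <= 1.0):
            raise ValueError("creatine_fraction_range must be within [0, 1]")

    @classmethod
    def default_for(cls, library: Library, **overrides) -> "ArtifactConfig":
        """Defaults with noise calibrated to the weakest urine multiplet.

        The noise standard deviation is set so the weakest preferred
        multiplet in the urine sample has SNR ≈ 15, just above the SNR > 10
        quantifiability cut; the residual-water hump is as tall as the most
        intense metabolite peak, mirroring a tuned presaturation.
        """
        cfg = cls(**overrides)
        heights = []
        for m in library.metabolites:
            mult = m.preferred
            h = max(
                m.urine_concentration * mult.n_protons * line.weight * cfg.response_factor
                for line in mult.lines
            )
            if m.name != "cysteine":  # dimerized away: never present
                heights.append(h)
        weakest, tallest = min(heights), max(heights)
        if "noise_sd" not in overrides:
            cfg.noise_sd = weakest / TARGET_WEAKEST_SNR
        if "baseline_amplitude" not in overrides:
            cfg.baseline_amplitude = 20.0 * cfg.noise_sd
        if "water_hump" not in overrides:
            cfg.water_hump = (4.70, tallest, 0.010)
        return cfg

    def noiseless(self) -> "ArtifactConfig":
        """Copy with every stochastic/additive artifact switched off."""
        return replace(
            self,
            noise_sd=0.0,
            baseline_amplitude=0.0,
            water_hump=(self.water_hump[0], 0.0, self.water_hump[2]),
            global_shift_sd=0.0,
            per_peak_shift_sd=0.0,
        )

    def attenuation(self, delta: np.ndarray | float) -> np.ndarray | float:
        """Presaturation attenuation profile A(δ), symmetric about δw."""
        d = np.asarray(delta, dtype=float) - self.presat_center
        return 1.0 - self.presat_alpha * np.exp(-(d ** 2) / (2.0 * self.presat_sigma ** 2))


# ---------------------------------------------------------------------------
# chemistry
# ---------------------------------------------------------------------------

def apply_chemistry(
    conc_table: dict[str, float],
    rng: np.random.Generator,
    library: Library,
    creatine_fraction_range: tuple[float, float] = (0.1, 0.9),
) -> dict[str, float]:
    """Effective in-solution concentrations after sample chemistry.

    A fraction ``f ~ Uniform(creatine_fraction_range)`` redistributes the
    conserved creatine+creatinine total; cysteine is fully dimerized
    (cystine gains cysteine/2 on top of any cystine already in the table,
    2:1 molar stoichiometry).
    """
    eff = dict(conc_table)
    partners = {
        m.name: m.interconversion_partner
        for m in library.metabolites
        if m.interconversion_partner
    }
    if partners:
        if not {"creatine", "creatinine"} <= set(conc_table):
            raise ValueError("interconversion flagged but partner missing from table")
        total = conc_table["creatine"] + conc_table["creatinine"]
        f = rng.uniform(*creatine_fraction_range)
        eff["creatine"] = f * total
        eff["creatinine"] = (1.0 - f) * total
    for m in library.metabolites:
        if m.dimerizes_to and m.name in conc_table:
            dimer = m.dimerizes_to
            # nominal cystine already records the dimerized cysteine, so the
            # dimer concentration is simply cysteine/2 of the weighed-in amount
            eff[dimer] = conc_table[m.name] / 2.0
            eff[m.name] = 0.0
    return eff


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------

def _pseudo_voigt_profile(x: np.ndarray, center: float, fwhm: float, eta: float) -> np.ndarray:
    """Unit-height pseudo-Voigt η·L + (1−η)·G evaluated on ``x``."""
    u = (x - center) / fwhm
    lorentz = 1.0 / (1.0 + 4.0 * u ** 2)
    gauss = np.exp(-4.0 * math.log(2.0) * u ** 2)
    return eta * lorentz + (1.0 - eta) * gauss


def _render_line(
    axis: np.ndarray,
    intensity: np.ndarray,
    center: float,
    height: float,
    fwhm: float,
    eta: float,
) -> None:
    """Add one line in place, restricted to its ±LINE_SUPPORT·fwhm window."""
    if height == 0.0:
        return
    half = LINE_SUPPORT * fwhm
    # axis is strictly decreasing
    i0 = int(np.searchsorted(-axis, -(center + half)))
    i1 = int(np.searchsorted(-axis, -(center - half)))
    if i0 >= i1:
        return
    seg = axis[i0:i1]
    intensity[i0:i1] += height * _pseudo_voigt_profile(seg, center, fwhm, eta)


def simulate_spectrum(
    library: Library,
    conc_table: dict[str, float],
    config: ArtifactConfig,
    pulse_sequence: str = "zgpr",
    rng: Optional[np.random.Generator] = None,
    meta: Optional[SpectrumMeta] = None,
    noesy_ratios: Optional[dict[tuple[str, int, int], float]] = None,
) -> Spectrum1D:
    """Render one spectrum from effective concentrations.

    ``noesy_ratios`` maps (metabolite, multiplet index, line index) to the
    per-peak zgpr/NOESYpr intensity ratio; required when
    ``pulse_sequence == "noesypr"`` so that all spectra of one study share
    the same sequence response.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    missing = [m.name for m in library.metabolites if m.name not in conc_table]
    if missing:
        raise ValueError(f"concentration table missing metabolites: {missing}")
    if pulse_sequence == "noesypr" and noesy_ratios is None:
        raise ValueError("noesypr rendering requires shared per-peak ratios")

    axis = make_axis(config.window, config.n_points)
    intensity = np.zeros_like(axis)
    global_shift = rng.normal(0.0, config.global_shift_sd) if config.global_shift_sd else 0.0

    entries = [*library.metabolites, library.tsp]
    for m in entries:
        conc = library.tsp.urine_concentration if m is library.tsp else conc_table[m.name]
        if conc == 0.0:
            continue
        for mi, mult in enumerate(m.multiplets):
            for li, line in enumerate(mult.lines):
                center = mult.center + line.offset + global_shift
                if config.per_peak_shift_sd:
                    center += rng.normal(0.0, config.per_peak_shift_sd)
                height = (
                    conc * mult.n_protons * line.weight * config.response_factor
                    * float(config.attenuation(mult.center + line.offset))
                )
                if pulse_sequence == "noesypr":
                    height /= noesy_ratios[(m.name, mi, li)]
                _render_line(axis, intensity, center, height,
                             mult.default_fwhm, mult.default_eta)

    wc, wa, ws = config.water_hump
    if wa:
        intensity += wa * np.exp(-((axis - wc) ** 2) / (2.0 * ws ** 2))
    if config.baseline_amplitude:
        coeffs = rng.uniform(-config.baseline_amplitude, config.baseline_amplitude, size=4)
        xn = np.linspace(-1.0, 1.0, axis.size)
        intensity += np.polynomial.polynomial.polyval(xn, coeffs)
    if config.noise_sd:
        intensity += rng.normal(0.0, config.noise_sd, size=axis.size)

    if meta is None:
        meta = SpectrumMeta(pulse_sequence=pulse_sequence)
    return Spectrum1D(ppm_axis=axis, intensity=intensity, meta=meta)


# ---------------------------------------------------------------------------
# study assembly
# ---------------------------------------------------------------------------

@dataclass
class StudyDataset:
    """Spectra plus exact ground truth for one simulated study."""

    spectra: list[Spectrum1D]
    truth: pd.DataFrame            # nominal concentrations: metabolite x (urine, cal1..5)
    effective_truth: pd.DataFrame  # per-spectrum effective concentrations
    master_seed: int
    config: ArtifactConfig = field(repr=False, default=None)
    library: Library = field(repr=False, default=None)

    def select(self, pulse_sequence: str, sample_role: Optional[str] = None) -> list[Spectrum1D]:
        out = [s for s in self.spectra if s.meta.pulse_sequence == pulse_sequence]
        if sample_role is not None:
            out = [s for s in out if s.meta.sample_role == sample_role]
        return out

    def effective(self, spectrum_id: str) -> dict[str, float]:
        row = self.effective_truth.loc[spectrum_id]
        return row.to_dict()


def _spectrum_id(meta: SpectrumMeta) -> str:
    if meta.sample_role == "urine":
        return f"{meta.pulse_sequence}/urine_r{meta.replicate_index}"
    return f"{meta.pulse_sequence}/cal_l{meta.calibration_level}"


def simulate_study(
    library: Optional[Library] = None,
    config: Optional[ArtifactConfig] = None,
    master_seed: int = 0,
    pulse_sequences: tuple[str, ...] = ("zgpr", "noesypr"),
) -> StudyDataset:
    """Generate the full study: 3 urine replicates + 5 calibration spectra
    per pulse sequence.

    The urine replicates share a single chemistry draw (one tube measured
    three times) but have independent noise and shift jitter; each
    calibration solution draws its chemistry independently (five separate
    solutions, hence the non-proportional individual creatine/creatinine
    ladders).  Both pulse sequences see the *same* samples: chemistry draws
    are shared across sequences, as are the per-peak sequence ratios.
    """
    if library is None:
        library = default_library()
    if config is None:
        config = ArtifactConfig.default_for(library)

    root = np.random.SeedSequence(master_seed)
    ss_chem, ss_ratio, ss_noise = root.spawn(3)
    chem_rng = np.random.default_rng(ss_chem)
    ratio_rng = np.random.default_rng(ss_ratio)

    # chemistry: one urine draw, five calibration draws (shared by sequences)
    urine_nominal = library.urine_truth()
    urine_eff = apply_chemistry(
        urine_nominal, chem_rng, library, config.creatine_fraction_range
    )
    cal_eff = [
        apply_chemistry(
            library.calibration_truth(level), chem_rng, library,
            config.creatine_fraction_range,
        )
        for level in range(1, 6)
    ]

    # per-peak zgpr/NOESYpr ratios, one draw per study
    lo, hi = config.noesy_ratio_range
    noesy_ratios: dict[tuple[str, int, int], float] = {}
    for m in [*library.metabolites, library.tsp]:
        for mi, mult in enumerate(m.multiplets):
            for li in range(len(mult.lines)):
                noesy_ratios[(m.name, mi, li)] = float(ratio_rng.uniform(lo, hi))

    spectra: list[Spectrum1D] = []
    eff_rows: dict[str, dict[str, float]] = {}
    noise_children = iter(ss_noise.spawn(len(pulse_sequences) * 8))
    for seq in pulse_sequences:
        for rep in range(1, 4):
            meta = SpectrumMeta(pulse_sequence=seq, sample_role="urine",
                                replicate_index=rep,
                                provenance=f"seed={master_seed}")
            spec = simulate_spectrum(
                library, urine_eff, config, seq,
                rng=np.random.default_rng(next(noise_children)),
                meta=meta, noesy_ratios=noesy_ratios,
            )
            spectra.append(spec)
            eff_rows[_spectrum_id(meta)] = dict(urine_eff)
        for level in range(1, 6):
            meta = SpectrumMeta(pulse_sequence=seq, sample_role="calibration",
                                calibration_level=level,
                                provenance=f"seed={master_seed}")
            spec = simulate_spectrum(
                library, cal_eff[level - 1], config, seq,
                rng=np.random.default_rng(next(noise_children)),
                meta=meta, noesy_ratios=noesy_ratios,
            )
            spectra.append(spec)
            eff_rows[_spectrum_id(meta)] = dict(cal_eff[level - 1])

    truth = pd.DataFrame(
        {
            "urine": library.urine_truth(),
            **{
                f"cal{level}": library.calibration_truth(level)
                for level in range(1, 6)
            },
        }
    )
    effective_truth = pd.DataFrame.from_dict(eff_rows, orient="index")
    return StudyDataset(
        spectra=spectra,
        truth=truth,
        effective_truth=effective_truth,
        master_seed=master_seed,
        config=config,
        library=library,
    )
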