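"""Synthetic study generation: chemistry, lineshapes, artifacts, layout."""

from dataclasses import replace

import numpy as np
import pytest

from qnmrbench.generator import ArtifactConfig, apply_chemistry, simulate_spectrum, simulate_study
from qnmrbench.integrate import integrate_region


class TestChemistry:
    def test_creatine_sum_conserved(self, library):
        rng = np.random.default_rng(0)
        table = library.urine_truth()
        total = table["creatine"] + table["creatinine"]
        for _ in range(10):
            eff = apply_chemistry(table, rng, library)
            assert eff["creatine"] + eff["creatinine"] == pytest.approx(total)
            assert 0 <= eff["creatine"] <= total

    def test_fraction_boundary_all_creatine(self, library):
        rng = np.random.default_rng(1)
        table = library.urine_truth()
        total = table["creatine"] + table["creatinine"]
        eff = apply_chemistry(table, rng, library, creatine_fraction_range=(1.0, 1.0))
        assert eff["creatine"] == pytest.approx(total)
        assert eff["creatinine"] == pytest.approx(0.0)

    def test_cysteine_dimerizes_2_to_1(self, library):
        rng = np.random.default_rng(2)
        table = dict(library.urine_truth())
        table["cysteine"] = 200.0
        eff = apply_chemistry(table, rng, library)
        assert eff["cysteine"] == 0.0
        assert eff["cystine"] == pytest.approx(100.0)


class TestSimulateSpectrum:
    def test_area_linear_in_concentration(self, mini_library, clean_config):
        table = {m.name: m.urine_concentration for m in mini_library.metabolites}
        double = {k: 2 * v for k, v in table.items()}
        s1 = simulate_spectrum(mini_library, table, clean_config)
        s2 = simulate_spectrum(mini_library, double, clean_config)
        region = mini_library["alpha"].quant_region
        a1, a2 = integrate_region(s1, region), integrate_region(s2, region)
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_area_proportional_to_protons_times_conc(self, mini_library, clean_config):
        table = {m.name: m.urine_concentration for m in mini_library.metabolites}
        s = simulate_spectrum(mini_library, table, clean_config)
        # exact proportionality when conc x protons changes for one multiplet
        table2 = dict(table)
        table2["alpha"] = 3.0 * table["alpha"]
        s2 = simulate_spectrum(mini_library, table2, clean_config)
        region = mini_library["alpha"].quant_region
        assert integrate_region(s2, region) == pytest.approx(
            3.0 * integrate_region(s, region), rel=1e-9
        )
        # across different multiplets the shared capture fraction makes the
        # per-(conc x proton) response equal up to grid discretization
        areas = {
            m.name: integrate_region(s, m.quant_region)
            / (m.urine_concentration * m.preferred.n_protons)
            for m in mini_library.metabolites
        }
        vals = list(areas.values())
        assert max(vals) / min(vals) == pytest.approx(1.0, rel=1e-3)

    def test_full_suppression_at_notch_center(self, mini_library):
        cfg = ArtifactConfig(presat_alpha=1.0, presat_center=6.0)
        table = {m.name: m.urine_concentration for m in mini_library.metabolites}
        s = simulate_spectrum(mini_library, table, cfg)
        area_b = integrate_region(s, mini_library["beta"].quant_region)
        assert area_b == pytest.approx(0.0, abs=1e-12)

    def test_seeded_determinism_bitwise(self, library, default_config):
        table = library.urine_truth()
        a = simulate_spectrum(library, table, default_config,
                              rng=np.random.default_rng(9))
        b = simulate_spectrum(library, table, default_config,
                              rng=np.random.default_rng(9))
        assert np.array_equal(a.intensity, b.intensity)

    def test_missing_metabolite_rejected(self, mini_library, clean_config):
        with pytest.raises(ValueError, match="missing"):
            simulate_spectrum(mini_library, {"alpha": 1.0}, clean_config)

    def test_attenuation_symmetric_about_center(self, default_config):
        c = default_config.presat_center
        x = np.linspace(0.01, 1.0, 25)
        np.testing.assert_allclose(
            default_config.attenuation(c + x), default_config.attenuation(c - x)
        )


class TestSimulateStudy:
    def test_layout_2_sequences_times_8_spectra(self, study):
        assert len(study.spectra) == 16
        for seq in ("zgpr", "noesypr"):
            assert len(study.select(seq, "urine")) == 3
            assert len(study.select(seq, "calibration")) == 5

    def test_replicates_share_chemistry(self, study):
        rows = [study.effective(f"zgpr/urine_r{r}") for r in (1, 2, 3)]
        assert rows[0] == rows[1] == rows[2]

    def test_calibration_chemistry_independent(self, study):
        fracs = set()
        for level in range(1, 6):
            eff = study.effective(f"zgpr/cal_l{level}")
            total = eff["creatine"] + eff["creatinine"]
            fracs.add(round(eff["creatine"] / total, 6))
        assert len(fracs) == 5  # five separate solutions, five draws

    def test_interconversion_sum_exact_per_spectrum(self, study, library):
        for sid in study.effective_truth.index:
            eff = study.effective(sid)
            if "urine" in sid:
                nominal = library.urine_truth()
            else:
                level = int(sid.rsplit("_l", 1)[1])
                nominal = library.calibration_truth(level)
            assert eff["creatine"] + eff["creatinine"] == pytest.approx(
                nominal["creatine"] + nominal["creatinine"]
            )

    def test_zgpr_noesypr_height_ratio_in_range(self, library, clean_config):
        study = simulate_study(library, clean_config, master_seed=4)
        z = study.select("zgpr", "urine")[0]
        n = study.select("noesypr", "urine")[0]
        # ratio at well-isolated singlet apexes
        for name in ("formic acid", "trimethylamine-N-oxide", "allantoin"):
            lo, hi = library[name].quant_region
            mask = (z.ppm_axis >= lo) & (z.ppm_axis <= hi)
            ratio = z.intensity[mask].max() / n.intensity[mask].max()
            assert 1.1 <= ratio <= 1.3

    def test_master_seed_reproducibility(self, library, default_config):
        a = simulate_study(library, default_config, master_seed=3,
                           pulse_sequences=("zgpr",))
        b = simulate_study(library, default_config, master_seed=3,
                           pulse_sequences=("zgpr",))
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.intensity, sb.intensity)
        assert a.effective_truth.equals(b.effective_truth)

    def test_calibration_levels_within_global_range(self, study, library):
        for level in range(1, 6):
            vals = [
                v for k, v in library.calibration_truth(level).items()
                if k != "cystine"
            ]
            assert min(vals) >= 100.0 and max(vals) <= 12000.0


def test_default_noise_gives_snr_near_15_for_weakest(library, default_config):
    heights = []
    for m in library.metabolites:
        if m.name == "cysteine":
            continue
        h = max(
            m.urine_concentration * m.preferred.n_protons * l.weight
            * default_config.response_factor
            for l in m.preferred.lines
        )
        heights.append(h)
    assert min(heights) / default_config.noise_sd == pytest.approx(15.0, rel=1e-6)
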