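import numpy as np
import pytest

from qnmrbench.generator import ArtifactConfig, simulate_study
from qnmrbench.library import Library, Line, MetaboliteDef, Multiplet, default_library
from qnmrbench.pipeline import preprocess_study


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def default_config(library):
    return ArtifactConfig.default_for(library)


@pytest.fixture(scope="session")
def study(library, default_config):
    """One default zgpr+noesypr study, shared read-only across tests."""
    return simulate_study(library, default_config, master_seed=1)


@pytest.fixture(scope="session")
def preprocessed(study):
    return preprocess_study(study)


def make_mini_library() -> Library:
    """Three well-separated singlets plus TSP: every peak is truly isolated
    (no neighbour within the rendering support), so noiseless quantification
    is exact to numerical precision."""
    def met(name, center, n_protons, urine):
        ladder = list(np.geomspace(0.5 * urine, 4.0 * urine, 5))
        return MetaboliteDef(
            name=name,
            multiplets=[Multiplet(center=center, lines=[Line(0.0, 1.0)],
                                  n_protons=n_protons)],
            quant_region=(center - 0.02, center + 0.02),
            urine_concentration=urine,
            calibration_concentrations=ladder,
        )

    tsp = MetaboliteDef(
        name="TSP",
        multiplets=[Multiplet(center=0.0, lines=[Line(0.0, 1.0)], n_protons=9)],
        quant_region=(-0.015, 0.015),
        urine_concentration=500.0,
        calibration_concentrations=[500.0] * 5,
    )
    return Library(
        metabolites=[
            met("alpha", 8.0, 2, 900.0),
            met("beta", 6.0, 3, 2000.0),
            met("gamma", 2.0, 1, 400.0),
        ],
        tsp=tsp,
    )


@pytest.fixture(scope="session")
def mini_library():
    return make_mini_library()


@pytest.fixture(scope="session")
def clean_config():
    """Artifact-free configuration: no noise, baseline, hump, notch or jitter."""
    return ArtifactConfig(presat_alpha=0.0, global_shift_sd=0.0, per_peak_shift_sd=0.0)
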