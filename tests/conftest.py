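import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import guia_adherence as ga
from guia_adherence.simulate import GeneratorConfig, calibrate, generate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The 50-record hand-scored worked fixture, written once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    return ga.emit_fixture(outdir)


@pytest.fixture(scope="session")
def small_survey():
    """A small fully processed synthetic survey shared across tests.

    ~4,500 students in 120 schools, default covariate marginals, a single
    injected rural effect (PR 2.0) so association tests have signal.
    """
    config = GeneratorConfig(
        seed=11, schools_total=120, effect_map={"area": {"rural": 2.0}},
        target_full_adherence=0.02,  # scaled-up outcome so a 4.5k sample carries signal
    )
    synth = generate(config, output="canonical")
    data, report = ga.flag_validity(synth.microdata)
    scored = ga.score_both_variants(data)
    data = pd.concat([data, scored.drop(columns=["score_valid"])], axis=1)
    design = ga.SurveyDesign.from_frame(data)
    return {"config": config, "data": data, "design": design, "report": report}


@pytest.fixture()
def toy_design():
    """2 strata x 2 PSUs x 2 records, unequal weights; hand-computable."""
    return ga.SurveyDesign(
        strata=["a", "a", "a", "a", "b", "b", "b", "b"],
        psu=["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"],
        weights=[1.0, 2.0, 1.0, 3.0, 2.0, 2.0, 1.0, 1.0],
    )
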