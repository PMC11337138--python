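import pytest

from caretl import GeneratorConfig, generate_export, run_pipeline

#: defects injected into the quality-assessment build, one of each kind
DEFECT_SPEC = {
    "event_after_death": 3,
    "value_out_of_range": 5,
    "birth_year_implausible": 2,
    "dangling_visit_reference": 4,
    "missing_required_field": 2,
}


@pytest.fixture(scope="session")
def small_export():
    """A 30-patient export with its ground-truth manifest."""
    return generate_export(GeneratorConfig(n_patients=30, seed=42))


@pytest.fixture(scope="session")
def clean_pipeline(tmp_path_factory):
    """A defect-free end-to-end run at moderate scale (file round-trip)."""
    cfg = GeneratorConfig(n_patients=40, seed=5)
    return run_pipeline(cfg, workdir=tmp_path_factory.mktemp("export40"))


@pytest.fixture(scope="session")
def pipeline_500(tmp_path_factory):
    """The headline 500-patient end-to-end run used by the acceptance tests."""
    cfg = GeneratorConfig(n_patients=500, seed=7)
    return run_pipeline(cfg, workdir=tmp_path_factory.mktemp("export500"))


@pytest.fixture(scope="session")
def defect_pipeline():
    """A build from a defect-injected export (about 10 deaths available, so
    every defect kind has candidates); the transform's outlier filter is off
    so injected implausible values reach the warehouse."""
    cfg = GeneratorConfig(n_patients=100, seed=13, death_rate=0.1)
    result = run_pipeline(cfg, defects=DEFECT_SPEC, filter_outliers=False,
                          run_validation=False)
    return result
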