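import pytest
from hypothesis import HealthCheck, settings

import settinglink as sl
from settinglink._seeds import derive_seed

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

STUDY_SEED = 0


@pytest.fixture(scope="session")
def study_config() -> sl.SyntheticConfig:
    """The default synthetic study conditions (8 settings, 20-concept
    signatures, 200 background concepts, 100 docs/setting)."""
    return sl.SyntheticConfig(seed=derive_seed(STUDY_SEED, "simulate"))


@pytest.fixture(scope="session")
def study_data(study_config):
    corpus, truth = sl.generate_corpus(study_config)
    db = sl.generate_cooccurrence_db(truth, study_config)
    return corpus, truth, db


@pytest.fixture(scope="session")
def small_config() -> sl.SyntheticConfig:
    """A scaled-down configuration for fast end-to-end checks."""
    return sl.SyntheticConfig(
        n_settings=4, signature_size=6, n_background=40, docs_per_setting=25,
        mean_doc_length=10.0, seed=derive_seed(13, "simulate"))


@pytest.fixture(scope="session")
def small_data(small_config):
    corpus, truth = sl.generate_corpus(small_config)
    db = sl.generate_cooccurrence_db(truth, small_config)
    return corpus, truth, db


def make_pipeline_config(output_dir, seed: int = 5) -> sl.PipelineConfig:
    """Scaled-down full-pipeline configuration for end-to-end checks."""
    return sl.PipelineConfig.from_dict({
        "output_dir": str(output_dir),
        "seed": seed,
        "sample_n": 50,
        "synthetic": {"n_settings": 5, "signature_size": 8, "n_background": 60,
                      "docs_per_setting": 30, "mean_doc_length": 12.0},
        "lda": {"iterations": 300, "burnin": 300,
                "infer_iterations": 350, "infer_burnin": 300},
        "ks": [1, 2, 4],
    })


@pytest.fixture
def toy_corpus() -> sl.Corpus:
    """Four documents, two settings, with one setting-exclusive concept."""
    return sl.Corpus([
        sl.ConceptDocument("d1", "Cardiology", ("C0010054", "C0020538")),
        sl.ConceptDocument("d2", "Cardiology", ("C0010054", "C0020538", "C0020538")),
        sl.ConceptDocument("d3", "Dermatology", ("C0011603", "C0020538")),
        sl.ConceptDocument("d4", "Dermatology", ("C0011603",)),
    ])
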