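import pytest
from hypothesis import settings

from dosecalc import fixtures, load_model, load_phantom, load_saf, parse_decay_file
from dosecalc.reporting import run_batch

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

CORPUS_SEED = 7


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """A full synthetic corpus written once per session."""
    out = tmp_path_factory.mktemp("corpus")
    return fixtures.generate_corpus(CORPUS_SEED, out)


@pytest.fixture(scope="session")
def corpus_objects(corpus):
    """Parsed nuclide, phantoms and SAF tables from the session corpus."""
    nuclide = parse_decay_file(corpus["decay"])[0]
    return {
        "nuclide": nuclide,
        "phantom_male": load_phantom(corpus["phantom_male"]),
        "phantom_female": load_phantom(corpus["phantom_female"]),
        "saf_male": load_saf(corpus["saf_male"]),
        "saf_female": load_saf(corpus["saf_female"]),
        "models": {
            name: load_model(corpus[f"model_{name}"])
            for name in ("plain", "bladder", "gi", "bone_short", "bone_long",
                         "blood", "legacy_gut", "residual")
        },
    }


@pytest.fixture(scope="session")
def batch_result(corpus, tmp_path_factory):
    out = tmp_path_factory.mktemp("batch_out")
    return run_batch(corpus["batch"], out_dir=out), out
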