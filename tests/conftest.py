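import pytest

import faersig as fs


@pytest.fixture(scope="session")
def paper_world():
    """One 50,000-report pediatric world with the 24 preset planted drugs."""
    return fs.generate(fs.paper_like_config(n_reports=50_000, seed=11))


@pytest.fixture(scope="session")
def paper_dataset(paper_world):
    """The analysis dataset and QC counts built from the session world."""
    dataset, qc = fs.prepare_dataset(paper_world.bundle)
    return dataset, qc


@pytest.fixture(scope="session")
def mixed_age_world():
    """A world with adult and missing ages, to exercise the pediatric filter."""
    cfg = fs.GeneratorConfig(
        n_reports=50_000,
        seed=5,
        cataract_background_prob=0.002,
        duplicate_fraction=0.1,
        age=fs.synthetic.AgeModel(pediatric_fraction=0.8, missing_prob=0.05),
    )
    return fs.generate(cfg)
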