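import pytest
from hypothesis import settings

from cdpkfam import synthetic_data as sd
from cdpkfam.seqio import load_family_table

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def family_table():
    """The packaged 40-gene family reference table."""
    return load_family_table()


@pytest.fixture(scope="session")
def study_genome():
    """Synthetic genome at study scale: 40 members in 4 groups with 10
    segmental + 4 tandem duplicate pairs at ~90% identity."""
    return sd.generate_family_genome(sd.GeneratorConfig(seed=20130701))


@pytest.fixture(scope="session")
def small_genome():
    """A small genome for cheap end-to-end checks."""
    config = sd.GeneratorConfig(
        seed=7,
        groups=(sd.GroupSpec("I", 6), sd.GroupSpec("II", 4)),
        duplications=(
            sd.DuplicationSpec("segmental", 0.9),
            sd.DuplicationSpec("segmental", 0.9),
            sd.DuplicationSpec("tandem", 0.9),
        ),
        n_chromosomes=4,
        n_background_genes=20,
    )
    return sd.generate_family_genome(config)
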