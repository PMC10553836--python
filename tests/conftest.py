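import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from dogrose.genotype_io import LocusPanel, SampleRecord


@pytest.fixture(scope="session")
def panel():
    return LocusPanel()


@pytest.fixture
def make_record():
    """Factory for small sample records with sensible metadata defaults."""
    def _make(sample_id, phenotype, species="R. canina", section="Caninae",
              subsection="Caninae", site_id="S01", dataset_tag="GE",
              latitude=51.0, longitude=10.0, ploidy_measured=None):
        full = {locus: None for locus in LocusPanel().locus_ids}
        full.update(phenotype)
        return SampleRecord(
            sample_id=sample_id, dataset_tag=dataset_tag, species=species,
            section=section, subsection=subsection, site_id=site_id,
            latitude=latitude, longitude=longitude,
            ploidy_measured=ploidy_measured, phenotype=full)
    return _make


@pytest.fixture
def two_site_clones(make_record):
    """Three plants, two sharing one identical 7-locus phenotype at
    different sites."""
    base = {
        "RhAB73": (170, 172), "RhP50": (200,), "RhP518": (131, 138),
        "RhO517": (150,), "RhD201": (194, 202), "RhE506": (204, 243),
        "RhB303": (120,),
    }
    other = dict(base, RhAB73=(170, 174))
    return [
        make_record("a1", base, site_id="S01"),
        make_record("a2", base, site_id="S02"),
        make_record("b1", other, site_id="S01"),
    ]
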