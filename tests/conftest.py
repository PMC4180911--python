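import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def south_asian_records():
    from ethnometa.datasets import load_table1_south_asian

    return load_table1_south_asian()


@pytest.fixture
def diagram_records():
    from ethnometa.datasets import load_table1_diagram

    return load_table1_diagram()


@pytest.fixture
def gwas_designs():
    from ethnometa.datasets import load_table2_gwas

    return load_table2_gwas()


@pytest.fixture
def pooled_by_snp(south_asian_records):
    """Random-effects pooled result per SNP of the multi-study panel."""
    from ethnometa import estimate_from_record, pool

    groups = {}
    for rec in south_asian_records:
        groups.setdefault(rec.snp_id, []).append(rec)
    return {
        snp: pool([estimate_from_record(r) for r in group])
        for snp, group in groups.items()
    }
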