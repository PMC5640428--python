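import pytest

from baitprey.model import (
    Age,
    Antibody,
    Channel,
    EnrichmentProfile,
    PreyObservation,
)


@pytest.fixture(scope="session")
def table1_rows():
    from baitprey.io import read_table1_fixture

    return read_table1_fixture()


def make_obs(
    prey="P1",
    purification="C_TERM_P50_r1_BAIT",
    antibody=Antibody.C_TERM,
    age=Age.P50,
    replicate=1,
    channel=Channel.BAIT,
    spectral_count=5,
    unique_peptides=2,
    length=500,
):
    return PreyObservation(
        prey_id=prey,
        gene_symbol=prey,
        purification_id=purification,
        antibody=antibody,
        age=age,
        replicate=replicate,
        channel=channel,
        spectral_count=spectral_count,
        unique_peptides=unique_peptides,
        protein_length=length,
    )


def make_profile(
    prey="P1",
    fold=5.0,
    unique=2,
    bait=50,
    control=10,
    replicates=3,
    conditions=((Antibody.C_TERM, Age.P50),),
    maxp=0.95,
):
    return EnrichmentProfile(
        prey_id=prey,
        gene_symbol=prey,
        fold_ratio=fold,
        unique_peptides_max=unique,
        psm_total_bait=bait,
        psm_total_control=control,
        replicate_presence=replicates,
        conditions_seen=frozenset(conditions),
        maxp=maxp,
    )
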