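from __future__ import annotations

import pytest

from cardioburden.io import (
    Consequence,
    Sex,
    VariantKey,
    VariantObservation,
    Zygosity,
)
from cardioburden.simulate import study_fixture


def make_obs(
    case_id: str = "case1",
    gene: str = "KCNQ1",
    chrom: str = "chr11",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "G",
    consequence: Consequence | str = Consequence.MISSENSE,
    zygosity: Zygosity | str = Zygosity.HETEROZYGOUS,
    **kwargs,
) -> VariantObservation:
    return VariantObservation(
        case_id=case_id,
        gene=gene,
        key=VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt),
        consequence=consequence,
        zygosity=zygosity,
        **kwargs,
    )


@pytest.fixture(scope="session")
def fixture_data():
    """(observations, references, panel) of the packaged 290-case dataset."""
    return study_fixture()


@pytest.fixture(scope="session")
def fixture_observations(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def fixture_references(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def fixture_panel(fixture_data):
    return fixture_data[2]
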