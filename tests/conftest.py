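import pytest

from handcost import ConversionTables, build_reference_fixture, packaged_tables


@pytest.fixture(scope="session")
def tables():
    return packaged_tables()


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_reference_fixture()


@pytest.fixture(scope="session")
def toy_tables():
    """fx 5 TRY/USD in 2020, CPI ratio 1.2 to the target period."""
    return ConversionTables(
        fx={2020: 5.0, 2022: 1.0},
        cpi={"2020": 100.0, "2022": 120.0, "2022Q4": 120.0},
    )


@pytest.fixture(scope="session")
def identity_tables():
    """fx 1, flat CPI: conversion is the identity."""
    return ConversionTables(fx={2022: 1.0}, cpi={"2022": 100.0, "2022Q4": 100.0})
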