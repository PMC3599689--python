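import pytest

from molstream import (CANNED_FIXTURE_NAMES, canned_fixture, canned_sdf,
                       convert_sdf)

#: The five-molecule reference collection used across filter/summary tests.
FIVE_SET = ["ethanol_heavy", "benzene_kekulized", "pyridine",
            "methane_full_H", "cyclohexane"]


@pytest.fixture
def ethanol():
    return canned_fixture("ethanol_heavy")[1]


@pytest.fixture
def benzene():
    return canned_fixture("benzene_kekulized")[1]


@pytest.fixture
def five_sdf(tmp_path):
    """SD-file of the five-molecule reference collection."""
    path = tmp_path / "five.sdf"
    path.write_text(canned_sdf(FIVE_SET), encoding="utf-8")
    return path


@pytest.fixture
def five_container(five_sdf, tmp_path):
    out = tmp_path / "five.rbz.jsonl.bz2"
    report = convert_sdf(five_sdf, out)
    assert report.n_accepted == len(FIVE_SET)
    return out


@pytest.fixture
def all_canned():
    return [(name, *canned_fixture(name)) for name in CANNED_FIXTURE_NAMES]
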