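import importlib.resources

import pytest

from cfcg.io_core import ComponentRecord, EdgeTable, HerbDose


@pytest.fixture(scope="session")
def table2_path() -> str:
    """Packaged 127-row two-herb component property table."""
    return str(importlib.resources.files("cfcg") / "data" / "ermiao_components.tsv")


@pytest.fixture(scope="session")
def doses_path() -> str:
    return str(importlib.resources.files("cfcg") / "data" / "ermiao_doses.tsv")


def make_record(cid="c1", herbs=("H",), mw=200.0, rbn=2, n_hacc=3, n_hdon=1,
                clogp=2.0, concentration=None) -> ComponentRecord:
    return ComponentRecord(
        component_id=cid, name=cid, herbs=frozenset(herbs), mw=mw, rbn=rbn,
        n_hacc=n_hacc, n_hdon=n_hdon, clogp=clogp, concentration=concentration,
    )


@pytest.fixture
def micro_network():
    """Three-component two-herb micro-network with hand-computed topology.

    c1 is exclusive to herb H, c2 to herb C, c3 is shared; doses are 10 g
    (H) and 5 g (C) and only c3 has a measured concentration (2 mg/g).
    """
    records = [
        make_record("c1", herbs=("H",)),
        make_record("c2", herbs=("C",)),
        make_record("c3", herbs=("H", "C"), concentration=2.0),
    ]
    edges = EdgeTable(
        edges=(("c1", "t1"), ("c1", "t2"), ("c2", "t2"),
               ("c2", "t3"), ("c3", "t2"), ("c3", "t4")),
        kind="component-target",
    )
    doses = [HerbDose("H", 10.0), HerbDose("C", 5.0)]
    return records, edges, doses
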