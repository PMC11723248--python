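import numpy as np
import pandas as pd
import pytest

from ifptml.assaydb import (
    AssayConditions,
    AssayRecord,
    DescriptorTable,
    HydrogelComponent,
    Ink,
)
from ifptml.fusion import CutoffRange
from ifptml.synthetic import SyntheticSpec, generate_database


@pytest.fixture(scope="session")
def uniformity_range() -> CutoffRange:
    """Curated acceptance range for the uniformity factor."""
    return CutoffRange(property="Uniformity", lim_inf=0.93, avg=0.98,
                       lim_sup=1.03, n0=62, n1=36)


@pytest.fixture(scope="session")
def case_study_ranges() -> dict[str, CutoffRange]:
    """Acceptance ranges for the three case-study endpoints."""
    return {
        "Uniformity": CutoffRange("Uniformity", 0.93, 0.98, 1.03, 62, 36),
        "Expansion": CutoffRange("Expansion", 8.00, 10.18, 25.00, 628, 632),
        "Porosity": CutoffRange("Porosity", 78.00, 77.35, 85.00, 1, 1),
    }


@pytest.fixture(scope="session")
def descriptor_table() -> DescriptorTable:
    return DescriptorTable(
        pd.DataFrame(
            {"W": [10.0, 2.0], "H": [4.0, 8.0]},
            index=pd.Index(["monoA", "monoB"], name="monomer_id"),
        )
    )


def make_record(assay_id="a1", monomer="monoA", conc=1.0, prop="Uniformity",
                value=0.95, second=None, **conditions) -> AssayRecord:
    comps = [HydrogelComponent(monomer, "CC(=O)O", conc)]
    if second is not None:
        comps.append(HydrogelComponent(second[0], "CCO", second[1]))
    return AssayRecord(
        assay_id=assay_id,
        ink=Ink(components=tuple(comps)),
        conditions=AssayConditions(c0_property=prop, **conditions),
        value=value,
    )


@pytest.fixture(scope="session")
def small_db():
    """A small but fully featured synthetic database (fast to fit)."""
    return generate_database(SyntheticSpec(n_assays=400, seed=11))


@pytest.fixture(scope="session")
def default_db():
    """The default-size synthetic database (shared across tests)."""
    return generate_database(SyntheticSpec(seed=1))
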