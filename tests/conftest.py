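import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")

from hormsense import (
    DegTable,
    HormoneDataset,
    PathwayAnnotation,
    make_paper_template_config,
)
from hormsense.synth import generate_hormone_dataset


@pytest.fixture(scope="session")
def template_dataset():
    """One template-design synthetic dataset shared across read-only tests."""
    cfg = make_paper_template_config(seed=11)
    ds, truth = generate_hormone_dataset(cfg)
    return ds, truth


@pytest.fixture()
def small_hormone_dataset():
    """Minimal valid 2-dose root-only dataset with 3 hormones."""
    rows = []
    rng = np.random.default_rng(7)
    for dose in (0.0, 20.0):
        for rep in (1, 2, 3):
            rows.append(
                {
                    "sample_id": f"root_d{dose:g}_r{rep}",
                    "tissue": "root",
                    "dose_mg_L": dose,
                    "replicate": rep,
                }
            )
    conc = rng.lognormal(np.log(20), 0.1, size=(6, 3))
    return HormoneDataset(
        samples=pd.DataFrame(rows),
        concentrations=conc,
        hormone_names=["JA", "ABA", "SA"],
    )


@pytest.fixture()
def toy_deg_table():
    """Six-row DEG table straddling every filter boundary."""
    fc_p = [(3.0, 0.01), (2.0, 0.01), (0.4, 0.04), (1.2, 0.001), (0.5, 0.01), (4.0, 0.06)]
    return DegTable(
        rows=pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(6)],
                "tissue": "root",
                "dose_mg_L": 20.0,
                "fold_change": [fc for fc, _ in fc_p],
                "p_value": [p for _, p in fc_p],
            }
        )
    )


@pytest.fixture()
def toy_annotation():
    return PathwayAnnotation(
        rows=pd.DataFrame(
            {
                "gene_id": ["g0", "g1", "g2", "g3", "g4"],
                "pathway": ["ET", "ET", "ET", "JA", "JA"],
                "effect_class": ["direct", "direct", "indirect", "direct", "indirect"],
            }
        )
    )
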