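import numpy as np
import pytest

from dynbrain import synth


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject synthetic cohort with the default planted design."""
    return synth.generate_cohort({"HC": 4, "noHE": 4, "MHE": 4}, seed=11)


@pytest.fixture(scope="session")
def default_design():
    return synth.default_design()


@pytest.fixture(scope="session")
def small_ensembles(small_cohort, default_design):
    """Partition ensembles (3 runs each) for the small cohort's subjects."""
    import dynbrain as db

    spec = db.WindowSpec(length=30, step=30, tr=2.5)
    params = db.ModularityParams(gamma=1.0, omega=1.0, n_runs=3, seed=5)
    out = []
    for rec, truth in small_cohort:
        dg = db.dynamic_graph(rec, spec)
        mg = db.build_multilayer(dg, params)
        out.append((db.ensemble(mg, params), truth))
    return out
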