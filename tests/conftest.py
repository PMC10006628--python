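import numpy as np
import pandas as pd
import pytest

from somastrat.datatypes import SomamerTable
from somastrat.simulate import SimConfig, simulate_cohort


def make_table(rfu, dilution=None, hyb=None, flagged=None, sample_type=None,
               plate=None, protein=None):
    """Hand-built SomamerTable from a 2-D array of RFU values."""
    rfu = np.asarray(rfu, dtype=float)
    n, p = rfu.shape
    som_ids = [f"SM{j}" for j in range(p)]
    samp_ids = [f"S{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "protein_symbol": protein if protein is not None else [f"PR{j}" for j in range(p)],
            "dilution_set": dilution if dilution is not None else [1] * p,
            "is_hyb_control": hyb if hyb is not None else [False] * p,
            "flagged_removed": flagged if flagged is not None else [False] * p,
        },
        index=pd.Index(som_ids, name="somamer_id"),
    )
    smeta = pd.DataFrame(
        {
            "sample_type": sample_type if sample_type is not None else ["study"] * n,
            "plate_id": plate if plate is not None else ["P1"] * n,
        },
        index=pd.Index(samp_ids, name="sample_id"),
    )
    return SomamerTable(pd.DataFrame(rfu, index=smeta.index, columns=som_ids), meta, smeta)


@pytest.fixture
def small_cfg():
    """A compact but complete assay configuration."""
    return SimConfig(
        n_patients=60, n_somamers=40, removal_count=4, dup2_count=3, dup3_count=1,
        n_plates=2, calibrators_per_plate=3, qc_per_plate=2, buffer_per_plate=1,
        n_informative=6, seed=123,
    )


@pytest.fixture
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)
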