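import numpy as np
import pandas as pd
import pytest

from evuptake.containers import FeatureTable


def make_table(values, roles, injection=None, kind="lipid", annotations=None,
               rts=None, psm=None):
    """Compact FeatureTable builder for constructed fixtures.

    ``values``: dict feature_id -> list of abundances (np.nan = missing),
    ``roles``: list of sample roles aligned with the value lists.
    """
    frame = pd.DataFrame(values).T
    frame.columns = [f"S{i + 1}" for i in range(frame.shape[1])]
    frame.index.name = "feature_id"
    samples = pd.DataFrame(
        {"role": roles,
         "injection_order": injection or list(range(1, frame.shape[1] + 1))},
        index=frame.columns,
    )
    meta = pd.DataFrame(
        {
            "annotation": annotations or list(frame.index),
            "retention_time": rts if rts is not None else 5.0,
            "msi_level": 2,
        },
        index=frame.index,
    )
    psm_df = None
    if psm is not None:
        psm_df = pd.DataFrame(psm).T
        psm_df.columns = frame.columns
        psm_df.index = frame.index
    return FeatureTable(values=frame, meta=meta, samples=samples, kind=kind,
                        psm=psm_df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
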