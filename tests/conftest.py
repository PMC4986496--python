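import datetime as dt

import numpy as np
import pytest

from voxcalc.hu_calibration import (
    KV_STANDARD_LINE,
    builtin_mv_calibration_table,
    select_calibration,
)


@pytest.fixture(scope="session")
def mv_line():
    """The MV calibration in force mid-2013 on machine A (offset 8, slope 970)."""
    return select_calibration(dt.date(2013, 6, 1), "A", builtin_mv_calibration_table())


@pytest.fixture(scope="session")
def kv_line():
    return KV_STANDARD_LINE


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130601)


@pytest.fixture(scope="session")
def batch_dataset(tmp_path_factory):
    """A 3-patient x 4-fraction synthetic dataset (coarse preset), with one
    flagged fraction, in the hierarchical batch layout.  Generated once and
    copied by tests that need to mutate or run it."""
    from voxcalc.synthetic_data import make_dataset

    root = tmp_path_factory.mktemp("dataset") / "cohort"
    make_dataset(root, n_patients=3, n_fractions=4, seed=11,
                 flagged={"pat001": (2,)})
    return root
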