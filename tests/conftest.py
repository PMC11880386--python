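import numpy as np
import pytest

from hiskit import presets
from hiskit.cohort import reconstruct_joint_table, reconstruct_tps_table


def reconstruct_tables(cut):
    """Rebuild the (2x2, 2x2x2) tables of the reference cohort at a TPS cut."""
    margins = presets.TABLE1_MARGINS
    sens, spec = presets.UNIVARIATE_SENS_SPEC[cut]
    tps_table = reconstruct_tps_table(
        margins.n_resp, margins.n_nonresp, sens, spec,
        expected_positive_total=margins.tps_positive_total(cut),
    )
    c_sens, c_spec = presets.COMBINED_SENS_SPEC[cut]
    joint = reconstruct_joint_table(margins, cut, tps_table, c_sens, c_spec)
    return tps_table, joint


@pytest.fixture(scope="session")
def tables_by_cut():
    return {cut: reconstruct_tables(cut) for cut in presets.TPS_CUTS}


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
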