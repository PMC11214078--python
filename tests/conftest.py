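import numpy as np
import pytest

import leafmargin as lm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tissue():
    """3x3 grid with assigned fields (md_width 2, prox from row 2)."""
    t = lm.build_grid(3, 3)
    lm.assign_identity_fields(t, md_width=2, prox_start_row=2, prox_ramp_rows=1)
    lm.set_cuc_pattern(t, 1.0)
    return t


@pytest.fixture
def column_tissue():
    """1x7 single-column tissue for 1D polarity tests."""
    return lm.build_grid(7, 1)


def make_field(tissue, vy, p_tot=1.0, theta_np=0.1):
    """Polarity field with prescribed vertical components (vx = 0)."""
    vy = np.asarray(vy, dtype=float)
    vx = np.zeros_like(vy)
    mag = np.abs(vy)
    classes = np.where(
        mag < theta_np * p_tot, "nonpolar", np.where(vy > 0, "apical", "basal")
    )
    return lm.PolarityField(vx, vy, mag, classes.astype(str), p_tot, theta_np)
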