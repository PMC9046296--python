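import numpy as np
import pandas as pd
import pytest

from chondrostage.datatypes import INDICATORS, SampleProfile, StageLabel
from chondrostage.synthetic_data import (
    ImageConfig,
    make_stage_params,
    render_image,
    sample_cell_measurements,
)

ZERO_NOISE = ImageConfig(poisson_noise=False, read_noise_sd=0.0)


@pytest.fixture
def p2_params():
    return make_stage_params(StageLabel.P2)


@pytest.fixture
def zero_noise_image(p2_params):
    """A 20-cell zero-noise field of view with ground truth."""
    rng = np.random.default_rng(3)
    cells = sample_cell_measurements(p2_params, 20, rng)
    return render_image(cells, ZERO_NOISE, rng)


def make_profile(sample_id, values, stage=StageLabel.UNKNOWN, batch="b1"):
    """Profile with every indicator set to the same round vector."""
    frame = pd.DataFrame({ind: np.asarray(values, dtype=float) for ind in INDICATORS})
    return SampleProfile(sample_id=sample_id, batch_id=batch, stage=stage,
                         values=frame)


def match_labels(measured_mask, truth_mask, labels):
    """Measured label -> ground-truth label by majority pixel overlap."""
    out = {}
    for lbl in labels:
        vals, counts = np.unique(truth_mask[measured_mask == lbl],
                                 return_counts=True)
        out[int(lbl)] = int(vals[np.argmax(counts)])
    return out
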