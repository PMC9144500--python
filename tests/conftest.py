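"""Shared fixtures: small frames and session-scoped recovery runs."""

import numpy as np
import pytest

from dermaquant import Micrograph, make_skin_section
from dermaquant.pipeline import quantify_image

#: Reduced frame for unit tests; tall enough for the deepest preset front
#: (110 µm ≈ 312 px at 2.84 px/µm, with 3-SD biological jitter, below a
#: surface placed in the upper quarter).
SMALL_SHAPE = (576, 640)


def rgb(r, g, b, shape=(8, 8)):
    """Uniform RGB test image."""
    px = np.zeros(shape + (3,), dtype=np.uint8)
    px[..., 0], px[..., 1], px[..., 2] = r, g, b
    return Micrograph(px, scale=1.0)


@pytest.fixture(scope="session")
def recovery_runs():
    """Twenty seeded replicates per formulation arm, quantified.

    Session-scoped because several tests (depth recovery, fold changes,
    SCT recovery) share the same study conditions: 20 replicates,
    default frame and 2.84 px/µm scale.
    """
    presets = ["control_groupI", "nlc_groupII", "nlc_groupIII", "glycerol_control"]
    out = {}
    for name in presets:
        rows = []
        for rep in range(20):
            img, truth = make_skin_section(name, seed=100_000 + 997 * rep)
            m = quantify_image(img)
            m["depth_true"] = truth.depth_true
            rows.append(m)
        out[name] = rows
    return out
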