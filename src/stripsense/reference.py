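"""Published reference data from the original field deployment of this method.

The method was originally calibrated on 192 phone photographs of chlorine
test strips (three phone models, three lighting conditions).  This module
ships the published artifacts of that deployment as built-in constants: the
regression coefficients of the three calibration families and the binary and
multiclass confusion matrices of the trained classifier.  They let the
evaluation machinery be exercised on the published counts, and give users a
ready-made (if deployment-specific) model; synthetic scenes should train
their own calibration instead.
"""

from __future__ import annotations

import numpy as np

from .classify import BINARY, MULTICLASS, ConfusionMatrix

#: Published coefficients, keyed by family.  Term order matches the design
#: matrix each family builds; ``b`` is the intercept.  In the polynomial
#: family the printed report never explicitly binds its three predictors to
#: channels; the (R, G, B) order is assumed by analogy with the multiple
#: linear family and is recorded here as an assumption.
PUBLISHED_COEFFICIENTS: dict[str, dict[str, float]] = {
    "linear_sum": {"sum": -0.0070353, "b": 3.7360509},
    "multiple_rg": {"r": 0.015354, "g": -0.026582, "b": 1.878656},
    "polynomial_sq": {
        "r": 6.2720e-2,
        "g": -6.242e-2,
        "b_chan": -1.3970e-1,
        "r2": 1.297e-4,
        "g2": 4.526e-4,
        "b2": -1.626e-4,
        "b": 1.086e1,
    },
}

#: Adjusted R^2 reported alongside the published fits.
PUBLISHED_ADJ_R2 = {"linear_sum": 0.61, "multiple_rg": 0.71, "polynomial_sq": 0.75}

# Binary confusion matrices (rows = predicted, cols = true; positive class
# first).  97 processed training photos, 49 processed testing photos.
BINARY_TRAIN = ConfusionMatrix(BINARY, np.array([[46, 9], [1, 41]]))
BINARY_TEST = ConfusionMatrix(BINARY, np.array([[23, 1], [2, 23]]))

# Multiclass confusion matrices, same orientation, classes in increasing
# concentration order (<=0.2, 0.2-0.5, >0.5 mg/L).
MULTICLASS_TRAIN = ConfusionMatrix(MULTICLASS, np.array([[22, 2, 0], [8, 14, 1], [0, 9, 41]]))
MULTICLASS_TEST = ConfusionMatrix(MULTICLASS, np.array([[9, 1, 0], [2, 11, 1], [0, 2, 23]]))


def combined_multiclass() -> ConfusionMatrix:
    """Elementwise sum of the training and testing multiclass matrices."""
    return MULTICLASS_TRAIN + MULTICLASS_TEST


#: Per-group photo counts of the published capture campaign: group label ->
#: (concentration interval (lo, hi], complete count, training count).
PUBLISHED_GROUPS: dict[int, tuple[tuple[float, float], int, int]] = {
    1: ((0.0, 0.125), 21, 14),
    2: ((0.125, 0.2), 27, 18),
    3: ((0.2, 0.5), 54, 36),
    4: ((0.5, 1.0), 36, 24),
    5: ((1.0, 2.0), 46, 31),
    6: ((2.0, 4.0), 8, 6),
}

PUBLISHED_N_TOTAL = 192
PUBLISHED_N_TRAIN = 129
PUBLISHED_TRAIN_FRACTION = 0.67
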