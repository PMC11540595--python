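"""Printed summary statistics from the study, used as analysis inputs.

These are the published means, region presets and design constants that the
pipeline consumes (e.g., the mask-validation magnitude ratio is recomputed
from the printed ipsi/contra means rather than from raw recordings, which the
package does not require).
"""

from __future__ import annotations

# Mask validation: mean response magnitudes (average +/- SEM in the source).
GLOMERULAR_IPSI_MAGNITUDE = 7.9  # dF/F %, ipsilateral glomerular imaging
GLOMERULAR_CONTRA_MAGNITUDE = 0.93  # dF/F %, contralateral
MT_IPSI_MAGNITUDE_HZ = 1.6  # mitral/tufted cell recordings, ipsilateral
MT_CONTRA_MAGNITUDE_HZ = 0.16  # contralateral

# Region presets.
AON_BASELINE_HZ = 3.9
APC_BASELINE_HZ = 2.8
AON_SPARSENESS_IPSI = 0.224
AON_SPARSENESS_CONTRA = 0.252
AON_POSITIVE_FRACTION = 0.46
APC_POSITIVE_FRACTION = 0.48
AON_BCN_SLOPE = 0.79
APC_BCN_SLOPE = 0.69

# Study design.
N_ODORS = 15
N_SIDES = 2
N_REPS = 7

# Reported best-fit structure weight for the AON.
AON_FITTED_ALPHA = 0.42


def magnitude_ratio(contra_mean: float, ipsi_mean: float, ndigits: int = 2) -> float:
    """Contra/ipsi mean-magnitude ratio, rounded as reported."""
    if ipsi_mean <= 0:
        raise ValueError("ipsilateral mean must be positive")
    return round(contra_mean / ipsi_mean, ndigits)
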