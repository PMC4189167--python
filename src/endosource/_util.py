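"""Small shared helpers."""
from __future__ import annotations

import numpy as np


def round_half_up(x):
    """Round to the nearest integer, halves away from zero-for-positives.

    Fragment sizes are non-negative, so this is plain round-half-up:
    26.5 -> 27, 26.4 -> 26. numpy's ``round`` rounds halves to even,
    which would split the x.5 boundary between adjacent bins.
    """
    arr = np.floor(np.asarray(x, dtype=float) + 0.5)
    if np.isscalar(x) or np.ndim(x) == 0:
        return int(arr)
    return arr.astype(int)
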