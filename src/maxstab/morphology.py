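"""Small shared morphology helpers."""

from __future__ import annotations

import inspect

import numpy as np
from skimage.morphology import remove_small_objects

# skimage >= 0.26 renamed min_size (exclusive) to max_size (inclusive)
_HAS_MAX_SIZE = "max_size" in inspect.signature(remove_small_objects).parameters


def remove_small_components(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop connected components with fewer than ``min_size`` true voxels."""
    if min_size <= 1:
        return mask.copy()
    if _HAS_MAX_SIZE:
        return remove_small_objects(mask, max_size=min_size - 1)
    return remove_small_objects(mask, min_size=min_size)
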