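"""Enhancing-tumor segmentation from pre/post-contrast T1-weighted volumes.

Both volumes are normalized by their brain-median signal (removing global
gain differences), subtracted voxel-by-voxel, and voxels with at least a 10 %
signal increase relative to their pre-contrast value — inside the lesion
outline — form the enhancing-tumor mask. Small connected clusters are removed
as salt-and-pepper noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

DEFAULT_THRESHOLD = 0.10
DEFAULT_MIN_CLUSTER = 5


def normalize_t1w(volume: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Divide a T1-weighted volume by its brain-mask median (output median 1)."""
    volume = np.asarray(volume, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    vals = volume[brain_mask]
    med = np.nanmedian(vals)
    if not np.isfinite(med) or med <= 0:
        raise ValueError("nonpositive brain-median signal; cannot normalize")
    return volume / med


@dataclass
class SubtractionResult:
    normalized_pre: np.ndarray
    normalized_post: np.ndarray
    subtraction: np.ndarray
    enhancing_mask: np.ndarray


def enhancing_tumor_mask(
    pre: np.ndarray,
    post: np.ndarray,
    brain_mask: np.ndarray,
    lesion_mask: np.ndarray | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
) -> SubtractionResult:
    """Enhancing-tumor mask via the normalized-subtraction >= 10 % rule.

    A voxel enhances when ``post_n - pre_n >= threshold * pre_n`` after
    brain-median normalization of both volumes. The rule is restricted to the
    lesion outline when one is given; connected components (26-connectivity)
    smaller than ``min_cluster`` voxels are dropped. An empty result is valid
    (a non-enhancing lesion) and returned as an all-False mask.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    pre_n = normalize_t1w(np.asarray(pre, float), brain_mask)
    post_n = normalize_t1w(np.asarray(post, float), brain_mask)
    sub = post_n - pre_n
    with np.errstate(invalid="ignore"):
        mask = (sub >= threshold * pre_n) & brain_mask
    if lesion_mask is not None:
        mask &= np.asarray(lesion_mask, dtype=bool)
    if min_cluster > 1 and mask.any():
        structure = np.ones((3,) * mask.ndim, dtype=bool)
        labels, n = ndimage.label(mask, structure=structure)
        if n:
            counts = np.bincount(labels.ravel())
            keep = counts >= min_cluster
            keep[0] = False
            mask = keep[labels]
    return SubtractionResult(
        normalized_pre=pre_n,
        normalized_post=post_n,
        subtraction=sub,
        enhancing_mask=mask,
    )
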