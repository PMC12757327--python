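"""The Mk-Mask degradation operator.

A generated complete shape cannot be compared to a partial scan directly:
the scan misses whole regions. The mask degrades the generated cloud into
a shape akin to the partial input by keeping, for every partial point,
its K nearest generated points, and taking the union of those
neighborhoods. Applied at each pyramid level this yields the degraded
triplet (X_b, X_b', X_b'') that the reconstruction and feature-matching
losses compare against the partial input's pyramid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_geometry import PointCloud, _coords
from .sampling import ResolutionPyramid, knn_query

__all__ = ["DegradedTriplet", "mk_mask", "mk_mask_indices", "degrade_pyramid"]


@dataclass
class DegradedTriplet:
    """Per-level masked subsets of a generated pyramid."""

    xb: PointCloud
    xb_prime: PointCloud
    xb_dprime: PointCloud
    k_used: int

    def levels(self):
        return (self.xb, self.xb_prime, self.xb_dprime)


def mk_mask_indices(generated, partial, K: int) -> np.ndarray:
    """Sorted unique indices of generated points kept by the mask.

    The union over all partial points of the indices of their K nearest
    generated points. Sorted ascending, so the result is independent of
    the point order of the partial input.
    """
    idx = knn_query(partial, generated, K)
    return np.unique(idx)


def mk_mask(generated, partial, K: int) -> PointCloud:
    """Degrade ``generated`` to the union of K-neighborhoods of ``partial``.

    The output is a deduplicated subset of the generated cloud with at
    most ``min(|generated|, K·|partial|)`` points; with ``K = 1`` and
    ``partial == generated`` it is the identity.
    """
    gen = _coords(generated)
    keep = mk_mask_indices(gen, partial, K)
    out = gen[keep]
    if isinstance(generated, PointCloud):
        return generated.with_points(out)
    return PointCloud(out)


def degrade_pyramid(
    gen_pyramid: ResolutionPyramid,
    partial_pyramid: ResolutionPyramid,
    K: int,
    k_schedule=None,
) -> DegradedTriplet:
    """Mask each generated pyramid level against the matching partial level.

    The same K is used at every level by default; ``k_schedule`` may give
    a per-level ``(K1, K2, K3)`` override.
    """
    ks = tuple(k_schedule) if k_schedule is not None else (K, K, K)
    if len(ks) != 3:
        raise ValueError("k_schedule must provide exactly three values")
    xb = mk_mask(gen_pyramid.level1, partial_pyramid.level1, ks[0])
    xbp = mk_mask(gen_pyramid.level2, partial_pyramid.level2, ks[1])
    xbd = mk_mask(gen_pyramid.level3, partial_pyramid.level3, ks[2])
    return DegradedTriplet(xb, xbp, xbd, k_used=ks[0])
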