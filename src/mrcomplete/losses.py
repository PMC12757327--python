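"""The inversion training objective.

Two components drive the joint search over latent code and generator
parameters:

* a multi-stage reconstruction loss — squared Chamfer (CD-T) between the
  masked generated cloud and the partial input at each pyramid level,
  with the coarser stages down-weighted by α and β::

      T_C = CD-T(X_b, X_in) + α·CD-T(X_b', X_in') + β·CD-T(X_b'', X_in'')

* a multi-scale feature-matching loss — the L1 distance between
  discriminator features of the masked cloud and of the partial input,
  summed over the three per-level discriminators::

      T_D = Σ_l ‖D_l(X_b^l) − D_l(X_in^l)‖₁

The total objective is the convex combination ``T = h_C·T_C + h_D·T_D``
with ``h_C + h_D = 1`` enforced at construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .degradation import DegradedTriplet
from .metrics import cd_t
from .sampling import ResolutionPyramid

__all__ = [
    "LossWeights",
    "multi_stage_reconstruction",
    "feature_matching",
    "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the objective; ``h_c + h_d`` must equal one.

    Defaults down-weight the coarser reconstruction stages geometrically
    (α = 0.5, β = 0.25) and keep the objective reconstruction-dominant
    (h_C = 0.8, h_D = 0.2): feature matching refines detail, Chamfer
    alignment carries the overall shape.
    """

    alpha: float = 0.5
    beta: float = 0.25
    h_c: float = 0.8
    h_d: float = 0.2

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if not (0.0 <= self.h_c <= 1.0 and 0.0 <= self.h_d <= 1.0):
            raise ValueError("h_c and h_d must lie in [0, 1]")
        if abs(self.h_c + self.h_d - 1.0) > 1e-9:
            raise ValueError(
                f"h_c + h_d must equal 1, got {self.h_c} + {self.h_d}"
            )


def multi_stage_reconstruction(
    triplet: DegradedTriplet,
    partial_pyramid: ResolutionPyramid,
    w: LossWeights,
) -> float:
    """CD-T summed over pyramid stages with α/β stage weights."""
    xb, xbp, xbd = triplet.levels()
    pin, pinp, pind = partial_pyramid.levels()
    return (
        cd_t(xb, pin)
        + w.alpha * cd_t(xbp, pinp)
        + w.beta * cd_t(xbd, pind)
    )


def feature_matching(
    triplet: DegradedTriplet,
    partial_pyramid: ResolutionPyramid,
    discriminators: Sequence,
) -> float:
    """Sum over levels of L1 distance between discriminator features.

    ``discriminators`` are the three per-level discriminators (objects
    exposing ``features(cloud) -> (vector, score)``); the feature vector
    is the pooled global descriptor before the classification head.
    """
    if len(discriminators) != 3:
        raise ValueError("exactly three discriminators are required")
    total = 0.0
    for disc, degraded, partial in zip(
        discriminators, triplet.levels(), partial_pyramid.levels()
    ):
        f_deg, _ = disc.features(degraded)
        f_in, _ = disc.features(partial)
        f_deg = np.asarray(f_deg, dtype=np.float64)
        f_in = np.asarray(f_in, dtype=np.float64)
        if f_deg.shape != f_in.shape:
            raise ValueError(
                f"feature-vector length mismatch: {f_deg.shape} vs {f_in.shape}"
            )
        total += float(np.sum(np.abs(f_deg - f_in)))
    return total


def total_loss(tc: float, td: float, w: LossWeights) -> float:
    """Weighted total objective ``h_C·T_C + h_D·T_D``."""
    return w.h_c * tc + w.h_d * td
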