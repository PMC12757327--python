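"""Point-cloud distances: CD-T, CD-P, UCD, UHD and the F-score.

Conventions (d(a, B) is the Euclidean distance from a to its nearest
neighbor in B):

* ``CD-T(X, Y) = mean_x d(x, Y)^2 + mean_y d(y, X)^2`` — squared two-sided
  Chamfer, the training metric.
* ``CD-P(X, Y) = (mean_x d(x, Y) + mean_y d(y, X)) / 2`` — unsquared.
* ``UCD(P, F) = mean_p d(p, F)^2`` — one-directional, partial → full; no
  ground truth needed.
* ``UHD(P, F) = max_p d(p, F)`` — one-directional Hausdorff, unsquared.
* ``F-score@τ`` — harmonic mean (in percent) of the fraction of predicted
  points within τ of the truth (precision) and vice versa (recall).

Published numbers are conventionally scaled for readability (CD and UCD
×10^4, UHD ×10^2); :meth:`MetricReport.to_report_dict` applies those
scales at the reporting layer only — raw values feed the losses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .core_geometry import _coords

__all__ = [
    "MetricReport",
    "cd_t",
    "cd_p",
    "ucd",
    "uhd",
    "f_score",
    "nn_distances",
    "DEFAULT_F_SCORE_TAU",
]

#: Default F-score threshold: 1% of the normalized (-1,1) unit scale.
DEFAULT_F_SCORE_TAU = 0.01


def nn_distances(src, dst) -> np.ndarray:
    """Euclidean distance from each src point to its nearest dst point."""
    s = _coords(src)
    d = _coords(dst)
    if s.shape[0] * d.shape[0] <= 4096:
        return np.sqrt(
            np.min(np.sum((s[:, None, :] - d[None, :, :]) ** 2, axis=2), axis=1)
        )
    dist, _ = cKDTree(d).query(s, k=1)
    return dist


def cd_t(x, y) -> float:
    """Two-sided squared Chamfer distance (training variant)."""
    return float(np.mean(nn_distances(x, y) ** 2) + np.mean(nn_distances(y, x) ** 2))


def cd_p(x, y) -> float:
    """Two-sided unsquared Chamfer distance, averaged over directions."""
    return float((np.mean(nn_distances(x, y)) + np.mean(nn_distances(y, x))) / 2.0)


def ucd(partial, full) -> float:
    """Unidirectional (partial → full) mean squared nearest distance."""
    return float(np.mean(nn_distances(partial, full) ** 2))


def uhd(partial, full) -> float:
    """Unidirectional (partial → full) Hausdorff (max unsquared) distance."""
    return float(np.max(nn_distances(partial, full)))


def f_score(pred, truth, tau: float = DEFAULT_F_SCORE_TAU) -> float:
    """F-score@τ in percent: harmonic mean of precision and recall."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    precision = float(np.mean(nn_distances(pred, truth) <= tau))
    recall = float(np.mean(nn_distances(truth, pred) <= tau))
    if precision + recall == 0.0:
        return 0.0
    return 100.0 * 2.0 * precision * recall / (precision + recall)


@dataclass
class MetricReport:
    """Bundle of the five evaluation metrics for one completion.

    Raw (unscaled) values; ``to_report_dict`` applies the conventional
    reporting scales. UCD/UHD are measured against the partial input and
    are available without ground truth; cd/f_score need the truth cloud.
    """

    cd_t: Optional[float] = None
    cd_p: Optional[float] = None
    ucd: Optional[float] = None
    uhd: Optional[float] = None
    f_score: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("cd_t", "cd_p", "ucd", "uhd", "f_score"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.f_score is not None and self.f_score > 100.0:
            raise ValueError(f"f_score must be <= 100, got {self.f_score}")

    @classmethod
    def evaluate(cls, completed, truth=None, partial=None,
                 tau: float = DEFAULT_F_SCORE_TAU) -> "MetricReport":
        report = cls()
        if truth is not None:
            report.cd_t = cd_t(completed, truth)
            report.cd_p = cd_p(completed, truth)
            report.f_score = f_score(completed, truth, tau)
        if partial is not None:
            report.ucd = ucd(partial, completed)
            report.uhd = uhd(partial, completed)
        return report

    def to_report_dict(self) -> dict:
        """Metrics at publication scales: CD/UCD ×10^4, UHD ×10^2."""
        out = {}
        if self.cd_t is not None:
            out["cd_t_x1e4"] = self.cd_t * 1e4
        if self.cd_p is not None:
            out["cd_p"] = self.cd_p
        if self.ucd is not None:
            out["ucd_x1e4"] = self.ucd * 1e4
        if self.uhd is not None:
            out["uhd_x1e2"] = self.uhd * 1e2
        if self.f_score is not None:
            out["f_score"] = self.f_score
        return out
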