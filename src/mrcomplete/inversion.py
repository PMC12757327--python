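"""Completion by GAN inversion with multi-resolution degradation.

Given a pretrained generator ``G(y; δ)`` and a partial scan ``X_in``,
completion is the search::

    y*, δ* = argmin_{y, δ}  E( N(G(y; δ)), X_in )

where ``N`` is the multi-resolution degradation: the generated cloud is
farthest-point-sampled into a 2048/1024/512 pyramid, each level is
Mk-masked against the matching level of the partial input's pyramid, and
the objective combines per-stage squared Chamfer distances with the
per-level discriminator feature-matching loss (see :mod:`.losses`).

The latent is initialized by scoring a large seeded random sample of
prior draws with the degraded objective and keeping the argmin; ``y``
and ``δ`` are then refined jointly by Adam with separate step sizes.
The best-objective iterate (not the last) is returned, since the
adversarial term can oscillate. Generator adaptation is per instance:
the inversion works on a copy of ``δ``, so the pretrained model is
untouched and consecutive completions are independent.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core_geometry import PointCloud, _coords, center, normalize, read_cloud, write_cloud
from .degradation import mk_mask_indices
from .gan import Adam, Discriminator, Generator, LatentCode, load_model
from .losses import LossWeights
from .metrics import MetricReport
from .sampling import PYRAMID_SIZES, build_partial_pyramid, ifps_indices

__all__ = [
    "InversionConfig",
    "CompletionResult",
    "InversionDivergenceError",
    "init_latent",
    "invert",
    "complete",
    "complete_directory",
]

#: Default neighborhood size of the Mk-Mask degradation.
DEFAULT_K = 50


class InversionDivergenceError(RuntimeError):
    """Objective became non-finite; carries the trace up to that point."""

    def __init__(self, message: str, trace: List[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class InversionConfig:
    """Settings of the completion search.

    ``latent_step``/``delta_step`` are the Adam learning rates for the
    latent code and the generator parameters; the much smaller δ step
    keeps the per-instance adaptation close to the pretrained prior.
    ``schedule`` is "joint" (update both every iteration) or
    "alternating" (y on even, δ on odd iterations). ``decay`` scales
    both step sizes over the run: "none" keeps them constant, "cosine"
    anneals them to zero, which settles the iterates instead of
    bouncing around the optimum.
    """

    n_init_samples: int = 256
    n_iterations: int = 200
    latent_step: float = 0.01
    delta_step: float = 0.0001
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    K: int = DEFAULT_K
    schedule: str = "joint"
    decay: str = "none"

    def __post_init__(self) -> None:
        if self.n_init_samples < 1 or self.n_iterations < 0:
            raise ValueError("n_init_samples must be >= 1, n_iterations >= 0")
        if self.latent_step <= 0 or self.delta_step <= 0:
            raise ValueError("step sizes must be positive")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.schedule not in ("joint", "alternating"):
            raise ValueError("schedule must be 'joint' or 'alternating'")
        if self.decay not in ("none", "cosine"):
            raise ValueError("decay must be 'none' or 'cosine'")


@dataclass
class CompletionResult:
    """Outcome of one inversion run."""

    completed: PointCloud
    best_latent: LatentCode
    adapted_delta: dict
    objective_trace: List[float]
    metrics: MetricReport
    #: generation at the initialization latent, before any refinement
    init_completed: Optional[PointCloud] = None

    def __post_init__(self) -> None:
        if not self.objective_trace:
            raise ValueError("objective trace must be non-empty")


# ---------------------------------------------------------------------------
# Objective: value and analytic gradient wrt the generated coordinates.
# ---------------------------------------------------------------------------

def _cd_t_grad(xb: np.ndarray, xin: np.ndarray,
               xin_tree: cKDTree) -> Tuple[float, np.ndarray]:
    """CD-T(xb, xin) and its gradient wrt the rows of ``xb``.

    With nearest-neighbor assignments held fixed, each direction of the
    squared Chamfer distance is a mean of quadratics, so the gradient is
    exact wherever assignments are locally constant.
    """
    nb, nc = xb.shape[0], xin.shape[0]
    d_b, j_b = xin_tree.query(xb, k=1)
    value = float(np.mean(d_b ** 2))
    grad = (2.0 / nb) * (xb - xin[j_b])
    tree_b = cKDTree(xb)
    d_c, j_c = tree_b.query(xin, k=1)
    value += float(np.mean(d_c ** 2))
    np.add.at(grad, j_c, (2.0 / nc) * (xb[j_c] - xin))
    return value, grad


def masked_objective(
    points: np.ndarray,
    partial_levels: Sequence[np.ndarray],
    partial_trees: Sequence[cKDTree],
    partial_feats: Sequence[np.ndarray],
    discriminators: Sequence[Discriminator],
    w: LossWeights,
    K: int,
    level_indices: Optional[Sequence[np.ndarray]] = None,
) -> Tuple[float, np.ndarray, dict]:
    """Degraded multi-stage objective and its gradient wrt ``points``.

    ``points`` is the full generated cloud; ``level_indices`` gives the
    (nested) pyramid selections as global index arrays, recomputed by
    IFPS when omitted. Returns ``(objective, grad_points, parts)`` where
    ``parts`` holds the reconstruction and feature components.
    """
    m = points.shape[0]
    if level_indices is None:
        idx1 = np.arange(m)
        idx2 = ifps_indices(points, min(PYRAMID_SIZES[1], m))
        idx3 = idx2[ifps_indices(points[idx2], min(PYRAMID_SIZES[2], len(idx2)))]
        level_indices = (idx1, idx2, idx3)

    stage_w = (1.0, w.alpha, w.beta)
    grad = np.zeros_like(points)
    tc = 0.0
    td = 0.0
    for l in range(3):
        gidx = level_indices[l]
        gen_l = points[gidx]
        k_l = min(K, gen_l.shape[0])
        keep = mk_mask_indices(gen_l, partial_levels[l], k_l)
        gmask = gidx[keep]
        xb = points[gmask]

        e_l, g_rec = _cd_t_grad(xb, partial_levels[l], partial_trees[l])
        tc += stage_w[l] * e_l
        g_xb = w.h_c * stage_w[l] * g_rec

        if w.h_d > 0.0 and discriminators is not None:
            cache, f_b, _ = discriminators[l].forward_cached(xb)
            diff = f_b - partial_feats[l]
            td += float(np.sum(np.abs(diff)))
            g_feat = discriminators[l].backward_input(
                cache, grad_f=w.h_d * np.sign(diff)
            )
            g_xb = g_xb + g_feat

        np.add.at(grad, gmask, g_xb)

    objective = w.h_c * tc + w.h_d * td
    return objective, grad, {"tc": tc, "td": td}


def _prepare_partial(partial, discriminators, w: LossWeights):
    pyr = build_partial_pyramid(partial)
    levels = [np.ascontiguousarray(_coords(lv)) for lv in pyr.levels()]
    trees = [cKDTree(lv) for lv in levels]
    feats = [None, None, None]
    if w.h_d > 0.0 and discriminators is not None:
        feats = [discriminators[l].features(levels[l])[0] for l in range(3)]
    return pyr, levels, trees, feats


# ---------------------------------------------------------------------------
# Latent initialization by seeded random search.
# ---------------------------------------------------------------------------

def init_latent_scored(
    g: Generator, partial, cfg: InversionConfig
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Score ``n_init_samples`` prior draws; return (latents, scores, argmin).

    Each candidate is scored by the degraded objective: the generated
    cloud is Mk-masked against the partial input and compared by CD-T
    (reconstruction only — no discriminator term during initialization).
    """
    xin = np.ascontiguousarray(_coords(partial))
    tree = cKDTree(xin)
    rng = np.random.default_rng(cfg.seed)
    latents = rng.standard_normal((cfg.n_init_samples, g.latent_dim))
    scores = np.empty(cfg.n_init_samples)
    for i, y in enumerate(latents):
        _, pts = g.forward_cached(y)
        keep = mk_mask_indices(pts, xin, min(cfg.K, pts.shape[0]))
        scores[i], _ = _cd_t_grad(pts[keep], xin, tree)
    return latents, scores, int(np.argmin(scores))


def init_latent(g: Generator, partial, cfg: InversionConfig) -> LatentCode:
    """The prior draw with the smallest degraded objective."""
    latents, _, best = init_latent_scored(g, partial, cfg)
    return LatentCode(latents[best])


# ---------------------------------------------------------------------------
# The inversion loop.
# ---------------------------------------------------------------------------

def invert(
    g: Generator,
    discriminators: Optional[Sequence[Discriminator]],
    partial,
    cfg: Optional[InversionConfig] = None,
    truth=None,
) -> CompletionResult:
    """Complete a partial cloud by joint (y, δ) optimization.

    The partial input must be normalized to (-1, 1) and hold at least
    512 points (so its pyramid is constructible). ``g`` is never
    mutated: δ adaptation happens on an internal copy. The trace holds
    the objective at the initialization and after every iteration; the
    returned completion is the iterate with the smallest objective.
    """
    cfg = cfg or InversionConfig()
    xin = _coords(partial)
    if np.abs(xin).max() > 1.0 + 1e-6:
        raise ValueError("partial input is not normalized to (-1, 1)")
    if xin.shape[0] < PYRAMID_SIZES[2]:
        raise ValueError(
            f"partial input needs at least {PYRAMID_SIZES[2]} points, "
            f"got {xin.shape[0]}"
        )
    w = cfg.weights
    if w.h_d > 0.0 and discriminators is None:
        raise ValueError("discriminators required when h_d > 0")

    work = g.clone()
    _, levels, trees, feats = _prepare_partial(xin, discriminators, w)

    y = init_latent(work, xin, cfg).y.copy()
    y_opt = Adam({"y": y}, cfg.latent_step)
    d_opt = Adam(work.delta, cfg.delta_step)

    trace: List[float] = []
    best = None  # (objective, y, delta, points)
    init_pts = None

    for it in range(cfg.n_iterations + 1):
        g_cache, pts = work.forward_cached(y)
        if it == 0:
            init_pts = pts.copy()
        obj, grad_pts, parts = masked_objective(
            pts, levels, trees, feats, discriminators, w, cfg.K
        )
        if not np.isfinite(obj):
            raise InversionDivergenceError(
                f"objective became non-finite at iteration {it}", trace
            )
        trace.append(obj)
        if best is None or obj < best[0]:
            best = (obj, y.copy(), work.copy_delta(), pts.copy())
        if it == cfg.n_iterations:
            break
        d_grads, grad_y = work.backward(g_cache, grad_pts)
        if cfg.decay == "cosine":
            scale = 0.5 * (1.0 + np.cos(np.pi * it / max(cfg.n_iterations, 1)))
            y_opt.lr = cfg.latent_step * scale
            d_opt.lr = cfg.delta_step * scale
        update_y = cfg.schedule == "joint" or it % 2 == 0
        update_d = cfg.schedule == "joint" or it % 2 == 1
        if update_y:
            y_opt.step({"y": y}, {"y": grad_y})
        if update_d:
            d_opt.step(work.delta, d_grads)

    _, best_y, best_delta, best_pts = best
    completed = PointCloud(best_pts, source="inversion")
    report = MetricReport.evaluate(completed, truth=truth, partial=xin)
    return CompletionResult(
        completed=completed,
        best_latent=LatentCode(best_y),
        adapted_delta=best_delta,
        objective_trace=trace,
        metrics=report,
        init_completed=PointCloud(init_pts, source="inversion-init"),
    )


# ---------------------------------------------------------------------------
# End-to-end file wrappers.
# ---------------------------------------------------------------------------

def complete(
    model_path: str,
    partial_path: str,
    cfg: Optional[InversionConfig] = None,
    truth_path: Optional[str] = None,
    out_path: Optional[str] = None,
    report_path: Optional[str] = None,
    preprocess: bool = True,
) -> CompletionResult:
    """Load model and scan, preprocess, invert, write outputs.

    ``preprocess`` recenters and normalizes the partial scan; disable it
    when the scan is already expressed in the normalized frame of its
    ground truth (synthetic crops).
    """
    model = load_model(model_path)
    partial = read_cloud(partial_path)
    if preprocess:
        partial = normalize(center(partial))
    truth = read_cloud(truth_path) if truth_path else None
    result = invert(model.generator, model.discriminators, partial,
                    cfg=cfg, truth=truth)
    if out_path:
        write_cloud(result.completed, out_path)
    if report_path:
        report = {
            "partial": partial_path,
            "n_points": len(result.completed),
            "objective_trace": result.objective_trace,
            **result.metrics.to_report_dict(),
        }
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return result


def complete_directory(
    model_path: str,
    in_dir: str,
    out_dir: str,
    cfg: Optional[InversionConfig] = None,
    preprocess: bool = True,
) -> List[CompletionResult]:
    """Complete every ``*.xyz``/``*.ply`` cloud in a directory, one at a
    time (completion batch size is 1; results are emitted sequentially)."""
    os.makedirs(out_dir, exist_ok=True)
    results = []
    for name in sorted(os.listdir(in_dir)):
        if not name.lower().endswith((".xyz", ".ply")):
            continue
        stem = os.path.splitext(name)[0]
        results.append(complete(
            model_path,
            os.path.join(in_dir, name),
            cfg=cfg,
            out_path=os.path.join(out_dir, f"{stem}_completed.xyz"),
            report_path=os.path.join(out_dir, f"{stem}_report.json"),
            preprocess=preprocess,
        ))
    return results
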