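import numpy as np
import pytest
from scipy.spatial import cKDTree

import mrcomplete as mc
from mrcomplete import Discriminator, Generator, InversionConfig, LossWeights
from mrcomplete.inversion import init_latent_scored, masked_objective
from mrcomplete.sampling import ifps_indices


def cropped_carton(seed=0, keep_axis=0):
    """A normalized carton and its half-space-cropped partial, same frame."""
    truth = mc.carton_dataset(1, seed=100 + seed)[0]
    normal = np.zeros(3)
    normal[keep_axis] = 1.0
    scan = mc.ScanSpec(occlusion=("halfspace", tuple(normal), 0.0), seed=seed)
    return truth, mc.simulate_partial_scan(truth, scan)


@pytest.fixture
def small_setup():
    """Generator + discriminators + partial, sized for fast iteration."""
    gen = Generator(seed=11)
    discs = tuple(Discriminator(level=l, seed=20 + l) for l in (1, 2, 3))
    _, partial = cropped_carton(seed=1)
    return gen, discs, partial


class TestObjectiveGradient:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        """The loss is differentiable in the generated coordinates wherever
        nearest-neighbor assignments are locally constant."""
        discs = tuple(
            Discriminator(level=l, feature_width=8, point_hidden=8, seed=l)
            for l in (1, 2, 3)
        )
        pts = rng.normal(size=(40, 3)) * 0.5
        idx1 = np.arange(40)
        idx2 = ifps_indices(pts, 20)
        idx3 = idx2[ifps_indices(pts[idx2], 10)]
        levels = [rng.normal(size=(n, 3)) * 0.5 for n in (15, 8, 4)]
        trees = [cKDTree(l) for l in levels]
        w = LossWeights()
        feats = [discs[l].features(levels[l])[0] for l in range(3)]

        def value(p):
            obj, _, _ = masked_objective(
                p, levels, trees, feats, discs, w, K=3,
                level_indices=(idx1, idx2, idx3),
            )
            return obj

        _, grad, _ = masked_objective(
            pts, levels, trees, feats, discs, w, K=3,
            level_indices=(idx1, idx2, idx3),
        )
        eps = 1e-6
        rng2 = np.random.default_rng(1)
        checked = 0
        for _ in range(12):
            i, j = rng2.integers(0, 40), rng2.integers(0, 3)
            e = np.zeros((40, 3)); e[i, j] = eps
            fd = (value(pts + e) - value(pts - e)) / (2 * eps)
            assert grad[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)
            checked += 1
        assert checked == 12


class TestInitLatent:
    def test_single_sample_returned(self, small_setup):
        gen, _, partial = small_setup
        cfg = InversionConfig(n_init_samples=1, seed=3)
        code = mc.init_latent(gen, partial, cfg)
        expected = np.random.default_rng(3).standard_normal((1, 96))[0]
        np.testing.assert_array_equal(code.y, expected)

    def test_argmin_of_scored_candidates(self, small_setup):
        gen, _, partial = small_setup
        cfg = InversionConfig(n_init_samples=16, seed=4)
        latents, scores, best = init_latent_scored(gen, partial, cfg)
        assert scores[best] == scores.min()
        code = mc.init_latent(gen, partial, cfg)
        np.testing.assert_array_equal(code.y, latents[best])

    def test_planted_latent_recovered(self):
        """If a candidate generated the (uncropped) input exactly, its
        objective is zero and it must be returned."""
        gen = Generator(seed=21)
        cfg = InversionConfig(n_init_samples=32, seed=6)
        candidates = np.random.default_rng(6).standard_normal((32, 96))
        planted = candidates[17]
        partial = gen.generate(planted)
        code = mc.init_latent(gen, partial.points, cfg)
        np.testing.assert_array_equal(code.y, planted)
        _, scores, best = init_latent_scored(gen, partial.points, cfg)
        assert best == 17
        assert scores[17] == pytest.approx(0.0, abs=1e-12)


class TestInvert:
    def test_zero_iterations_returns_best_init_generation(self, small_setup):
        gen, discs, partial = small_setup
        cfg = InversionConfig(n_iterations=0, n_init_samples=8, seed=5)
        res = mc.invert(gen, discs, partial, cfg)
        assert len(res.objective_trace) == 1
        expect = gen.generate(mc.init_latent(gen, partial, cfg))
        assert np.array_equal(res.completed.points, expect.points)

    def test_seeded_determinism(self, small_setup):
        gen, discs, partial = small_setup
        cfg = InversionConfig(n_iterations=5, n_init_samples=8, seed=9)
        a = mc.invert(gen, discs, partial, cfg)
        b = mc.invert(gen, discs, partial, cfg)
        assert np.array_equal(a.completed.points, b.completed.points)
        assert a.objective_trace == b.objective_trace

    def test_best_iterate_not_worse_than_init(self, small_setup):
        gen, discs, partial = small_setup
        cfg = InversionConfig(n_iterations=20, n_init_samples=8, seed=2)
        res = mc.invert(gen, discs, partial, cfg)
        assert len(res.objective_trace) == 21
        assert np.isfinite(res.objective_trace).all()
        assert min(res.objective_trace) <= res.objective_trace[0]
        best = min(res.objective_trace)
        # the returned iterate carries the minimum recorded objective
        re_gen = gen.clone()
        re_gen.set_delta(res.adapted_delta)
        assert len(res.completed) == 2048

    def test_per_instance_isolation(self, small_setup):
        gen, discs, partial = small_setup
        delta_before = gen.copy_delta()
        cfg = InversionConfig(n_iterations=4, n_init_samples=4, seed=1)
        _, partial_b = cropped_carton(seed=2, keep_axis=1)
        mc.invert(gen, discs, partial, cfg)  # completion A
        res_after_a = mc.invert(gen, discs, partial_b, cfg)
        res_alone = mc.invert(gen, discs, partial_b, cfg)
        # the pretrained generator is untouched, so B is unaffected by A
        for k in delta_before:
            assert np.array_equal(gen.delta[k], delta_before[k])
        assert np.array_equal(res_after_a.completed.points,
                              res_alone.completed.points)

    def test_unnormalized_partial_rejected(self, small_setup, rng):
        gen, discs, _ = small_setup
        with pytest.raises(ValueError, match="normalized"):
            mc.invert(gen, discs, rng.normal(size=(600, 3)) * 10)

    def test_too_small_partial_rejected(self, small_setup, rng):
        gen, discs, _ = small_setup
        with pytest.raises(ValueError, match="at least"):
            mc.invert(gen, discs, rng.uniform(-1, 1, size=(100, 3)))

    def test_ucd_not_worse_than_best_init(self, small_setup):
        gen, discs, partial = small_setup
        base = InversionConfig(n_iterations=0, n_init_samples=8, seed=3)
        cfg = InversionConfig(n_iterations=30, n_init_samples=8, seed=3)
        res0 = mc.invert(gen, discs, partial, base)
        res = mc.invert(gen, discs, partial, cfg)
        assert mc.ucd(partial, res.completed) <= mc.ucd(partial, res0.completed)

    def test_metrics_populated(self, small_setup):
        gen, discs, partial = small_setup
        truth, _ = cropped_carton(seed=1)
        cfg = InversionConfig(n_iterations=2, n_init_samples=4, seed=0)
        res = mc.invert(gen, discs, partial, cfg, truth=truth)
        assert res.metrics.ucd is not None and res.metrics.uhd is not None
        assert res.metrics.cd_t is not None and res.metrics.f_score is not None


class TestFileWrappers:
    def test_complete_end_to_end_files(self, tmp_path):
        clouds = mc.carton_dataset(8, seed=0)
        model = mc.pretrain_gan(
            clouds, mc.TrainConfig(epochs=1, batch_size=4, seed=0)
        )
        model_path = str(tmp_path / "model.npz")
        mc.save_model(model, model_path)
        truth, partial = cropped_carton(seed=4)
        partial_path = str(tmp_path / "partial.xyz")
        mc.write_cloud(partial, partial_path)
        out_path = str(tmp_path / "completed.xyz")
        report_path = str(tmp_path / "report.json")
        cfg = InversionConfig(n_iterations=2, n_init_samples=4, seed=0)
        res = mc.complete(model_path, partial_path, cfg=cfg,
                          out_path=out_path, report_path=report_path,
                          preprocess=False)
        assert len(res.completed) == 2048
        written = mc.read_cloud(out_path)
        assert len(written) == 2048
        import json

        report = json.loads(open(report_path).read())
        assert report["n_points"] == 2048
        assert len(report["objective_trace"]) == 3
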