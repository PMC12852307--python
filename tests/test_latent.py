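"""Tests for the latent-feature emulator, product kernel and PCA extractor."""

import numpy as np
import pytest

import cohortgp as cg
from cohortgp.errors import CoverageError, RankError, ShapeError
from cohortgp.gp import _corr_product


def _mini_cohort(n_members=2, n_sims=2, k=1, seed=0):
    rng = np.random.default_rng(seed)
    members = [
        cg.SimulationEnsemble(
            f"m{i}", rng.uniform(0, 1, (n_sims, k)),
            rng.normal(size=(n_sims, 2)), ["u", "v"],
        )
        for i in range(n_members)
    ]
    return cg.CohortDataset(members)


class TestHybridDataset:
    def test_row_and_column_counting(self):
        cohort = _mini_cohort()
        lat = cg.LatentFeatures({"m0": [0.1], "m1": [0.9]})
        hyb = cg.build_hybrid_dataset(cohort, lat)
        assert hyb.inputs.shape == (4, 2)
        assert hyb.outputs.shape == (4, 2)
        assert list(hyb.row_member_ids) == ["m0", "m0", "m1", "m1"]

    def test_full_case_study_shape(self):
        """19 members x 180 simulations with 6 parameters and 9 latent modes
        concatenate into 3420 rows of 15 input features."""
        cfg = cg.SyntheticCohortConfig(n_members=19, n_sims=180, n_inputs=6, d_latent=9, seed=1)
        syn = cg.generate_cohort(cfg)
        hyb = cg.build_hybrid_dataset(syn.dataset, syn.latents)
        assert hyb.inputs.shape == (3420, 15)

    def test_single_member_appends_constant_latent_columns(self):
        cohort = _mini_cohort(n_members=1, n_sims=5)
        lat = cg.LatentFeatures({"m0": [0.3, -0.4]})
        hyb = cg.build_hybrid_dataset(cohort, lat)
        assert np.array_equal(hyb.inputs[:, :1], cohort.members[0].design)
        assert np.allclose(hyb.inputs[:, 1:], [0.3, -0.4])

    def test_missing_latent_raises_coverage_error(self):
        cohort = _mini_cohort()
        with pytest.raises(CoverageError, match="m1"):
            cg.build_hybrid_dataset(cohort, cg.LatentFeatures({"m0": [0.0]}))


class TestProductKernel:
    def test_gram_is_elementwise_product_of_component_grams(self, small_cohort):
        hyb = cg.build_hybrid_dataset(small_cohort.dataset, small_cohort.latents)
        em = cg.train_latent_emulator(
            hyb, subsample_size=40, seed=0, latents=small_cohort.latents,
            optimizer_config=cg.OptimizerConfig(optimize=False),
        )
        gp = em.emulators["y0"]
        Xs = (gp.training_inputs - gp.in_shift) / gp.in_scale
        full = _corr_product(gp.components, Xs, Xs)
        part0 = _corr_product(gp.components[:1], Xs, Xs)
        part1 = _corr_product(gp.components[1:], Xs, Xs)
        assert np.allclose(full, part0 * part1, atol=1e-12)
        # product Gram must stay PSD up to jitter
        w = np.linalg.eigvalsh(gp.signal_variance * full)
        assert w.min() > -1e-8

    def test_constant_latent_kernel_reduces_to_pooled_gp(self, small_cohort):
        """With the latent kernel frozen flat, the latent emulator equals a
        pooled GP on the parameters alone."""
        hyb = cg.build_hybrid_dataset(small_cohort.dataset, small_cohort.latents)
        frozen = cg.OptimizerConfig(optimize=False)
        theta_k = cg.KernelSpec(lengthscales=np.array([0.4, 0.4]), signal_variance=1.2,
                                noise_variance=0.05)
        flat_latent = cg.KernelSpec(lengthscales=np.full(2, 1e8), signal_variance=1.2,
                                    noise_variance=0.05)
        em = cg.train_latent_emulator(
            hyb, theta_kernel=theta_k, latent_kernel=flat_latent,
            seed=0, latents=small_cohort.latents,
            mean_spec=cg.MeanSpec(form="constant"), optimizer_config=frozen,
        )
        pooled = cg.fit_gp(
            hyb.inputs[:, :2], hyb.outputs[:, 0], kernel_spec=theta_k,
            mean_spec=cg.MeanSpec(form="constant"), optimizer_config=frozen, seed=0,
        )
        Q = np.random.default_rng(0).uniform(0, 1, (6, 2))
        lat_pred = em.for_member("y0", small_cohort.latents.vector("member_00")).predict(Q)
        pooled_pred = pooled.predict(Q)
        assert np.allclose(lat_pred.mean, pooled_pred.mean, atol=1e-8)
        assert np.allclose(lat_pred.variance, pooled_pred.variance, atol=1e-8)

    def test_training_subsample_is_seeded(self, small_cohort):
        hyb = cg.build_hybrid_dataset(small_cohort.dataset, small_cohort.latents)
        frozen = cg.OptimizerConfig(optimize=False)
        a = cg.train_latent_emulator(hyb, subsample_size=30, seed=4, optimizer_config=frozen)
        b = cg.train_latent_emulator(hyb, subsample_size=30, seed=4, optimizer_config=frozen)
        assert np.array_equal(a.training_subset, b.training_subset)


@pytest.fixture(scope="module")
def fitted(small_cohort, fast_opt):
    hyb = cg.build_hybrid_dataset(small_cohort.dataset, small_cohort.latents)
    return cg.train_latent_emulator(
        hyb, subsample_size=120, seed=0, latents=small_cohort.latents,
        optimizer_config=fast_opt,
    )


class TestPrediction:
    def test_matches_underlying_gp_on_concatenated_inputs(self, fitted, small_cohort):
        Q = np.random.default_rng(1).uniform(0, 1, (5, 2))
        l = small_cohort.latents.vector("member_01")
        pred = cg.predict_for_member(fitted, Q, l)["y1"]
        joint = np.column_stack([Q, np.tile(l, (5, 1))])
        direct = fitted.emulators["y1"].predict(joint)
        assert np.array_equal(pred.mean, direct.mean)

    def test_identical_latents_give_identical_predictions(self, fitted):
        Q = np.random.default_rng(2).uniform(0, 1, (4, 2))
        l = np.array([0.2, -0.5])
        a = cg.predict_for_member(fitted, Q, l)["y0"]
        b = cg.predict_for_member(fitted, Q, l.copy())["y0"]
        assert np.array_equal(a.mean, b.mean)

    def test_latent_dimension_mismatch_raises(self, fitted):
        with pytest.raises(ShapeError):
            cg.predict_for_member(fitted, np.zeros((2, 2)), np.zeros(5))

    def test_member_order_permutation_is_irrelevant(self, small_cohort):
        """Reordering cohort members only permutes hybrid rows; frozen-kernel
        predictions are unchanged."""
        frozen = cg.OptimizerConfig(optimize=False)
        lat = small_cohort.latents
        hyb = cg.build_hybrid_dataset(small_cohort.dataset, lat)
        perm = cg.CohortDataset(list(reversed(small_cohort.dataset.members)))
        hyb_p = cg.build_hybrid_dataset(perm, lat)
        Q = np.random.default_rng(3).uniform(0, 1, (4, 2))
        l = lat.vector("member_03")
        a = cg.train_latent_emulator(hyb, seed=0, latents=lat, optimizer_config=frozen)
        b = cg.train_latent_emulator(hyb_p, seed=0, latents=lat, optimizer_config=frozen)
        pa = cg.predict_for_member(a, Q, l)["y0"]
        pb = cg.predict_for_member(b, Q, l)["y0"]
        assert np.allclose(pa.mean, pb.mean, atol=1e-9)


class TestPCA:
    def test_exact_low_rank_explains_everything(self):
        rng = np.random.default_rng(0)
        V = rng.normal(size=(8, 2)) @ rng.normal(size=(2, 6))
        model, feats = cg.pca_latent_features(V, 2)
        assert abs(model.explained_variance_fractions.sum() - 1.0) < 1e-10
        assert feats.d_latent == 2

    def test_modes_orthonormal(self):
        rng = np.random.default_rng(1)
        model, _ = cg.pca_latent_features(rng.normal(size=(10, 7)), 4)
        assert np.allclose(model.modes @ model.modes.T, np.eye(4), atol=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        V = rng.normal(size=(12, 5))
        model, feats = cg.pca_latent_features(V, 3, member_ids=[f"p{i}" for i in range(12)])
        C = np.cov(V, rowvar=False, bias=False)
        w, U = np.linalg.eigh(C)
        order = np.argsort(w)[::-1][:3]
        for j, col in enumerate(order):
            u = U[:, col]
            if u[np.argmax(np.abs(u))] < 0:
                u = -u
            assert np.allclose(model.modes[j], u, atol=1e-6)
        scores = (V - V.mean(axis=0)) @ model.modes.T
        for i, mid in enumerate(f"p{i}" for i in range(12)):
            assert np.allclose(feats.vector(mid), scores[i], atol=1e-8)

    def test_rank_bound_enforced(self):
        with pytest.raises(RankError):
            cg.pca_latent_features(np.zeros((4, 10)), 4)


class TestLeaveOneOut:
    def test_two_member_cohort_produces_two_holdout_studies(self, fast_opt):
        cfg = cg.SyntheticCohortConfig(
            n_inputs=2, d_latent=1, n_members=2, n_sims=30, n_outputs=1,
            discrepancy_scale=0.1, seed=5,
        )
        syn = cg.generate_cohort(cfg)
        table = cg.leave_one_member_out(
            syn.dataset, syn.latents, [20], replicates=1, seed=0,
            n_posterior_samples=50, optimizer_config=fast_opt,
        )
        assert set(table["held_out"]) == {"member_00", "member_01"}
        # 2 holdouts x 2 models x 2 evaluations x 1 output x 1 budget
        assert len(table) == 8
        assert set(table["model"]) == {"latent", "individual"}
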