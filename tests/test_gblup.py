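"""GRM construction, REML variance components, BLUP prediction, LOOCV."""

import numpy as np
import pandas as pd
import pytest

import canopygp as cg
from canopygp.gblup import _reml_profile, _ridged


def _matrix(dosages, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = ids or [f"A{i}" for i in range(n)]
    return cg.GenotypeMatrix(ids, [f"M{j}" for j in range(m)], dosages)


def _structured_grm(n, seed, n_markers=400):
    cfg = cg.SimulationConfig(seed=seed, n_accessions=n, n_genotyped=n, n_markers=n_markers)
    return cg.genomic_relationship_matrix(cg.simulate_genotypes(cfg))


def _simulate_y(G, h2, seed, mu=3.0, var_total=1.0):
    """Phenotypes drawn from the G-BLUP generative model itself."""
    rng = np.random.default_rng(seed)
    n = G.n
    L = np.linalg.cholesky(G.matrix + 1e-8 * np.eye(n))
    g = L @ rng.normal(0.0, np.sqrt(h2 * var_total), n)
    e = rng.normal(0.0, np.sqrt((1 - h2) * var_total), n)
    return mu + g + e


class TestGenomicRelationshipMatrix:
    def test_single_marker_hand_computation(self):
        # dosages (0, 1, 2): p = 0.5, W = (-1, 0, 1), denom = 2 p (1-p) = 0.5
        grm = cg.genomic_relationship_matrix(_matrix([[0], [1], [2]]), min_maf=0.0)
        expected = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        np.testing.assert_allclose(grm.matrix, expected, atol=1e-12)
        assert grm.denominator == pytest.approx(0.5)

    def test_duplicated_accessions_are_identical_rows(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(6, 50)).astype(float)
        X[5] = X[0]
        grm = cg.genomic_relationship_matrix(_matrix(X))
        np.testing.assert_allclose(grm.matrix[0], grm.matrix[5], atol=1e-12)
        assert grm.matrix[0, 0] == pytest.approx(grm.matrix[0, 5])

    def test_symmetric_with_centred_columns_and_unit_mean_diagonal(self):
        grm = _structured_grm(80, seed=2)
        np.testing.assert_allclose(grm.matrix, grm.matrix.T, atol=1e-12)
        # row sums of G are proportional to column sums of W, which vanish
        np.testing.assert_allclose(grm.matrix.sum(axis=0), 0.0, atol=1e-8)
        assert np.mean(np.diag(grm.matrix)) == pytest.approx(1.0, abs=0.35)

    def test_missing_dosages_mean_imputed(self):
        X = np.array([[0.0, 2.0], [1.0, np.nan], [2.0, 0.0]])
        grm = cg.genomic_relationship_matrix(_matrix(X), min_maf=0.0)
        assert np.isfinite(grm.matrix).all()

    def test_monomorphic_only_raises(self):
        with pytest.raises(ValueError):
            cg.genomic_relationship_matrix(_matrix([[2.0], [2.0], [2.0]]))


class TestRemlFit:
    def test_recovers_heritability_at_n_300(self):
        grm = _structured_grm(300, seed=7, n_markers=1000)
        y = _simulate_y(grm, h2=0.5, seed=42)
        fit = cg.reml_fit(y, grm)
        assert not fit.boundary
        assert fit.h2 == pytest.approx(0.5, abs=0.15)
        assert fit.mu == pytest.approx(3.0, abs=0.5)
        assert fit.sigma_g2 >= 0 and fit.sigma_e2 >= 0

    def test_constant_phenotype_gives_boundary_no_signal_fit(self):
        grm = _structured_grm(30, seed=1)
        fit = cg.reml_fit(np.full(30, 1.7), grm)
        assert fit.boundary
        assert fit.sigma_g2 == 0.0
        preds = cg.blup_predict(fit, grm, grm.accession_ids[:-1], grm.accession_ids[-1:],
                                np.full(29, 1.7))
        assert preds.iloc[0] == pytest.approx(1.7)

    def test_optimum_beats_41_point_grid_oracle(self):
        grm = _structured_grm(100, seed=3)
        y = _simulate_y(grm, h2=0.4, seed=9)
        fit = cg.reml_fit(y, grm)
        d, U = np.linalg.eigh(_ridged(grm.matrix))
        d = np.clip(d, 0.0, None)
        y_t, one_t = U.T @ y, U.T @ np.ones_like(y)
        grid = np.linspace(-10, 10, 41)
        grid_logliks = [_reml_profile(ld, d, y_t, one_t)[0] for ld in grid]
        assert fit.loglik >= max(grid_logliks) - 1e-9

    def test_pure_noise_lands_near_zero_heritability(self):
        grm = _structured_grm(150, seed=4)
        y = np.random.default_rng(11).normal(size=150)
        fit = cg.reml_fit(y, grm)
        assert fit.h2 < 0.25


class TestBlupPredict:
    def test_shift_equivariance(self):
        grm = _structured_grm(40, seed=5)
        train, test = grm.accession_ids[:35], grm.accession_ids[35:]
        y = _simulate_y(grm, h2=0.6, seed=1)[:35]
        fit = cg.reml_fit(y, grm.subset(train))
        base = cg.blup_predict(fit, grm, train, test, y)
        shifted_fit = cg.reml_fit(y + 5.0, grm.subset(train))
        shifted = cg.blup_predict(shifted_fit, grm, train, test, y + 5.0)
        np.testing.assert_allclose(shifted.to_numpy(), base.to_numpy() + 5.0, atol=1e-6)

    def test_identity_grm_predicts_the_mean(self):
        ids = [f"A{i}" for i in range(20)]
        grm = cg.GRM(ids, np.eye(20))
        y = np.random.default_rng(0).normal(2.0, 1.0, 19)
        fit = cg.reml_fit(y, grm.subset(ids[:19]))
        pred = cg.blup_predict(fit, grm, ids[:19], ids[19:], y)
        assert pred.iloc[0] == pytest.approx(fit.mu, abs=1e-9)

    def test_genetic_duplicate_with_high_heritability_is_copied(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 3, size=(30, 200)).astype(float)
        X[29] = X[0]  # test accession duplicates training accession 0
        grm = cg.genomic_relationship_matrix(_matrix(X))
        ids = grm.accession_ids
        y = _simulate_y(grm, h2=0.999, seed=2, var_total=1.0)[:29]
        fit = cg.reml_fit(y, grm.subset(ids[:29]))
        pred = cg.blup_predict(fit, grm, ids[:29], ids[29:], y)
        assert pred.iloc[0] == pytest.approx(y[0], abs=0.1)

    def test_overlapping_train_test_raises(self):
        grm = _structured_grm(10, seed=6)
        fit = cg.reml_fit(np.random.default_rng(1).normal(size=10), grm)
        with pytest.raises(ValueError):
            cg.blup_predict(fit, grm, grm.accession_ids, grm.accession_ids[:1], np.zeros(10))


class TestRidgeEquivalence:
    @pytest.mark.parametrize("n, m, delta", [(20, 60, 1.0), (30, 100, 0.3), (15, 40, 3.0)])
    def test_gblup_equals_ridge_marker_blup(self, n, m, delta):
        """G-BLUP with G = WW'/c must equal ridge regression on markers.

        Independent oracle: solve the ridge system for marker effects with
        penalty c * delta and predict test accessions from their markers.
        """
        rng = np.random.default_rng(n + m)
        X = rng.integers(0, 3, size=(n, m)).astype(float)
        genotypes = _matrix(X)
        grm = cg.genomic_relationship_matrix(genotypes, min_maf=0.0)
        p = genotypes.allele_frequencies()
        keep = (p > 0) & (p < 1)
        W = (X - 2 * p)[:, keep]
        c = grm.denominator
        n_train = n - 5
        train, test = grm.accession_ids[:n_train], grm.accession_ids[n_train:]
        y = _simulate_y(grm, h2=0.5, seed=3)[:n_train]
        mu = float(y.mean())

        # oracle: alpha = (W'W + c delta I)^-1 W' (y - mu), ridge-stabilised
        # exactly like the G-BLUP path
        Wt = W[:n_train]
        ridge = 1e-6 * np.mean(np.diag(grm.matrix))
        A = Wt.T @ Wt + c * (delta + ridge) * np.eye(Wt.shape[1])
        alpha = np.linalg.solve(A, Wt.T @ (y - mu))
        oracle = mu + W[n_train:] @ alpha

        fit = cg.GBLUPFit(mu=mu, sigma_g2=1.0, sigma_e2=delta, loglik=0.0,
                          breeding_values=pd.Series(np.zeros(n_train), index=train))
        got = cg.blup_predict(fit, grm, train, test, y)
        np.testing.assert_allclose(got.to_numpy(), oracle, atol=1e-8)


class TestLoocv:
    def test_held_out_phenotype_never_leaks(self):
        grm = _structured_grm(25, seed=9)
        y = _simulate_y(grm, h2=0.5, seed=5)
        base = cg.loocv(y, grm, min_n=20)
        y_perturbed = y.copy()
        y_perturbed[3] += 10.0
        perturbed = cg.loocv(y_perturbed, grm, min_n=20)
        assert perturbed.predictions.iloc[3] == pytest.approx(
            base.predictions.iloc[3], abs=1e-9
        )

    def test_null_phenotype_carries_no_predictive_information(self):
        """With zero heritability, predictions must not track phenotypes.

        REML drives sigma_g^2 to the boundary, so predictions collapse to
        the leave-one-out training mean; their only dependence on y_i is
        the O(1/n) mean shift, which makes the Pearson correlation of a
        near-constant prediction vector degenerate (-> -1) while carrying
        no usable information.  The stable no-skill measures are the
        regression slope of predictions on observations and the collapse
        of prediction variance itself.
        """
        grm = _structured_grm(150, seed=10)
        y = np.random.default_rng(21).normal(size=150)
        result = cg.loocv(y, grm)
        pred = result.predictions.to_numpy()
        slope = np.cov(pred, y)[0, 1] / np.var(y)
        assert abs(slope) < 0.15
        assert pred.std() < 0.15 * y.std()

    def test_affine_transform_preserves_accuracy(self):
        grm = _structured_grm(30, seed=12)
        y = _simulate_y(grm, h2=0.6, seed=7)
        r1 = cg.loocv(y, grm, min_n=20)
        r2 = cg.loocv(2.5 * y - 1.0, grm, min_n=20)
        assert r2.accuracy == pytest.approx(r1.accuracy, abs=1e-6)

    def test_too_few_accessions_raise(self):
        grm = _structured_grm(10, seed=13)
        with pytest.raises(ValueError):
            cg.loocv(np.zeros(10), grm)
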