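import numpy as np
import pytest
from scipy import stats

from permacomm.assembly import (
    MantelModelFit, _log_ready, fit_neutral_model, fit_sloan, modified_mantel,
    niche_overlap, null_communities, pairwise_niche_overlap, sloan_occupancy,
    stochasticity_by_group, stochasticity_ratio,
)
from permacomm.datamodel import DistanceMatrix
from permacomm.diversity import bray_curtis_matrix
from conftest import make_table, small_config


class TestNullModel:
    def _sparse_table(self, seed=1, n_taxa=40, n_samp=8, k=6):
        rng = np.random.default_rng(seed)
        counts = np.zeros((n_taxa, n_samp), int)
        for j in range(n_samp):
            present = rng.choice(n_taxa, size=k, replace=False)
            counts[present, j] = rng.integers(1, 20, size=k)
        t = make_table(counts)
        return t.drop_zero_taxa()[0]

    def test_richness_and_totals_preserved(self):
        t = self._sparse_table()
        obs_rich = (t.counts > 0).sum(axis=0)
        obs_tot = t.counts.sum(axis=0)
        for null in null_communities(t, n_null=20, seed=0):
            assert np.array_equal((null > 0).sum(axis=0), obs_rich)
            assert np.allclose(null.sum(axis=0), obs_tot)

    def test_occurrence_frequency_proportionality(self):
        # inclusion across many nulls tracks the pool occurrence frequency
        t = self._sparse_table(seed=2)
        occ = (t.counts > 0).sum(axis=1).astype(float)
        draw = np.zeros(t.n_taxa)
        n_null = 1000
        for null in null_communities(t, n_null=n_null, seed=3):
            draw += (null > 0).sum(axis=1)
        expected = occ / occ.sum() * draw.sum()
        chi2 = ((draw - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=t.n_taxa - 1)
        assert p > 0.01

    def test_too_few_nulls_rejected(self):
        with pytest.raises(ValueError):
            list(null_communities(self._sparse_table(), n_null=1))


class TestStochasticityRatio:
    def test_ratios_bounded_and_clamped(self, small_dataset):
        table, frame, _ = small_dataset
        res = stochasticity_ratio(table, n_null=20, seed=0)
        assert (res.pair_ratios >= 0).all() and (res.pair_ratios <= 1).all()
        assert 0 <= res.mean_ratio <= 1

    def test_neutral_exceeds_filtered(self):
        from permacomm.simulate import generate_community, generate_metadata

        def ratio(alpha, sigma, seed):
            cfg = small_config(selection_strength=alpha, niche_breadth=sigma,
                               seed=seed)
            frame = generate_metadata(cfg)
            table, _ = generate_community(cfg, frame)
            table, _ = table.drop_zero_taxa()
            return stochasticity_ratio(table, n_null=30, seed=seed).mean_ratio

        neutral = np.mean([ratio(0.0, 0.4, s) for s in range(3)])
        filtered = np.mean([ratio(0.9, 0.15, s) for s in range(3)])
        assert neutral > filtered

    def test_selection_strength_monotonically_lowers_ratio(self):
        from permacomm.simulate import generate_community, generate_metadata

        means = []
        for alpha in (0.0, 0.3, 0.6, 0.9):
            vals = []
            for s in range(3):
                cfg = small_config(selection_strength=alpha,
                                   niche_breadth=0.25, seed=s)
                frame = generate_metadata(cfg)
                table, _ = generate_community(cfg, frame)
                table, _ = table.drop_zero_taxa()
                vals.append(
                    stochasticity_ratio(table, n_null=25, seed=s).mean_ratio)
            means.append(np.mean(vals))
        r, p = stats.spearmanr([0.0, 0.3, 0.6, 0.9], means)
        assert r == -1.0 and p < 0.05

    def test_per_group_seeding_is_reproducible(self, small_dataset):
        table, frame, _ = small_dataset
        g = frame.column("main_layer")
        a = stochasticity_by_group(table, g, n_null=10, seed=4)
        b = stochasticity_by_group(table, g, n_null=10, seed=4)
        for lab in a:
            assert a[lab].mean_ratio == b[lab].mean_ratio


class TestNeutralModel:
    def test_predicted_occupancy_monotone_in_abundance(self):
        p = np.linspace(1e-6, 0.2, 100)
        occ = sloan_occupancy(p, Nm=800, d=1e-4)
        assert (np.diff(occ) >= -1e-12).all()
        assert ((occ >= 0) & (occ <= 1)).all()

    def test_parameter_recovery_from_model_occupancies(self):
        rng = np.random.default_rng(0)
        nm_true, n_samples, d = 1000.0, 100, 5e-5
        p = rng.lognormal(-8, 1.5, 300)
        pred = sloan_occupancy(p, nm_true, d)
        occ = rng.binomial(n_samples, pred) / n_samples
        nm_hat = fit_sloan(p, occ, d)
        assert abs(nm_hat / nm_true - 1) < 0.2

    def test_generator_migration_recovered(self, small_dataset):
        # neutral-regime data carry a recoverable migration rate
        from permacomm.simulate import generate_community, generate_metadata
        cfg = small_config(selection_strength=0.0, seed=21)
        frame = generate_metadata(cfg)
        table, _ = generate_community(cfg, frame)
        table, _ = table.drop_zero_taxa()
        fit = fit_neutral_model(table)
        assert abs(fit.m / cfg.migration - 1) < 0.2
        assert fit.R2 > 0.5

    def test_near_saturated_occupancies(self):
        # nearly all taxa everywhere: predictions approach 1
        rng = np.random.default_rng(1)
        counts = rng.integers(50, 100, size=(25, 10))
        counts[0, 0] = 0
        fit = fit_neutral_model(make_table(counts))
        assert fit.predicted_occupancy.mean() > 0.95

    def test_noise_occupancies_allow_negative_r2(self):
        rng = np.random.default_rng(3)
        p = rng.lognormal(-6, 1, 100)
        occ = rng.uniform(0.05, 0.95, 100)
        nm = fit_sloan(p, occ, d=1e-4)
        pred = sloan_occupancy(p, nm, 1e-4)
        r2 = 1 - ((occ - pred) ** 2).sum() / ((occ - occ.mean()) ** 2).sum()
        assert r2 <= 1.0      # may be <= 0; just must be reported, not clipped

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            fit_neutral_model(make_table(np.ones((5, 4), int)))


class TestNicheOverlap:
    def test_identical_distributions_full_overlap(self):
        t = make_table([[2, 4, 6], [1, 2, 3]])
        assert niche_overlap(t) == pytest.approx(1.0)

    def test_disjoint_distributions_zero_overlap(self):
        t = make_table([[5, 0], [0, 5]])
        assert niche_overlap(t) == pytest.approx(0.0)

    def test_hand_case(self):
        # p1=(.5,.5,0), p2=(0,.5,.5): O = .25/.5 = .5 both directions
        t = make_table([[1, 1, 0], [0, 1, 1]])
        assert niche_overlap(t) == pytest.approx(0.5)

    def test_pairwise_matrix_symmetric_unit_diagonal(self, small_dataset):
        table, _, _ = small_dataset
        sub = table.select_taxa(np.arange(20))
        sub, _ = sub.drop_zero_taxa()
        o = pairwise_niche_overlap(sub)
        assert np.allclose(o, o.T)
        assert np.allclose(np.diag(o), 1.0)


class TestModifiedMantel:
    def test_zero_replacement_convention(self):
        # minimum positive 1 -> zeros become 0.05, ln = -3.00
        v, shift, repl = _log_ready(np.array([0.0, 1.0, 2.0]))
        assert repl == pytest.approx(0.05)
        assert np.log(v[0]) == pytest.approx(-3.00, abs=0.005)

    def test_identity_relationship_selects_linear_model(self):
        rng = np.random.default_rng(0)
        env = rng.uniform(1, 5, 12)
        x = np.abs(env[:, None] - env[None, :])
        d = DistanceMatrix([f"s{i}" for i in range(12)], x)
        fit = modified_mantel(d, env, n_perm=49, seed=1)
        assert fit.model == "Y~X"
        assert fit.r == pytest.approx(1.0)

    def test_exponential_relationship_selects_log_y(self):
        rng = np.random.default_rng(0)
        env = rng.uniform(0.5, 2.0, 12)
        x = np.abs(env[:, None] - env[None, :])
        y = np.exp(3.0 * x)            # ln(Y) = 3X exactly off-diagonal
        np.fill_diagonal(y, 0.0)
        d = DistanceMatrix([f"s{i}" for i in range(12)], y)
        fit = modified_mantel(d, env, n_perm=49, seed=1)
        assert fit.model == "ln(Y)~X"
        assert fit.candidate_r["ln(Y)~X"] == pytest.approx(1.0)

    def test_constant_env_rejected(self, small_dataset):
        table, _, _ = small_dataset
        d = bray_curtis_matrix(table)
        with pytest.raises(ValueError):
            modified_mantel(d, np.ones(table.n_samples))

    def test_all_four_candidates_scored(self, small_dataset):
        table, frame, _ = small_dataset
        d = bray_curtis_matrix(table)
        fit = modified_mantel(d, frame.column("depth_m").astype(float),
                              n_perm=49, seed=0)
        assert set(fit.candidate_r) == {"Y~X", "Y~ln(X)", "ln(Y)~X", "ln(Y)~ln(X)"}
        assert abs(fit.candidate_r[fit.model]) == max(
            abs(v) for v in fit.candidate_r.values())
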