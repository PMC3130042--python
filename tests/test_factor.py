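"""Factor-model checks: seeding, recruitment, PCA equivalence, EM behaviour."""

import numpy as np
import pytest

from metapqtl.errors import DegenerateFactorError
from metapqtl.factor import (
    FactorHyperparams,
    Metaprotein,
    composition_metrics,
    fit_all,
    fit_metaprotein,
    load_scores,
    peptide_correlations,
    save_fit,
    seed_factors,
)
from metapqtl.errors import ConfigError

from conftest import make_table


def _signal(n=40, seed=0):
    return np.random.default_rng(seed).standard_normal(n)


class TestSeedFactors:
    def test_threshold_at_two_features(self):
        rng = np.random.default_rng(1)
        table = make_table(
            rng.standard_normal((6, 10)),
            ["A", "A", "A", "B", "B", "C"],
        )
        seeds = seed_factors(table)
        assert [protein for protein, _ in seeds] == ["A", "B"]
        assert len(seeds[0][1]) == 3 and len(seeds[1][1]) == 2

    def test_unidentified_features_never_seed(self):
        rng = np.random.default_rng(2)
        table = make_table(rng.standard_normal((4, 8)), ["A", "A", None, None])
        seeds = seed_factors(table)
        assert [protein for protein, _ in seeds] == ["A"]

    def test_synthetic_default_yields_one_seed_per_protein(self, default_sim):
        _, table, _, _ = default_sim
        assert len(seed_factors(table)) == 10

    def test_no_valid_seed_is_an_error(self):
        table = make_table(np.random.default_rng(3).standard_normal((3, 6)), ["A", "B", None])
        with pytest.raises(DegenerateFactorError):
            seed_factors(table)


class TestFitMetaprotein:
    def test_noiseless_identical_seed_peptides(self):
        f = _signal()
        table = make_table(np.vstack([10 + f, 12 + f]), ["A", "A"])
        state = fit_metaprotein(table, "A", ["F0", "F1"], [], FactorHyperparams())
        probs = [p for _, _, p in state.metaprotein.members]
        assert len(probs) == 2
        assert np.allclose(probs, 1.0, atol=1e-6)
        score = state.score.to_numpy()
        shared = (f - f.mean()) / f.std()
        assert abs(np.corrcoef(score, shared)[0, 1]) > 1 - 1e-9

    def test_foreign_copy_of_signal_is_recruited(self):
        # Bernoulli-Gaussian posterior odds: with near-zero residual noise the
        # marginal likelihood ratio overwhelms the small pi_other prior.
        f = _signal()
        table = make_table(
            np.vstack([10 + f, 12 + 0.9 * f, 15 + 1.1 * f]), ["A", "A", "B"]
        )
        hp = FactorHyperparams()
        state = fit_metaprotein(table, "A", ["F0", "F1"], ["F2"], hp)
        members = {fid: p for fid, _, p in state.metaprotein.members}
        assert "F2" in members and members["F2"] > 0.99

    def test_discordant_seed_peptide_is_excluded(self):
        # under a non-dogmatic seed prior the marginal-likelihood Occam
        # penalty drops a peptide whose trend does not track the others
        f, g = _signal(seed=1), _signal(seed=2)
        table = make_table(
            np.vstack([10 + f, 11 + f, 12 + f, 30 + g]), ["A", "A", "A", "A"]
        )
        hp = FactorHyperparams(pi_seed=0.55)
        state = fit_metaprotein(table, "A", ["F0", "F1", "F2", "F3"], [], hp)
        member_ids = state.metaprotein.member_ids
        assert "F3" not in member_ids and set(member_ids) == {"F0", "F1", "F2"}

    def test_all_seed_excluded_raises(self):
        table = make_table(np.random.default_rng(5).standard_normal((2, 4)), ["A", "A"])
        with pytest.raises(DegenerateFactorError):
            # only 4 samples but require >=3 observed: make one column all-NaN
            bad = table.intensities.copy()
            bad.iloc[0, :] = np.nan
            bad.iloc[1, :] = np.nan
            table.intensities = bad
            fit_metaprotein(table, "A", ["F0", "F1"], [], FactorHyperparams())

    def test_sparsity_off_score_equals_first_principal_component(self, clean_sim):
        _, table, _, _ = clean_sim
        seeds = seed_factors(table)
        protein, seed_ids = seeds[0]
        hp = FactorHyperparams(pi_seed=1 - 1e-9, pi_other=1 - 1e-6)
        state = fit_metaprotein(table, protein, seed_ids, [], hp)
        block = table.intensities.loc[seed_ids].to_numpy().T
        centered = block - block.mean(axis=0)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        pc1 = u[:, 0] * s[0]
        r = np.corrcoef(state.score.to_numpy(), pc1)[0, 1]
        assert abs(r) >= 0.999

    def test_inclusion_probability_monotone_in_correlation(self):
        # same seed factor; candidate with higher |corr| gets higher p_j
        f = _signal(n=60, seed=7)
        noise = np.random.default_rng(8).standard_normal(60)
        weak = 0.4 * f + noise
        strong = 1.0 * f + 0.3 * noise
        probs = {}
        for name, candidate in [("weak", weak), ("strong", strong)]:
            table = make_table(
                np.vstack([10 + f, 12 + f, 14 + candidate]), ["A", "A", "B"]
            )
            hp = FactorHyperparams(pi_other=0.05)
            state = fit_metaprotein(table, "A", ["F0", "F1"], ["F2"], hp)
            probs[name] = state.metaprotein.inclusion_probs["F2"]
        assert probs["strong"] >= probs["weak"]

    def test_objective_is_monotone(self, default_sim):
        _, table, _, _ = default_sim
        for protein, seed_ids in seed_factors(table)[:3]:
            candidates = [f for f in table.feature_ids if f not in set(seed_ids)]
            state = fit_metaprotein(table, protein, seed_ids, candidates, FactorHyperparams())
            diffs = np.diff(state.objective_trace)
            assert (diffs >= -1e-8).all()

    def test_determinism(self, default_sim):
        _, table, _, _ = default_sim
        protein, seed_ids = seed_factors(table)[0]
        a = fit_metaprotein(table, protein, seed_ids, [], FactorHyperparams())
        b = fit_metaprotein(table, protein, seed_ids, [], FactorHyperparams())
        assert np.array_equal(a.score.to_numpy(), b.score.to_numpy())
        assert a.metaprotein.members == b.metaprotein.members


class TestFitAll:
    def test_one_factor_per_seed_with_standardized_scores(self, default_sim):
        _, table, _, _ = default_sim
        fit = fit_all(table, FactorHyperparams())
        assert fit.k == 10
        scores = fit.scores.to_numpy()
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(scores.var(axis=0), 1.0, atol=1e-6)

    def test_membership_recovers_truth_on_clean_data(self, clean_sim):
        config, table, _, truth = clean_sim
        fit = fit_all(table, FactorHyperparams())
        protein_to_factor = {mp.seed_protein: mp for mp in fit.factors}
        correct = 0
        for fid, true_members in truth.peptide_membership.items():
            fitted = {
                g
                for g, protein in enumerate(config.protein_ids())
                if fid in set(protein_to_factor[protein].member_ids)
            }
            correct += fitted == true_members
        assert correct / len(truth.peptide_membership) >= 0.95

    def test_scores_track_true_protein_scores(self, clean_sim):
        config, table, _, truth = clean_sim
        fit = fit_all(table, FactorHyperparams())
        corrs = []
        for k, mp in enumerate(fit.factors):
            g = config.protein_ids().index(mp.seed_protein)
            corrs.append(
                abs(np.corrcoef(fit.scores.iloc[:, k], truth.protein_scores.iloc[:, g])[0, 1])
            )
        assert np.median(corrs) >= 0.9

    def test_save_and_load_round_trip(self, tmp_path, default_sim):
        _, table, _, _ = default_sim
        hp = FactorHyperparams()
        fit = fit_all(table, hp)
        save_fit(fit, tmp_path / "fit", hp, provenance={"seed": 11})
        scores = load_scores(tmp_path / "fit")
        assert np.allclose(scores.to_numpy(), fit.scores.to_numpy())
        assert list(scores.columns) == list(fit.scores.columns)


class TestComposition:
    def _mp(self, members):
        return Metaprotein(
            name="A", seed_protein="A", members=[(m, 1.0, 1.0) for m in members],
            coverage_pct=np.nan, signature_pct=np.nan,
        )

    def test_full_coverage_with_foreign_members(self):
        table = make_table(
            np.random.default_rng(0).standard_normal((8, 6)),
            ["A"] * 5 + ["B", "C", "D"],
        )
        mp = self._mp([f"F{j}" for j in range(8)])
        coverage, signature = composition_metrics(mp, table)
        assert coverage == pytest.approx(100.0)
        assert signature == pytest.approx(62.5)

    def test_pure_factor_signature(self):
        table = make_table(np.zeros((5, 6)) + np.arange(6), ["A"] * 5)
        mp = self._mp(["F0", "F1", "F2", "F3", "F4"])
        assert composition_metrics(mp, table) == (pytest.approx(100.0), pytest.approx(100.0))

    def test_partial_coverage(self):
        table = make_table(np.random.default_rng(1).standard_normal((4, 6)), ["A"] * 4)
        mp = self._mp(["F0"])
        coverage, signature = composition_metrics(mp, table)
        assert coverage == pytest.approx(25.0)
        assert signature == pytest.approx(100.0)


class TestPeptideCorrelations:
    def test_duplicate_and_anticorrelated_members(self):
        f = _signal(seed=9)
        table = make_table(np.vstack([f, f, -f]), ["A", "A", "A"])
        mp = Metaprotein(
            name="A", seed_protein="A",
            members=[("F0", 1.0, 1.0), ("F1", 1.0, 1.0), ("F2", -1.0, 1.0)],
            coverage_pct=100.0, signature_pct=100.0,
        )
        corr = peptide_correlations(mp, table)
        assert corr.loc["F0", "F1"] == pytest.approx(1.0)
        assert corr.loc["F0", "F2"] == pytest.approx(-1.0)

    def test_insufficient_overlap_warns(self):
        x = np.full((2, 5), np.nan)
        x[0, :3] = [1.0, 2.0, 3.0]
        x[1, 3:] = [1.0, 2.0]
        table = make_table(x, ["A", "A"])
        mp = Metaprotein(
            name="A", seed_protein="A",
            members=[("F0", 1.0, 1.0), ("F1", 1.0, 1.0)],
            coverage_pct=100.0, signature_pct=100.0,
        )
        with pytest.warns(RuntimeWarning):
            corr = peptide_correlations(mp, table)
        assert np.isnan(corr.loc["F0", "F1"])


def test_hyperparameter_validation():
    with pytest.raises(ConfigError):
        FactorHyperparams(pi_seed=0.5, pi_other=0.9)
    with pytest.raises(ConfigError):
        FactorHyperparams(tau=0.0)
    with pytest.raises(ConfigError):
        FactorHyperparams(membership_threshold=1.5)
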