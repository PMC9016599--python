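"""ROC traverse, critical-value model, experiments, and regressions."""

import numpy as np
import pandas as pd
import pytest

from entsat import calibration as cal
from entsat.calibration import (
    CritModel,
    compute_roc,
    factorial_experiment,
    fit_crit_model,
    interaction_regression,
    predict_tcrit,
    run_gradient_experiment,
    select_tcrit,
)


def make_records(stat, positive, **extra):
    """Minimal records table for ROC tests."""
    n = len(stat)
    base = dict(
        replicate=np.arange(n),
        seed=np.arange(n),
        n_taxa=8,
        seq_len=500,
        mean_bl=0.2,
        stemminess=0.5,
        balanced=True,
        model="JC",
        p_invariant=0.0,
        tree_length_true=0.2 * 14,
        t_all=stat,
        t_inf=stat,
        rf_norm=np.where(positive, 0.5, 0.0),
        tl_error=np.where(positive, 1.0, 0.0),
        n_informative=100,
        n_variable=200,
        ok=True,
        fail_reason="",
    )
    base.update(extra)
    return pd.DataFrame(base)


class TestRoc:
    def test_perfect_separation(self):
        stat = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        pos = np.array([True, True, True, False, False, False])
        roc = compute_roc(make_records(stat, pos))
        assert roc.max_tpr_minus_fpr == pytest.approx(1.0)
        assert roc.tpr_at_tcrit == 1.0
        assert roc.fpr_at_tcrit == 0.0
        assert roc.chosen_tcrit == 10.0  # smallest threshold achieving max

    def test_vectors_non_decreasing(self, rng):
        stat = rng.normal(size=300)
        pos = rng.random(300) < 0.4
        roc = compute_roc(make_records(stat, pos))
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert len(roc.thresholds) == len(roc.tpr) == len(roc.fpr)

    def test_independent_labels_near_zero(self, rng):
        stat = rng.normal(size=1000)
        pos = rng.random(1000) < 0.5
        roc = compute_roc(make_records(stat, pos))
        assert roc.max_tpr_minus_fpr < 0.15  # permutation-baseline MC noise

    def test_single_class_rejected(self):
        stat = np.arange(5.0)
        with pytest.raises(ValueError):
            compute_roc(make_records(stat, np.ones(5, dtype=bool)))

    def test_tree_length_positives_definition(self):
        stat = np.array([0.0, 1.0, 2.0, 3.0])
        rec = make_records(stat, np.zeros(4, dtype=bool))
        rec["tl_error"] = [0.6, -0.7, 0.1, 0.0]  # |err| >= 0.5 -> positive
        roc = compute_roc(rec, positives_def="tree_length")
        assert roc.n_pos == 2 and roc.n_neg == 2

    def test_failed_replicates_excluded(self):
        stat = np.array([1.0, 2.0, 10.0, 11.0])
        rec = make_records(stat, np.array([True, True, False, False]))
        rec.loc[0, "ok"] = False
        roc = compute_roc(rec)
        assert roc.n_pos == 1 and roc.n_neg == 2


class TestSelectTcrit:
    def test_matches_exhaustive_scan(self, rng):
        stat = rng.normal(size=400)
        pos = stat + rng.normal(scale=0.5, size=400) < 0  # monotone noise
        roc = compute_roc(make_records(stat, pos))
        chosen = select_tcrit(roc)
        # brute force over every candidate threshold
        best, best_val = None, -np.inf
        for thr in roc.thresholds:
            tp = ((stat < thr) & pos).sum()
            fp = ((stat < thr) & ~pos).sum()
            if tp - fp > best_val:
                best, best_val = thr, tp - fp
        assert chosen == best
        assert chosen == roc.chosen_tcrit

    def test_binary_statistic_tie_break(self):
        stat = np.array([0.0, 0.0, 1.0, 1.0])
        pos = np.array([True, True, False, False])
        roc = compute_roc(make_records(stat, pos))
        assert select_tcrit(roc) == 1.0  # smallest threshold reaching TP-FP=2


class TestCritModel:
    def _exact_table(self):
        taxa = np.repeat([8, 32, 128], 4)
        length = np.tile([375, 625, 875, 1125], 3)
        t_crit = 1.5 + 2.0 * np.sqrt(taxa) + 0.3 * np.sqrt(length)
        return pd.DataFrame(
            dict(n_taxa=taxa, length_mid=length, t_crit=t_crit,
                 tpr=0.9, fpr=0.1, n=100)
        )

    def test_exact_linear_recovery(self):
        model = fit_crit_model(self._exact_table())
        assert model.intercept == pytest.approx(1.5, abs=1e-9)
        assert model.coef_sqrt_taxa == pytest.approx(2.0, abs=1e-9)
        assert model.coef_sqrt_len == pytest.approx(0.3, abs=1e-9)
        assert model.adjusted_r2 == pytest.approx(1.0, abs=1e-9)

    def test_adjusted_r2_closed_form(self, rng):
        table = self._exact_table()
        table["t_crit"] += rng.normal(scale=1.0, size=len(table))
        model = fit_crit_model(table)
        import statsmodels.api as sm

        X = sm.add_constant(
            np.column_stack(
                [np.sqrt(table["n_taxa"]), np.sqrt(table["length_mid"])]
            )
        )
        fit = sm.OLS(table["t_crit"], X).fit()
        n, p = len(table), 2
        adj = 1 - (1 - fit.rsquared) * (n - 1) / (n - p - 1)
        assert model.adjusted_r2 == pytest.approx(adj, abs=1e-12)

    def test_too_few_bins_rejected(self):
        table = self._exact_table().iloc[:2]
        with pytest.raises(ValueError):
            fit_crit_model(table)

    def test_prediction_at_calibration_bin(self):
        model = fit_crit_model(self._exact_table())
        t_crit, tpr, fpr, flag = predict_tcrit(model, 32, 625)
        assert t_crit == pytest.approx(1.5 + 2 * np.sqrt(32) + 0.3 * np.sqrt(625))
        assert (tpr, fpr) == (0.9, 0.1)
        assert not flag

    def test_extrapolation_flagged(self):
        model = fit_crit_model(self._exact_table())
        assert predict_tcrit(model, 2048, 625)[3] is True
        assert predict_tcrit(model, 32, 50_000)[3] is True

    def test_monotone_in_each_coordinate(self):
        model = fit_crit_model(self._exact_table())
        taxa = [8, 16, 32, 64, 128]
        preds = [model.predict(t, 500)[0] for t in taxa]
        assert np.all(np.diff(preds) > 0)  # positive sqrt-taxa coefficient

    def test_save_load_roundtrip(self, tmp_path):
        model = fit_crit_model(self._exact_table())
        path = tmp_path / "model.txt"
        model.save(str(path))
        back = CritModel.load(str(path))
        assert back.intercept == pytest.approx(model.intercept)
        assert back.coef_sqrt_taxa == pytest.approx(model.coef_sqrt_taxa)
        assert back.taxa_range == model.taxa_range
        assert len(back.per_bin) == len(model.per_bin)


class TestGradientExperiment:
    def test_determinism_and_shape(self):
        a = run_gradient_experiment(n_sims=6, seed=7, taxa_choices=(8,))
        b = run_gradient_experiment(n_sims=6, seed=7, taxa_choices=(8,))
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 6
        assert a["ok"].all()

    def test_rows_reproducible_from_recorded_seed(self):
        from entsat.calibration import _run_replicate

        rec = run_gradient_experiment(n_sims=4, seed=3, taxa_choices=(8,))
        row = rec.iloc[2]
        redo = _run_replicate(
            2, int(row.n_taxa), int(row.seq_len), float(row.mean_bl),
            float(row.stemminess), bool(row.balanced), str(row.model),
            float(row.p_invariant), int(row.seed),
        )
        assert redo["t_inf"] == pytest.approx(row.t_inf)
        assert redo["rf_norm"] == pytest.approx(row.rf_norm)

    def test_degenerate_ranges(self):
        rec = run_gradient_experiment(
            n_sims=4, seed=1, taxa_choices=(8,),
            ranges=dict(mean_bl=(0.3, 0.3), stemminess=(0.5, 0.5),
                        seq_len=(300, 300), p_invariant=(0.0, 0.0)),
        )
        assert (rec["mean_bl"] == 0.3).all()
        assert (rec["seq_len"] == 300).all()

    def test_saturation_statistic_direction(self):
        # short branches: far from saturation; long branches: close to it
        slow = run_gradient_experiment(
            n_sims=12, seed=5, taxa_choices=(8,),
            ranges=dict(mean_bl=(0.05, 0.05), p_invariant=(0.0, 0.0)),
            p_gtr=0.0,
        )
        fast = run_gradient_experiment(
            n_sims=12, seed=5, taxa_choices=(8,),
            ranges=dict(mean_bl=(0.65, 0.65), p_invariant=(0.0, 0.0)),
            p_gtr=0.0,
        )
        assert slow["t_inf"].mean() > fast["t_inf"].mean()
        assert slow["rf_norm"].mean() < fast["rf_norm"].mean()


class TestFactorialExperiment:
    def test_row_count_combinatorics(self):
        levels = dict(
            n_taxa=(8,), seq_len=(250, 300), mean_bl=(0.1, 0.5),
            stemminess=(0.5,), p_invariant=(0.0,),
            balanced=(True, False), model=("JC", "GTRG"),
        )
        rec = factorial_experiment(levels, reps_per_cell=2, seed=1)
        assert len(rec) == 2 * 2 * 2 * 2 * 2

    def test_reproducible(self):
        levels = dict(
            n_taxa=(8,), seq_len=(250,), mean_bl=(0.2,), stemminess=(0.5,),
            p_invariant=(0.0,), balanced=(True,), model=("JC",),
        )
        a = factorial_experiment(levels, reps_per_cell=3, seed=9)
        b = factorial_experiment(levels, reps_per_cell=3, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestInteractionRegression:
    def _factorial_frame(self, rng, n_reps=2):
        rows = []
        i = 0
        for taxa in (8, 32):
            for length in (250, 500):
                for bl in (0.1, 0.5):
                    for stem in (0.2, 0.8):
                        for bal in (True, False):
                            for kind in ("JC", "GTRG"):
                                for _ in range(n_reps):
                                    rows.append(dict(
                                        replicate=i, seed=i, n_taxa=taxa,
                                        seq_len=length, mean_bl=bl,
                                        stemminess=stem, balanced=bal,
                                        model=kind, p_invariant=0.0,
                                        tree_length_true=bl * (2 * taxa - 2),
                                        t_all=0.0, t_inf=0.0,
                                        rf_norm=float(rng.random()),
                                        tl_error=0.0,
                                        n_informative=100,
                                        n_variable=int(rng.integers(50, 200)),
                                        ok=True, fail_reason="",
                                    ))
                                    i += 1
        return pd.DataFrame(rows)

    def test_term_inventory(self, rng):
        table = interaction_regression(self._factorial_frame(rng), "rf_norm")
        fitted = table[~table["dropped"]]
        # intercept + 6 main effects + n_variable + 15 pairwise interactions
        assert set(fitted["term"]).issuperset({"n_taxa", "n_variable",
                                              "n_taxa:seq_len"})
        assert len(table) == 1 + 6 + 1 + 15

    def test_collinear_term_dropped_with_warning(self, rng):
        frame = self._factorial_frame(rng)
        frame["stemminess"] = 0.5  # constant factor -> collinear columns
        with pytest.warns(UserWarning):
            table = interaction_regression(frame, "rf_norm")
        assert table["dropped"].any()

    def test_equal_pvalues_equal_adjusted(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(np.full(8, 0.03), method="fdr_bh")[1]
        assert np.allclose(adj, adj[0])

    def test_signal_term_detected(self, rng):
        frame = self._factorial_frame(rng, n_reps=4)
        frame["rf_norm"] = (
            0.01 * frame["tree_length_true"]
            + 0.3 * (frame["model"] == "GTRG")
            + rng.normal(scale=0.01, size=len(frame))
        )
        table = interaction_regression(frame, "rf_norm")
        row = table[table["term"] == "model_gtr"].iloc[0]
        assert row["p_fdr"] < 0.01
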