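"""Scoring metrics and Borda aggregation."""

import numpy as np
import pandas as pd
import pytest

from purepremium import copulas as cop
from purepremium import selection as sel
from purepremium.copulas import CopulaSpec
from purepremium.synthetic import SyntheticConfig, simulate_panel


class TestMseMape:
    def test_perfect_prediction_is_zero(self):
        assert sel.metric_mse_mape([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_hand_computed_values(self):
        mse, mape = sel.metric_mse_mape([110.0, 90.0], [100.0, 100.0])
        assert mse == pytest.approx(100.0)
        assert mape == pytest.approx(10.0)

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(0)
        pred = rng.uniform(50, 150, 20)
        obs = rng.uniform(50, 150, 20)
        mse1, mape1 = sel.metric_mse_mape(pred, obs)
        mse2, mape2 = sel.metric_mse_mape(3.0 * pred, 3.0 * obs)
        assert mse2 == pytest.approx(9.0 * mse1)
        assert mape2 == pytest.approx(mape1)

    def test_zero_observed_raises(self):
        with pytest.raises(ValueError):
            sel.metric_mse_mape([1.0], [0.0])
        with pytest.raises(ValueError):
            sel.metric_mse_mape([1.0, 2.0], [1.0])


class TestRsce:
    def test_matches_brute_force_loop(self):
        spec = CopulaSpec("frank", 4.0)
        u, v = cop.sample_copula(80, spec, 0)
        u, v = cop.pseudo_observations(u, v)
        got = sel.metric_rsce(spec, (u, v))
        total = 0.0
        for ui, vi in zip(u, v):
            cn = np.mean((u <= ui) & (v <= vi))
            ct = float(cop.copula_cdf(ui, vi, spec))
            total += (ct - cn) ** 2
        assert got == pytest.approx(np.sqrt(total), abs=1e-12)

    def test_generating_family_beats_misspecified(self):
        truth = CopulaSpec("clayton", cop.theta_from_tau("clayton", 0.6))
        u, v = cop.sample_copula(2000, truth, 3)
        u, v = cop.pseudo_observations(u, v)
        fit_true = cop.fit_copula(u, v, "clayton")
        fit_bad = cop.fit_copula(u, v, "gumbel")
        assert sel.metric_rsce(fit_true.spec, (u, v)) < sel.metric_rsce(
            fit_bad.spec, (u, v))


class TestXvcic:
    def test_deterministic_given_data(self):
        u, v = cop.sample_copula(200, CopulaSpec("frank", 4.0), 5)
        a = sel.metric_xvcic(u, v, "frank", n_folds=5)
        b = sel.metric_xvcic(u, v, "frank", n_folds=5)
        assert a == b

    def test_prefers_generating_family(self):
        """Lower (better) for the generating family in most repetitions."""
        wins = 0
        reps = 20
        truth = CopulaSpec("clayton", cop.theta_from_tau("clayton", 0.5))
        for i in range(reps):
            u, v = cop.sample_copula(500, truth, 100 + i)
            u, v = cop.pseudo_observations(u, v)
            good = sel.metric_xvcic(u, v, "clayton", n_folds=5)
            bad = sel.metric_xvcic(u, v, "gumbel", n_folds=5)
            wins += good < bad
        assert wins >= 0.8 * reps

    def test_requires_twenty_pairs(self):
        with pytest.raises(ValueError):
            sel.metric_xvcic(np.ones(5) * 0.5, np.ones(5) * 0.5, "frank")


class TestRgofc:
    def test_flag_is_binary_and_null_not_rejected(self):
        u, v = cop.sample_copula(200, CopulaSpec("frank", 5.0), 9)
        flag, pval = sel.metric_rgofc(u, v, "frank", n_boot=100, seed=1)
        assert flag in (0, 1)
        assert 0.0 < pval <= 1.0

    def test_power_against_strong_misspecification(self):
        """Clayton tau=0.6 data fitted with Gumbel is rejected."""
        truth = CopulaSpec("clayton", cop.theta_from_tau("clayton", 0.6))
        u, v = cop.sample_copula(1000, truth, 2)
        u, v = cop.pseudo_observations(u, v)
        flag, pval = sel.metric_rgofc(u, v, "gumbel", n_boot=100, seed=3)
        assert flag == 1 and pval < 0.05

    def test_n_boot_floor(self):
        u, v = cop.sample_copula(100, CopulaSpec("frank", 5.0), 9)
        with pytest.raises(ValueError):
            sel.metric_rgofc(u, v, "frank", n_boot=50)


class TestBorda:
    def _board(self, table):
        scores = []
        for mid, (mse, mape, rsce, xv, flag) in table.items():
            scores.append(sel.ModelScore(mid, "poisson", "gamma", "frank",
                                         mse, mape, rsce, xv, flag, 0.5, 1.0))
        return sel.Scoreboard(scores=scores)

    def test_unanimous_winner(self):
        board = self._board({
            "A": (2.0, 2.0, 2.0, 2.0, 1),
            "B": (1.0, 1.0, 1.0, 1.0, 0),
            "C": (3.0, 3.0, 3.0, 3.0, 1),
        })
        assert sel.borda_select(board) == "B"
        assert board.totals["B"] == 4.0  # four rank-1 metrics + flag 0

    def test_hand_computed_totals(self):
        board = self._board({
            "A": (1.0, 4.0, 2.0, 3.0, 0),   # ranks 1,4,2,3 -> 10
            "B": (2.0, 1.0, 4.0, 2.0, 1),   # ranks 2,1,4,2 -> 9 + 1 = 10
            "C": (3.0, 2.0, 1.0, 4.0, 0),   # ranks 3,2,1,4 -> 10
            "D": (4.0, 3.0, 3.0, 1.0, 0),   # ranks 4,3,3,1 -> 11
        })
        sel.borda_select(board)
        assert board.totals.to_dict() == {"A": 10.0, "B": 10.0, "C": 10.0, "D": 11.0}
        # three-way tie on totals -> least RSCE wins (C has rsce=1.0)
        assert board.winner == "C"

    def test_totals_within_borda_bounds(self):
        rng = np.random.default_rng(4)
        table = {f"M{i}": tuple(rng.uniform(1, 9, 4)) + (int(rng.integers(0, 2)),)
                 for i in range(10)}
        board = self._board(table)
        sel.borda_select(board)
        assert board.totals.min() >= 4 * 1 + 0
        assert board.totals.max() <= 4 * 10 + 1

    def test_permutation_invariance(self):
        table = {
            "A": (1.0, 4.0, 2.0, 3.0, 0),
            "B": (2.0, 1.0, 4.0, 2.0, 1),
            "C": (3.0, 2.0, 1.0, 4.0, 0),
        }
        w1 = sel.borda_select(self._board(table))
        w2 = sel.borda_select(self._board(dict(reversed(list(table.items())))))
        assert w1 == w2

    def test_too_few_candidates(self):
        with pytest.raises(ValueError):
            sel.borda_select(self._board({"A": (1.0, 1.0, 1.0, 1.0, 0)}))


def test_score_models_restricted_grid_recovers_truth():
    """With the generating model in a small grid, it wins."""
    cfg = SyntheticConfig(seed=13, years=tuple(range(2004, 2019)),
                          base_exposed=np.full(56, 3000.0))
    panel = simulate_panel(cfg)
    grid = (("negbin", "lognormal", "frank"),
            ("poisson", "lognormal", "gumbel"),
            ("negbin", "lognormal", "clayton"))
    board = sel.score_models(panel, grid=grid, seed=0, n_boot=100,
                             rgofc_subsample=150)
    assert board.winner == "negbin+lognormal+frank"
    df = board.to_frame()
    assert len(df) == 3 and not df["failed"].any()


def test_scoreboard_csv_layout(tmp_path):
    cfg = SyntheticConfig(seed=13, years=tuple(range(2010, 2019)))
    panel = simulate_panel(cfg)
    grid = (("poisson", "gamma", "frank"), ("negbin", "gamma", "frank"))
    board = sel.score_models(panel, grid=grid, seed=0, n_boot=100)
    out = tmp_path / "scoreboard.csv"
    sel.scoreboard_to_csv(board, out, year=2018)
    df = pd.read_csv(out)
    assert list(df.columns[:5]) == ["year", "model_id", "frequency_family",
                                    "severity_family", "copula_family"]
    assert len(df) == 2
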