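"""Dirichlet-multinomial composition model: HPD oracle, limits, symmetries."""

import numpy as np
import pandas as pd
import pytest

from cryptomics.composition import (
    DirichletMultinomialModel,
    PosteriorDraws,
    credible_shifts,
    fit_dirichlet_multinomial,
    hpd_interval,
    hpd_interval_batch,
)
from cryptomics.core import ValidationError


def brute_force_hpd(samples, mass):
    """Independent oracle: scan every contiguous sorted window."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    m = int(np.ceil(mass * n))
    best = None
    for j in range(n - m + 1):
        width = s[j + m - 1] - s[j]
        if best is None or width < best[0] - 0 or (width == best[0] and False):
            if best is None or width < best[0]:
                best = (width, s[j], s[j + m - 1])
    return best[1], best[2]


class TestHpdInterval:
    def test_integer_ramp_tie_break(self):
        lo, hi = hpd_interval(np.arange(1, 101), mass=0.95)
        assert (lo, hi) == (1.0, 95.0)  # ties broken to smallest lower bound

    @pytest.mark.parametrize("n,mass", [(100, 0.95), (341, 0.9), (1000, 0.5), (37, 0.8)])
    def test_matches_brute_force_window_oracle(self, n, mass, rng):
        x = rng.gamma(2.0, 1.5, n)
        assert hpd_interval(x, mass) == pytest.approx(brute_force_hpd(x, mass))

    def test_standard_normal_quantiles(self, rng):
        x = rng.standard_normal(1_000_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_constant_samples_zero_width(self):
        lo, hi = hpd_interval(np.full(200, 3.3), 0.95)
        assert lo == hi == 3.3

    def test_mass_validation(self):
        with pytest.raises(ValidationError):
            hpd_interval(np.arange(100), mass=1.5)

    def test_batch_agrees_with_scalar(self, rng):
        x = rng.normal(size=(4, 500))
        batch = hpd_interval_batch(x, 0.9)
        for i in range(4):
            assert tuple(batch[i]) == hpd_interval(x[i], 0.9)


def _fit(table, cond, **kw):
    kw.setdefault("n_iter", 800)
    kw.setdefault("n_warmup", 400)
    kw.setdefault("n_chains", 2)
    kw.setdefault("seed", 0)
    return fit_dirichlet_multinomial(table, cond, **kw)


def _two_cond_table(rows_a, rows_b, columns):
    idx = [f"a{i}" for i in range(len(rows_a))] + [f"b{i}" for i in range(len(rows_b))]
    tab = pd.DataFrame(rows_a + rows_b, index=idx, columns=columns)
    cond = pd.Series(["CD"] * len(rows_a) + ["HFHSD"] * len(rows_b), index=idx)
    return tab, cond


class TestFit:
    def test_single_cell_type_degenerate(self):
        tab, cond = _two_cond_table([[100], [90]], [[80], [120]], ["only"])
        res = _fit(tab, cond)
        rep = res.shift_report()
        assert np.allclose(res.draws.p, 1.0)
        assert rep.loc["only", "delta_mean"] == 0.0
        assert not rep.loc["only", "credible"]

    def test_symmetric_data_near_zero_shift(self):
        row = [1200, 900, 600, 300]
        tab, cond = _two_cond_table([row] * 3, [row] * 3, list("ABCD"))
        res = _fit(tab, cond, n_iter=2000, n_warmup=800)
        rep = res.shift_report()
        assert rep["delta_mean"].abs().max() < 0.02

    def test_conjugate_limit_with_gamma_pinned(self):
        """gamma -> inf reduces to a multinomial; posterior = Dirichlet(1 + x)."""
        tab, cond = _two_cond_table([[90, 10]], [[50, 50]], ["A", "B"])
        import warnings

        with warnings.catch_warnings():
            # single sample per condition: R-hat on short chains may warn
            warnings.simplefilter("ignore", UserWarning)
            res = _fit(tab, cond, fixed_gamma=1e9, n_iter=4000, n_warmup=1500, seed=3)
        post = res.posterior_mean()
        assert post.loc["CD", "A"] == pytest.approx(91 / 102, abs=0.01)
        assert post.loc["CD", "B"] == pytest.approx(11 / 102, abs=0.01)
        assert post.loc["HFHSD", "A"] == pytest.approx(51 / 102, abs=0.015)

    def test_draws_stay_on_simplex(self):
        tab, cond = _two_cond_table(
            [[30, 40, 30]] * 3, [[10, 60, 30]] * 3, list("XYZ")
        )
        res = _fit(tab, cond)
        sums = res.draws.p.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_empty_cell_type_dropped_with_warning(self):
        tab, cond = _two_cond_table([[5, 0, 7]] * 3, [[3, 0, 9]] * 3, list("PQR"))
        with pytest.warns(UserWarning, match="dropped"):
            model = DirichletMultinomialModel(tab, cond)
        assert model.cell_types == ["P", "R"]

    def test_zero_count_condition_flagged_in_report(self):
        tab, cond = _two_cond_table([[20, 0]] * 3, [[15, 5]] * 3, ["A", "B"])
        res = _fit(tab, cond)
        rep = res.shift_report()
        assert rep.loc["B", "zero_count_condition"] == "CD"

    def test_label_permutation_statistically_equivalent(self):
        tab, cond = _two_cond_table(
            [[300, 200, 100]] * 3, [[100, 200, 300]] * 3, list("ABC")
        )
        res1 = _fit(tab, cond, n_iter=3000, n_warmup=1000)
        perm = ["C", "A", "B"]
        res2 = _fit(tab[perm], cond, n_iter=3000, n_warmup=1000, seed=1)
        m1 = res1.shift_report()["delta_mean"]
        m2 = res2.shift_report()["delta_mean"].reindex(m1.index)
        assert np.allclose(m1.values, m2.values, atol=0.02)

    def test_summary_mentions_conditions_and_types(self):
        tab, cond = _two_cond_table([[40, 60]] * 3, [[55, 45]] * 3, ["A", "B"])
        text = _fit(tab, cond).summary()
        assert "CD -> HFHSD" in text and "delta_mean" in text


class TestCredibleShifts:
    def _draws(self, delta):
        """Build PosteriorDraws with prescribed shift draws for one type."""
        T = len(delta)
        p = np.zeros((1, T, 2, 2))
        p[0, :, 0, 0] = 0.5
        p[0, :, 1, 0] = 0.5 + np.asarray(delta)
        p[..., 1] = 1.0 - p[..., 0]
        return PosteriorDraws(
            p, np.zeros((1, T)), ["k", "rest"], ("CD", "HFHSD"),
            np.ones((1, 2)), np.ones(1), {"log_gamma": 1.0},
        )

    def test_all_positive_draws_credible(self):
        rep = credible_shifts(self._draws(np.linspace(0.01, 0.1, 200)))
        assert bool(rep.loc["k", "credible"])

    def test_symmetric_draws_not_credible(self):
        rep = credible_shifts(self._draws(np.linspace(-0.1, 0.1, 201)))
        assert not bool(rep.loc["k", "credible"])

    def test_condition_swap_negates_shift_and_mirrors_hpd(self):
        draws = self._draws(np.sort(np.random.default_rng(5).normal(0.03, 0.02, 400)))
        rep = credible_shifts(draws)
        swapped = PosteriorDraws(
            draws.p[:, :, ::-1, :], draws.log_gamma, draws.cell_types,
            ("HFHSD", "CD"), draws.accept_theta, draws.accept_gamma, draws.rhat,
        )
        rep_swapped = credible_shifts(swapped)
        assert rep_swapped.loc["k", "delta_mean"] == pytest.approx(-rep.loc["k", "delta_mean"])
        assert rep_swapped.loc["k", "hpd_lower"] == pytest.approx(-rep.loc["k", "hpd_upper"])
        assert rep_swapped.loc["k", "hpd_upper"] == pytest.approx(-rep.loc["k", "hpd_lower"])
        assert rep_swapped.loc["k", "credible"] == rep.loc["k", "credible"]
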