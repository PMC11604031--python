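"""Sliding-window enumeration and the interval of maximum local divergence."""

import json

import numpy as np
import pytest

from kldomain import (
    CurveSet,
    DomainSelector,
    GaussianGridParams,
    GridDomain,
    ShrinkageConfig,
    divergence_profile,
    divergence_vs_length,
    enumerate_windows,
    select_interval,
    select_sequential,
    window_size_from_fraction,
)
from kldomain.exceptions import InvalidInputError, InvalidParameterError

from conftest import random_pd_params

FIXED = ShrinkageConfig(eta=1.0)


def oracle_kl(mean_x, cov_x, mean_y, cov_y):
    """Independent KL evaluation: explicit inverse and slogdet."""
    d = mean_y - mean_x
    inv_y = np.linalg.inv(cov_y)
    p = len(d)
    _, ld_y = np.linalg.slogdet(cov_y)
    _, ld_x = np.linalg.slogdet(cov_x)
    return 0.5 * (np.trace(inv_y @ cov_x) - p + d @ inv_y @ d + ld_y - ld_x)


class TestWindowRule:
    @pytest.mark.parametrize(
        "c, p, w",
        [
            (0.1, 100, 10),
            (0.9, 100, 90),
            (1.0, 50, 50),
            (0.1, 96, 10),
            (0.2, 96, 19),
            (0.25, 96, 24),
            (0.3, 96, 29),
            (0.4, 96, 38),
            (0.5, 96, 48),
            (0.6, 96, 58),
            (0.7, 96, 67),
            (0.75, 96, 72),
            (0.8, 96, 77),
            (0.9, 96, 86),
            (1.0, 96, 96),
        ],
    )
    def test_round_half_up(self, c, p, w):
        assert window_size_from_fraction(c, p) == w

    @pytest.mark.parametrize("c", [0.0, -0.1, 1.01])
    def test_invalid_fraction(self, c):
        with pytest.raises(InvalidParameterError):
            window_size_from_fraction(c, 100)


class TestEnumeration:
    @pytest.mark.parametrize("p, w, count", [(100, 10, 91), (100, 90, 11), (5, 5, 1)])
    def test_counts(self, p, w, count):
        wins = enumerate_windows(p, w)
        assert len(wins) == count
        assert [win.start for win in wins] == list(range(1, p - w + 2))

    def test_window_geometry_with_grid(self):
        grid = GridDomain.regular(0.0, np.pi, 100)
        win = enumerate_windows(100, 10, grid=grid)[0]
        pts = grid.points[:10]
        assert win.center_time == pytest.approx((pts[0] + pts[-1]) / 2)
        assert win.radius_time == pytest.approx((pts[-1] - pts[0]) / 2)
        assert win.center_index == pytest.approx(5.5)
        assert win.end == 10

    def test_oversized_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            enumerate_windows(5, 6)


class TestProfile:
    def test_identical_params_all_zero(self, rng):
        params = random_pd_params(rng, 20)
        prof = divergence_profile(params, params, 0.2)
        assert len(prof) == 17
        np.testing.assert_allclose(prof["kl"], 0.0, atol=1e-12)

    def test_c_one_reduces_to_global(self, rng):
        px, py = random_pd_params(rng, 8), random_pd_params(rng, 8)
        prof = divergence_profile(px, py, 1.0)
        assert len(prof) == 1
        assert prof["kl"].iloc[0] == pytest.approx(
            oracle_kl(px.mean, px.cov, py.mean, py.cov), rel=1e-10
        )

    def test_localized_difference_found(self, rng):
        p = 60
        grid = GridDomain.regular(0, 1, p)
        cov = np.eye(p)
        mean_x = np.zeros(p)
        mean_y = np.zeros(p)
        mean_y[25:35] = 3.0  # difference confined to indices 25..34 (0-based)
        px = GaussianGridParams(grid=grid, mean=mean_x, cov=cov)
        py = GaussianGridParams(grid=grid, mean=mean_y, cov=cov)
        prof = divergence_profile(px, py, 10 / p)
        best = prof.iloc[prof["kl"].idxmax()]
        assert best["start"] == 26  # 1-based: exactly the shifted block
        assert len(prof) == p - 10 + 1

    def test_profile_length_invariant(self, rng):
        for _ in range(10):
            p = int(rng.integers(5, 40))
            c = float(rng.uniform(0.05, 1.0))
            px, py = random_pd_params(rng, p), random_pd_params(rng, p)
            w = window_size_from_fraction(c, p)
            assert len(divergence_profile(px, py, c)) == p - w + 1


class TestSelectInterval:
    def test_identical_groups_tie_break_to_first_window(self, rng, unit_grid):
        vals = rng.normal(size=(30, 5))
        cx = CurveSet(grid=unit_grid, values=vals, label="X")
        cy = CurveSet(grid=unit_grid, values=vals.copy(), label="Y")
        result = select_interval(cx, cy, 0.4, shrinkage=FIXED)
        assert result.kl_value == pytest.approx(0.0, abs=1e-10)
        assert result.window.start == 1

    def test_matches_exhaustive_oracle(self, rng):
        # independent re-enumeration + inv/slogdet KL on the same estimates
        for _ in range(50):
            p = int(rng.integers(6, 41))
            n = 3 * p
            grid = GridDomain.regular(0, 1, p)
            base = rng.normal(size=(n, p))
            shift = np.zeros(p)
            lo = int(rng.integers(0, p - 2))
            shift[lo : lo + 3] = rng.normal(scale=2.0)
            cx = CurveSet(grid=grid, values=base + shift, label="X")
            cy = CurveSet(grid=grid, values=rng.normal(size=(n, p)), label="Y")
            c = float(rng.uniform(0.1, 0.9))
            result = select_interval(cx, cy, c, shrinkage=FIXED)

            w = window_size_from_fraction(c, p)
            mx, covx = cx.values.mean(0), np.cov(cx.values.T, bias=True)
            my, covy = cy.values.mean(0), np.cov(cy.values.T, bias=True)
            best_val, best_start = -np.inf, None
            for start in range(p - w + 1):
                sl = slice(start, start + w)
                val = oracle_kl(mx[sl], covx[sl, sl], my[sl], covy[sl, sl])
                if val > best_val:
                    best_val, best_start = val, start + 1
            assert result.window.start == best_start
            assert result.kl_value == pytest.approx(best_val, rel=1e-8)

    def test_recovers_injected_mean_shift(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            p, n = 50, 200
            grid = GridDomain.regular(0, 1, p)
            x = rng.normal(size=(n, p))
            y = rng.normal(size=(n, p))
            y[:, 19:29] += 1.5  # shifted block: 1-based columns 20..29
            cx = CurveSet(grid=grid, values=x, label="X")
            cy = CurveSet(grid=grid, values=y, label="Y")
            result = select_interval(cx, cy, 10 / p, shrinkage=FIXED)
            if 20 <= result.window.start <= 29:
                hits += 1
        assert hits >= 19

    def test_grid_mismatch_rejected(self, rng):
        a = CurveSet(grid=GridDomain.regular(0, 1, 5), values=rng.normal(size=(10, 5)))
        b = CurveSet(grid=GridDomain.regular(0, 2, 5), values=rng.normal(size=(10, 5)))
        with pytest.raises(InvalidInputError):
            select_interval(a, b, 0.5, shrinkage=FIXED)

    def test_report_serialization_deterministic(self, rng, unit_grid):
        vals_x = rng.normal(size=(25, 5))
        vals_y = rng.normal(size=(25, 5)) + 1.0
        cx = CurveSet(grid=unit_grid, values=vals_x, label="X")
        cy = CurveSet(grid=unit_grid, values=vals_y, label="Y")
        r1 = select_interval(cx, cy, 0.4, shrinkage=FIXED)
        r2 = select_interval(cx, cy, 0.4, shrinkage=FIXED)
        assert json.dumps(r1.to_dict()) == json.dumps(r2.to_dict())
        report = r1.to_dict()
        assert report["end"] == report["start"] + report["w"] - 1
        assert len(report["profile"]) == 5 - 2 + 1


class TestSequential:
    def _curves(self, rng, p, n=120):
        grid = GridDomain.regular(0, 1, p)
        x = rng.normal(size=(n, p))
        y = rng.normal(size=(n, p))
        y[:, : p // 3] += 2.0
        y[:, -p // 3 :] += 1.0
        return (
            CurveSet(grid=grid, values=x, label="X"),
            CurveSet(grid=grid, values=y, label="Y"),
        )

    def test_k1_equals_select_interval(self, rng):
        cx, cy = self._curves(rng, 30)
        seq = select_sequential(cx, cy, 10 / 30, K=1, shrinkage=FIXED)
        single = select_interval(cx, cy, 10 / 30, shrinkage=FIXED)
        assert len(seq) == 1
        assert seq[0].window == single.window
        assert seq[0].kl_value == pytest.approx(single.kl_value)

    def test_three_disjoint_windows_when_domain_allows(self, rng):
        cx, cy = self._curves(rng, 30)
        seq = select_sequential(cx, cy, 10 / 30, K=3, shrinkage=FIXED)
        assert len(seq) == 3
        covered = set()
        for res in seq:
            idx = set(res.window.indices0.tolist())
            assert not covered & idx
            covered |= idx

    def test_domain_exhaustion_returns_fewer(self, rng):
        cx, cy = self._curves(rng, 25)
        seq = select_sequential(cx, cy, 0.4, K=3, shrinkage=FIXED)  # w = 10 on p = 25
        assert len(seq) <= 2


class TestDivergenceVsLength:
    def test_identical_params_all_zero(self, rng):
        params = random_pd_params(rng, 12)
        table = divergence_vs_length(params, params, [0.25, 0.5, 1.0])
        np.testing.assert_allclose(table["max_kl"], 0.0, atol=1e-12)

    def test_c_one_row_equals_global(self, rng):
        px, py = random_pd_params(rng, 10), random_pd_params(rng, 10)
        table = divergence_vs_length(px, py, [1.0])
        assert table.shape[0] == 1
        assert table["max_kl"].iloc[0] == pytest.approx(
            oracle_kl(px.mean, px.cov, py.mean, py.cov), rel=1e-10
        )

    def test_doubling_aligned_window_is_monotone(self, rng):
        # w divides p, so every w-window is nested in some 2w-window
        p, w = 24, 4
        px, py = random_pd_params(rng, p), random_pd_params(rng, p)
        table = divergence_vs_length(px, py, [w / p, 2 * w / p])
        assert table["max_kl"].iloc[1] >= table["max_kl"].iloc[0] - 1e-10


class TestDomainSelectorEstimator:
    def _xy(self, rng, p=30, n=80):
        X = np.vstack([rng.normal(size=(n, p)), rng.normal(size=(n, p))])
        X[n:, 10:16] += 2.0
        y = np.array([0] * n + [1] * n)
        return X, y

    def test_sklearn_contract(self, rng):
        from sklearn.base import clone

        sel = DomainSelector(c=0.2, eta=1.0)
        assert clone(sel).get_params()["c"] == 0.2
        X, y = self._xy(rng)
        sel.fit(X, y)
        assert sel.window_.size == window_size_from_fraction(0.2, 30)
        assert sel.profile_.shape[0] == 30 - sel.window_.size + 1
        assert sel.transform(X).shape == (160, sel.window_.size)
        assert sel.get_support().sum() == sel.window_.size

    def test_finds_separating_block(self, rng):
        X, y = self._xy(rng)
        sel = DomainSelector(c=6 / 30, eta=1.0).fit(X, y)
        # difference lives in 0-based columns 10..15 -> 1-based 11..16
        assert 9 <= sel.window_.start <= 18

    def test_pipeline_composition(self, rng):
        from sklearn.pipeline import make_pipeline
        from sklearn.linear_model import LogisticRegression

        X, y = self._xy(rng)
        pipe = make_pipeline(
            DomainSelector(c=0.2, eta=1.0), LogisticRegression(max_iter=200)
        )
        pipe.fit(X, y)
        assert pipe.score(X, y) > 0.8
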