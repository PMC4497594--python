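"""Gravity family and radiation model: formulas, fitting, balancing, circles."""

import numpy as np
import pandas as pd
import pytest

from odmodels.models import (
    GravityParams,
    circle_populations,
    fit_constrained_gravity,
    fit_gravity,
    fit_radiation_fraction,
    gravity_factor,
    gravity_predict,
    radiation_predict,
)
from odmodels.synthetic import SyntheticConfig, generate_districts, simulate_flows

from conftest import toy_districts


def _dist(d):
    xy = d[["x_km", "y_km"]].to_numpy()
    diff = xy[:, None, :] - xy[None, :, :]
    return np.hypot(diff[..., 0], diff[..., 1])


def _od_from(d, trips=None):
    dist = _dist(d)
    n = len(d)
    i, j = np.where(~np.eye(n, dtype=bool))
    od = pd.DataFrame(
        {
            "origin_id": d["district_id"].to_numpy()[i],
            "dest_id": d["district_id"].to_numpy()[j],
            "pop_orig": d["population"].to_numpy()[i],
            "pop_dest": d["population"].to_numpy()[j],
            "dist_euclid_km": dist[i, j],
            "trips": 0 if trips is None else trips,
        }
    )
    return od


class TestGravityPredict:
    def test_all_exponents_zero_constant(self, small_od):
        pred = gravity_predict(GravityParams(0, 0, 0, np.log(3.5)), small_od)
        assert np.allclose(pred, 3.5)

    def test_direct_arithmetic(self):
        d = toy_districts([1000, 2000], [(0, 0), (10, 0)])
        od = _od_from(d)
        pred = gravity_predict(GravityParams(1, 1, 2, np.log(1e-3)), od)
        # 1e-3 * 1000 * 2000 / 100 = 20 on both directions
        assert np.allclose(pred, 20.0)

    def test_inverse_square_distance(self):
        d1 = toy_districts([1000, 2000], [(0, 0), (10, 0)])
        d2 = toy_districts([1000, 2000], [(0, 0), (20, 0)])
        p = GravityParams(1, 1, 2, np.log(1e-3))
        assert np.allclose(gravity_predict(p, _od_from(d1)), 4 * gravity_predict(p, _od_from(d2)))

    def test_zero_distance_error(self):
        d = toy_districts([10, 10], [(0, 0), (1, 0)])
        od = _od_from(d)
        od["dist_euclid_km"] = 0.0
        with pytest.raises(ValueError):
            gravity_predict(GravityParams(1, 1, 1, 0), od)


class TestFitGravity:
    def test_refit_is_a_fixed_point(self, study_world):
        _, d, od = study_world
        p1 = fit_gravity(od)
        od2 = od.copy()
        od2["trips"] = gravity_predict(p1, od)
        p2 = fit_gravity(od2)
        assert p2.alpha == pytest.approx(p1.alpha, abs=1e-6)
        assert p2.beta == pytest.approx(p1.beta, abs=1e-6)
        assert p2.gamma == pytest.approx(p1.gamma, abs=1e-6)
        assert p2.log_k == pytest.approx(p1.log_k, abs=1e-4)

    def test_flat_distance_truth_ci_covers_zero(self, small_world):
        d, _ = small_world
        covered = 0
        for seed in range(10):
            od = simulate_flows(d, GravityParams(0.8, 0.8, 0.0, -17.0), seed=seed)
            p = fit_gravity(od)
            lo, hi = p.conf_int["gamma"]
            covered += lo <= 0.0 <= hi
        assert covered >= 8

    def test_equal_populations_not_identifiable(self):
        d = toy_districts([100] * 6, [(i * 7.0, (i * i) % 5) for i in range(6)])
        od = _od_from(d, trips=1)
        with pytest.raises(ValueError, match="non-identifiable"):
            fit_gravity(od)

    def test_too_few_routes(self):
        d = toy_districts([10, 20], [(0, 0), (3, 4)])
        with pytest.raises(ValueError, match="at least 5"):
            fit_gravity(_od_from(d, trips=1))


def _brute_force_ipf(obs, f, variant, iters=50_000, tol=1e-12):
    """Plain-loop IPF oracle, independent of the implementation under test."""
    n, m = obs.shape
    a = np.ones(n)
    b = np.ones(m)
    O = obs.sum(axis=1)
    D = obs.sum(axis=0)
    for _ in range(iters):
        olda, oldb = a.copy(), b.copy()
        if variant in ("production", "doubly"):
            for i in range(n):
                s = sum(b[j] * f[i, j] for j in range(m))
                a[i] = O[i] / s if s > 0 else 0.0
        if variant in ("attraction", "doubly"):
            for j in range(m):
                s = sum(a[i] * f[i, j] for i in range(n))
                b[j] = D[j] / s if s > 0 else 0.0
        if max(np.abs(a - olda).max(), np.abs(b - oldb).max()) < tol:
            break
    return a, b


class TestConstrainedGravity:
    def test_margin_matching_seed_gives_unit_factors(self):
        d = toy_districts([100, 200, 400], [(0, 0), (30, 0), (0, 40)])
        params = GravityParams(1.0, 1.0, 1.5, -3.0)
        od = _od_from(d)
        od["trips"] = gravity_predict(params, od)
        cf = fit_constrained_gravity(od, "production", params=params)
        # factors absorb the origin term pop_i^alpha * k; ratio across origins
        # must be flat when predictions already match the margins
        expect = np.exp(params.log_k) * d.set_index("district_id")["population"] ** params.alpha
        ratio = cf.a_i / expect.reindex(cf.a_i.index)
        assert np.allclose(ratio, ratio.iloc[0])

    def test_matches_brute_force_ipf_3x3(self):
        rng = np.random.default_rng(8)
        d = toy_districts([120, 260, 410], [(0, 0), (25, 5), (10, 35)])
        od = _od_from(d, trips=rng.integers(1, 60, size=6))
        params = GravityParams(1.0, 1.0, 1.2, -2.0)
        for variant in ("production", "attraction", "doubly"):
            cf = fit_constrained_gravity(od, variant, params=params, tol=1e-12)
            # rebuild the kernel exactly as documented
            dist = _dist(d)
            pop = d["population"].to_numpy(dtype=float)
            f = np.where(np.eye(3, dtype=bool), 0.0, 1.0 / np.where(dist == 0, 1, dist) ** params.gamma)
            if variant == "production":
                f = f * pop[None, :] ** params.beta
            elif variant == "attraction":
                f = f * pop[:, None] ** params.alpha
            obs = od.pivot(index="origin_id", columns="dest_id", values="trips").fillna(0).to_numpy(dtype=float)
            a, b = _brute_force_ipf(obs, f, variant)
            pred_oracle = a[:, None] * b[None, :] * f
            got = cf.predictions.pivot(index="origin_id", columns="dest_id", values="predicted").fillna(0).to_numpy()
            np.testing.assert_allclose(got, pred_oracle, rtol=1e-6, atol=1e-9)

    def test_doubly_constrained_margins_match(self, small_od):
        cf = fit_constrained_gravity(small_od, "doubly")
        pred = small_od[["origin_id", "dest_id"]].copy()
        pred["p"] = cf.predictions["predicted"].to_numpy()
        obs_o = small_od.groupby("origin_id")["trips"].sum()
        got_o = pred.groupby("origin_id")["p"].sum()
        pos = obs_o > 0
        assert np.all(np.abs(got_o[pos] - obs_o[pos]) / obs_o[pos] < 1e-6)
        obs_d = small_od.groupby("dest_id")["trips"].sum()
        got_d = pred.groupby("dest_id")["p"].sum()
        pos = obs_d > 0
        assert np.all(np.abs(got_d[pos] - obs_d[pos]) / obs_d[pos] < 1e-6)

    def test_constrained_margins_never_worse_than_unconstrained(self, small_od):
        p = fit_gravity(small_od)
        pred_u = gravity_predict(p, small_od)
        obs_o = small_od.groupby("origin_id")["trips"].sum()
        err_u = np.abs(small_od.assign(p=pred_u).groupby("origin_id")["p"].sum() - obs_o).sum()
        cf = fit_constrained_gravity(small_od, "production", params=p)
        err_c = np.abs(
            small_od.assign(p=cf.predictions["predicted"].to_numpy()).groupby("origin_id")["p"].sum() - obs_o
        ).sum()
        assert err_c <= err_u + 1e-9


class TestCirclePopulations:
    def test_two_districts_zero(self):
        d = toy_districts([10, 20], [(0, 0), (3, 4)])
        s = circle_populations(d, _dist(d))
        assert s[0, 1] == 0 and s[1, 0] == 0

    def test_farthest_destination_full_circle(self, small_world):
        d, dist = small_world
        s = circle_populations(d, dist)
        pop = d["population"].to_numpy(dtype=float)
        total = pop.sum()
        for i in range(len(d)):
            j = int(np.nanargmax(np.where(np.arange(len(d)) == i, np.nan, dist[i])))
            assert s[i, j] == pytest.approx(total - pop[i] - pop[j])

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        d = toy_districts(rng.integers(50, 5000, size=6).tolist(), rng.uniform(0, 100, size=(6, 2)))
        dist = _dist(d)
        s = circle_populations(d, dist)
        pop = d["population"].to_numpy(dtype=float)
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                expect = sum(
                    pop[k] for k in range(6) if k not in (i, j) and dist[i, k] < dist[i, j]
                )
                assert s[i, j] == pytest.approx(expect)

    def test_permutation_equivariance(self, small_world):
        d, dist = small_world
        s = circle_populations(d, dist)
        perm = np.random.default_rng(1).permutation(len(d))
        s_p = circle_populations(d.iloc[perm].reset_index(drop=True), dist[np.ix_(perm, perm)])
        np.testing.assert_allclose(s_p, s[np.ix_(perm, perm)])


class TestRadiation:
    def test_two_district_collapse(self):
        d = toy_districts([100, 300], [(0, 0), (3, 4)])
        s = circle_populations(d, _dist(d))
        mu = radiation_predict(d, s, tct=1.0)
        # s=0: <N_01> = pop0 * pop0*pop1 / (pop0 * (pop0+pop1)) = pop0*pop1/(pop0+pop1)
        assert mu[0, 1] == pytest.approx(100 * 300 / 400)
        assert mu[1, 0] == pytest.approx(300 * 100 / 400)

    def test_row_sum_telescoping_identity(self, small_world):
        d, dist = small_world
        pop = d["population"].to_numpy(dtype=float)
        M = pop.sum()
        mu = radiation_predict(d, circle_populations(d, dist), tct=1.0)
        rows = np.nansum(mu, axis=1)
        expect = pop * (1 - pop / M)
        assert np.all(np.abs(rows - expect) / expect < 1e-10)

    def test_matches_printed_formula_brute_force(self):
        rng = np.random.default_rng(9)
        d = toy_districts(rng.integers(100, 9000, size=8).tolist(), rng.uniform(0, 200, size=(8, 2)))
        dist = _dist(d)
        s = circle_populations(d, dist)
        tct = 0.6
        mu = radiation_predict(d, s, tct=tct)
        pop = d["population"].to_numpy(dtype=float)
        for i in range(8):
            for j in range(8):
                if i == j:
                    continue
                ni = pop[i] * tct
                expect = ni * pop[i] * pop[j] / ((pop[i] + s[i, j]) * (pop[i] + pop[j] + s[i, j]))
                assert mu[i, j] == pytest.approx(expect)


class TestFitRadiationFraction:
    def test_recovers_planted_fraction(self, small_world):
        d, dist = small_world
        base = radiation_predict(d, circle_populations(d, dist), tct=1.0)
        od = _od_from(d)
        idx = pd.Index(d["district_id"])
        oi = idx.get_indexer(od["origin_id"])
        dj = idx.get_indexer(od["dest_id"])
        od["trips"] = 0.4 * base[oi, dj]
        spec = fit_radiation_fraction(od, d, dist)
        assert spec.tct == pytest.approx(0.4, abs=0.001)
        assert spec.tct_linear == pytest.approx(0.4, abs=1e-6)

    def test_boundary_clamp_when_observed_exceeds_predictions(self, small_world):
        d, dist = small_world
        base = radiation_predict(d, circle_populations(d, dist), tct=1.0)
        od = _od_from(d)
        idx = pd.Index(d["district_id"])
        od["trips"] = 2.0 * 0.5 * base[idx.get_indexer(od["origin_id"]), idx.get_indexer(od["dest_id"])]
        spec = fit_radiation_fraction(od, d, dist)
        assert spec.tct == pytest.approx(1.0)

    def test_all_zero_observed_is_an_error(self, small_world):
        d, dist = small_world
        od = _od_from(d, trips=0)
        with pytest.raises(ValueError, match="zero"):
            fit_radiation_fraction(od, d, dist)


class TestGravityFactor:
    def test_arithmetic(self):
        d = toy_districts([1000, 2000], [(0, 0), (10, 0)])
        gm = gravity_factor(_od_from(d))
        assert np.allclose(gm, 2e5)

    def test_symmetric_and_monotone(self, small_od):
        gm = gravity_factor(small_od)
        tab = small_od.assign(gm=gm).set_index(["origin_id", "dest_id"])["gm"]
        for (i, j), v in tab.sample(30, random_state=0).items():
            assert v == pytest.approx(tab[(j, i)])
        od2 = small_od.copy()
        od2["pop_orig"] *= 2
        assert np.all(gravity_factor(od2) > gm)
        od3 = small_od.copy()
        od3["dist_euclid_km"] *= 2
        assert np.all(gravity_factor(od3) < gm)
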