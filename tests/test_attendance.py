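import itertools

import numpy as np
import pytest
import scipy.special

import agrichoice as ac
from agrichoice.attendance import (
    AttendanceStructure,
    CapacityError,
    EAAParameters,
    eaa_loglik,
    enumerate_attendance_sets,
    fit_eaa,
    fit_joint_exclusion,
)
from agrichoice.data import default_scheme
from agrichoice.mnl import fit_mnl, grouped_design, mnl_loglik, null_loglik
from agrichoice.simulate import AttendanceSpec, SimulationConfig, eaa_config


def eaa_sim(seed, pi_ignore, n_resp=300, n_plots=320, blocks=()):
    cfg = eaa_config(
        seed=seed, n_respondents=n_resp, n_plots=n_plots,
        attendance_spec=AttendanceSpec(pi_ignore=pi_ignore, blocks=tuple(blocks)),
    )
    ds = ac.simulate_choices_eaa(cfg)
    return grouped_design(ds)


def brute_force_eaa_loglik(beta, gamma, structure, gd):
    """Independent oracle: explicit subset enumeration with plain loops."""
    pis = scipy.special.expit(gamma)
    col_idx = {c: i for i, c in enumerate(structure.columns)}
    total = 0.0
    for n in range(gd.n_units):
        unit_sum = 0.0
        for attend in itertools.product((0, 1), repeat=structure.n_free):
            prior = 1.0
            mask = np.zeros(len(structure.columns))
            for c in structure.always:
                mask[col_idx[c]] = 1.0
            for f, on in enumerate(attend):
                prior *= pis[f] if on else 1.0 - pis[f]
                if on:
                    for c in structure.free[f]:
                        mask[col_idx[c]] = 1.0
            prod = 1.0
            for g in np.flatnonzero(gd.unit_of_group == n):
                rows = slice(gd.group_ptr[g], gd.group_ptr[g + 1])
                u = gd.X[rows] @ (beta * mask)
                p = np.exp(u) / np.exp(u).sum()
                prod *= p[gd.chosen[rows]][0]
            unit_sum += prior * prod
        total += np.log(unit_sum)
    return total


class TestAttendanceStructure:
    def test_partition_enforced(self, scheme):
        cols = scheme.design_columns
        with pytest.raises(ValueError, match="partition"):
            AttendanceStructure(columns=cols, always=(), free=((cols[0],),))

    def test_capacity_cap(self):
        cols = tuple(f"c{i}" for i in range(20))
        with pytest.raises(CapacityError):
            AttendanceStructure(
                columns=cols, free=tuple((c,) for c in cols)
            )

    def test_joint_block_cannot_cover_all(self):
        cols = ("a", "b")
        with pytest.raises(ValueError, match="every design column"):
            AttendanceStructure.joint_block(cols, cols)


class TestEnumerateAttendanceSets:
    def structure2(self):
        return AttendanceStructure(
            columns=("x", "y"), free=(("x",), ("y",))
        )

    def test_half_probabilities(self):
        params = EAAParameters(
            beta=np.zeros(2), gamma=np.zeros(2), structure=self.structure2()
        )
        sets = enumerate_attendance_sets(params)
        assert len(sets) == 4
        assert all(p == pytest.approx(0.25) for _, p in sets)

    def test_always_attended_in_every_subset(self):
        st = AttendanceStructure(
            columns=("x", "y"), always=("x",), free=(("y",),)
        )
        params = EAAParameters(beta=np.zeros(2), gamma=np.zeros(1), structure=st)
        sets = enumerate_attendance_sets(params)
        assert all("x" in cols for cols, _ in sets)

    def test_64_subsets_sum_to_one(self):
        cols = tuple(f"c{i}" for i in range(6))
        st = AttendanceStructure(columns=cols, free=tuple((c,) for c in cols))
        rng = np.random.default_rng(0)
        params = EAAParameters(
            beta=np.zeros(6), gamma=rng.normal(size=6), structure=st
        )
        sets = enumerate_attendance_sets(params)
        assert len(sets) == 64
        assert sum(p for _, p in sets) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_priors_sum_to_one_any_gamma(self, seed):
        rng = np.random.default_rng(seed)
        st = self.structure2()
        params = EAAParameters(
            beta=np.zeros(2), gamma=rng.normal(scale=4, size=2), structure=st
        )
        total = sum(p for _, p in enumerate_attendance_sets(params))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestEAALoglik:
    def test_full_attendance_equals_mnl(self):
        gd = eaa_sim(0, {"conservation": 0.5}, n_resp=30, n_plots=33)
        st = AttendanceStructure.individual(gd.columns)
        rng = np.random.default_rng(1)
        beta = rng.normal(scale=0.4, size=gd.p)
        params = EAAParameters(
            beta=beta, gamma=np.full(st.n_free, np.inf), structure=st
        )
        ll = eaa_loglik(params, gd)
        ll_mnl, _ = mnl_loglik(beta, gd)
        assert ll == pytest.approx(ll_mnl, abs=1e-10)

    def test_no_attendance_is_uniform(self):
        gd = eaa_sim(2, {"conservation": 0.5}, n_resp=20, n_plots=22)
        st = AttendanceStructure.individual(gd.columns)
        beta = np.random.default_rng(3).normal(size=gd.p)
        params = EAAParameters(
            beta=beta, gamma=np.full(st.n_free, -np.inf), structure=st
        )
        assert eaa_loglik(params, gd) == pytest.approx(null_loglik(gd), abs=1e-10)

    def test_brute_force_oracle(self):
        # 3 free components, 3 units
        gd = eaa_sim(4, {"conservation": 0.6}, n_resp=3, n_plots=3)
        st = AttendanceStructure(
            columns=gd.columns,
            always=tuple(c for c in gd.columns
                         if c not in ("restoration", "benefits", "conservation")),
            free=(("restoration",), ("benefits",), ("conservation",)),
        )
        rng = np.random.default_rng(5)
        for _ in range(5):
            beta = rng.normal(scale=0.5, size=gd.p)
            gamma = rng.normal(scale=1.0, size=3)
            params = EAAParameters(beta=beta, gamma=gamma, structure=st)
            ll = eaa_loglik(params, gd)
            oracle = brute_force_eaa_loglik(beta, gamma, st, gd)
            assert ll == pytest.approx(oracle, abs=1e-10)

    def test_gradient_matches_finite_differences(self):
        from agrichoice.attendance import _eaa_ll_grad
        from agrichoice.latent import _unit_ptr

        gd = eaa_sim(6, {"conservation": 0.6}, n_resp=12, n_plots=13)
        st = AttendanceStructure.individual(gd.columns)
        uptr = _unit_ptr(gd)
        rng = np.random.default_rng(7)
        beta = rng.normal(scale=0.3, size=gd.p)
        gamma = rng.normal(scale=0.5, size=st.n_free)
        ll, grad = _eaa_ll_grad(beta, gamma, st, gd, uptr)
        theta = np.concatenate([beta, gamma])
        h = 1e-6
        for j in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            lp, _ = _eaa_ll_grad(tp[: gd.p], tp[gd.p :], st, gd, uptr, want_grad=False)
            lm, _ = _eaa_ll_grad(tm[: gd.p], tm[gd.p :], st, gd, uptr, want_grad=False)
            assert grad[j] == pytest.approx((lp - lm) / (2 * h), rel=1e-4, abs=1e-5)


class TestFitEAA:
    def test_single_attribute_ana_recovery(self):
        # strong attribute ignored 85% of the time, n = 1,500 units
        cfg = eaa_config(
            seed=8, n_respondents=1400, n_plots=1500, n_situations=6,
            attendance_spec=AttendanceSpec(pi_ignore={"conservation": 0.85}),
        )
        ds = ac.simulate_choices_eaa(cfg)
        gd = grouped_design(ds)
        st = AttendanceStructure.joint_block(gd.columns, ("conservation",))
        fit = fit_eaa(gd, st, seed=0, n_starts=2)
        assert abs(fit.ana_probs["conservation"] - 0.85) < 0.07

    def test_full_attendance_data_low_ana(self):
        gd = eaa_sim(9, {}, n_resp=600, n_plots=640)
        st = AttendanceStructure(
            columns=gd.columns,
            always=tuple(c for c in gd.columns
                         if c not in ("conservation", "benefits", "restoration")),
            free=(("conservation",), ("benefits",), ("restoration",)),
        )
        fit = fit_eaa(gd, st, seed=0, n_starts=2)
        assert all(v < 0.1 for v in fit.ana_probs.values())

    def test_seeded_rerun_identical(self):
        gd = eaa_sim(10, {"conservation": 0.5}, n_resp=60, n_plots=66)
        st = AttendanceStructure.joint_block(gd.columns, ("conservation",))
        f1 = fit_eaa(gd, st, seed=4, n_starts=2)
        f2 = fit_eaa(gd, st, seed=4, n_starts=2)
        assert f1.loglik == f2.loglik

    def test_ll_at_least_mnl_embedded_start(self):
        gd = eaa_sim(11, {"conservation": 0.6}, n_resp=80, n_plots=88)
        st = AttendanceStructure.joint_block(gd.columns, ("conservation",))
        fit = fit_eaa(gd, st, seed=0, n_starts=1)
        assert fit.loglik >= fit.start_loglik - 1e-8

    def test_order_invariance(self):
        gd = eaa_sim(12, {"conservation": 0.6, "benefits": 0.3},
                     n_resp=100, n_plots=110)
        others = tuple(c for c in gd.columns
                       if c not in ("conservation", "benefits"))
        st1 = AttendanceStructure(columns=gd.columns, always=others,
                                  free=(("conservation",), ("benefits",)))
        st2 = AttendanceStructure(columns=gd.columns, always=others,
                                  free=(("benefits",), ("conservation",)))
        f1 = fit_eaa(gd, st1, seed=0, n_starts=1)
        f2 = fit_eaa(gd, st2, seed=0, n_starts=1)
        for name in ("conservation", "benefits"):
            assert f1.ana_probs[name] == pytest.approx(f2.ana_probs[name], abs=1e-4)

    def test_ana_probs_in_unit_interval(self):
        gd = eaa_sim(13, {"conservation": 0.5}, n_resp=50, n_plots=55)
        st = AttendanceStructure.joint_block(gd.columns, ("conservation",))
        fit = fit_eaa(gd, st, seed=0, n_starts=1)
        assert all(0.0 <= v <= 1.0 for v in fit.ana_probs.values())


class TestJointExclusion:
    def test_block_recovery(self):
        gd = eaa_sim(
            14, {}, n_resp=1100, n_plots=1200,
            blocks=((("conservation", "maintenance"), 0.6),),
        )
        fit = fit_joint_exclusion(gd, ("conservation", "maintenance"), seed=0)
        block_name = "conservation+maintenance"
        assert abs(fit.ana_probs[block_name] - 0.6) < 0.08

    def test_zero_exclusion_equals_mnl(self):
        gd = eaa_sim(15, {"conservation": 0.5}, n_resp=50, n_plots=55)
        fit = fit_joint_exclusion(
            gd, ("conservation", "maintenance"), seed=0, exclusion_prob=0.0
        )
        base = fit_mnl(gd)
        assert fit.loglik == pytest.approx(base.loglik, abs=1e-6)

    def test_reported_probability_in_unit_interval(self):
        gd = eaa_sim(16, {}, n_resp=40, n_plots=44,
                     blocks=((("conservation", "maintenance"), 0.5),))
        fit = fit_joint_exclusion(gd, ("conservation", "maintenance"), seed=1)
        p = fit.ana_probs["conservation+maintenance"]
        assert 0.0 <= p <= 1.0
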