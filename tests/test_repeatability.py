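import itertools
import math

import numpy as np
import pytest

from habrep import (
    BehaviorTable,
    ModelSpec,
    ResamplingSettings,
    SettingsError,
    SyntheticConfig,
    adjusted_repeatability,
    bootstrap_ci,
    fit_vc_lmm,
    generate,
    lrt,
    permutation_test,
    point_repeatability,
    rpt,
)

from conftest import make_table, one_way_table, random_one_way


def multi_factor_table(seed=0, n_animals=20, n_days=4):
    """Small crossed layout with animal, strain and batch variance."""
    rng = np.random.default_rng(seed)
    rows = []
    strains = ["s1", "s2"]
    strain_fx = {s: rng.normal(0, 1.5) for s in strains}
    batch_fx = {"e1": rng.normal(0, 1.0), "e2": rng.normal(0, 1.0)}
    for i in range(n_animals):
        strain = strains[i % 2]
        batch = "e1" if i < n_animals // 2 else "e2"
        a = rng.normal(0, 2.0)
        for d in range(1, n_days + 1):
            rows.append((f"a{i}", strain, batch, d, "m",
                         float(10 + a + strain_fx[strain] + batch_fx[batch]
                               + rng.normal())))
    return make_table(rows)


class TestPointRepeatability:
    def test_textbook_ratio(self):
        table = one_way_table([(0, 1), (10, 11), (20, 21)])
        fit = fit_vc_lmm(table, ModelSpec("m", ("animal_id",)))
        assert point_repeatability(fit, "animal_id") == pytest.approx(
            99.75 / 100.25, rel=1e-6)

    def test_boundary_component_gives_zero(self):
        table = one_way_table([(0, 2), (0, 2), (0, 2)])
        fit = fit_vc_lmm(table, ModelSpec("m", ("animal_id",)))
        assert point_repeatability(fit, "animal_id") == 0.0

    def test_unknown_factor_raises(self):
        fit = fit_vc_lmm(one_way_table([(0, 1), (2, 3)]),
                         ModelSpec("m", ("animal_id",)))
        with pytest.raises(KeyError):
            point_repeatability(fit, "strain")

    def test_shares_sum_below_one(self, study_table):
        table, _ = study_table
        fit = fit_vc_lmm(table, ModelSpec(
            "distance_cm", ("animal_id", "strain", "experiment")))
        total = sum(point_repeatability(fit, f)
                    for f in ("animal_id", "strain", "experiment"))
        assert 0.0 <= total <= 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        table = random_one_way(rng, 8, 4, sd_group=2.0, sd_resid=1.0)
        scaled = table.data.copy()
        scaled["value"] = -3.0 * scaled["value"] + 7.0
        spec = ModelSpec("m", ("animal_id",))
        r1 = point_repeatability(fit_vc_lmm(table, spec), "animal_id")
        r2 = point_repeatability(fit_vc_lmm(BehaviorTable(scaled), spec), "animal_id")
        assert r2 == pytest.approx(r1, abs=1e-6)


class TestLRT:
    def test_zero_statistic_gives_half(self):
        table = one_way_table([(0, 2), (0, 2), (0, 2)])
        stat, p = lrt(table, ModelSpec("m", ("animal_id",)), "animal_id")
        assert stat == 0.0
        assert p == 0.5

    def test_strong_signal_is_significant(self):
        table = one_way_table([(0, 0.1), (10, 10.1), (20, 20.1)])
        stat, p = lrt(table, ModelSpec("m", ("animal_id",)), "animal_id")
        assert stat > 10
        assert 0 < p < 1e-3

    def test_reduced_model_keeps_other_random_factors(self):
        table = multi_factor_table(seed=3)
        spec = ModelSpec("m", ("animal_id", "strain"))
        stat, p = lrt(table, spec, "animal_id")
        assert stat >= 0.0 and 0.0 < p <= 1.0


class TestPermutation:
    @staticmethod
    def _oracle_R(values):
        """Closed-form REML repeatability, balanced 2 groups x 2 replicates."""
        v = np.asarray(values, dtype=float)
        g = v.reshape(2, 2)
        grand = v.mean()
        msb = 2.0 * np.sum((g.mean(axis=1) - grand) ** 2)
        msw = np.sum((g - g.mean(axis=1, keepdims=True)) ** 2) / 2.0
        if msb > msw:
            sg, se = (msb - msw) / 2.0, msw
        else:
            sg, se = 0.0, np.sum((v - grand) ** 2) / 3.0
        return sg / (sg + se)

    @pytest.mark.parametrize("values", [
        (0.3, 1.7, 5.2, 6.9),
        (2.0, 2.6, 1.1, 7.3),
        (-1.0, 4.0, 3.5, 3.8),
    ])
    def test_matches_exhaustive_enumeration(self, values):
        """4 observations in 2 groups: all 4! residual permutations enumerated."""
        rows = [(f"g{i // 2}", "s", "e", i % 2 + 1, "m", float(v))
                for i, v in enumerate(values)]
        table = make_table(rows)
        spec = ModelSpec("m", ("animal_id",))
        p_impl = permutation_test(table, spec, "animal_id",
                                  ResamplingSettings(n_permut=100, seed=0))

        v = np.asarray(values, dtype=float)
        r_obs = self._oracle_R(v)
        resid = v - v.mean()
        count = sum(
            self._oracle_R(v.mean() + resid[list(perm)]) >= r_obs - 1e-9
            for perm in itertools.permutations(range(4)))
        assert p_impl == count / math.factorial(4)

    def test_separated_groups_hit_the_floor(self):
        rng = np.random.default_rng(0)
        table = one_way_table([100 * g + rng.normal(0, 0.1, size=4)
                               for g in range(5)])
        p = permutation_test(table, ModelSpec("m", ("animal_id",)),
                             "animal_id", ResamplingSettings(n_permut=100, seed=1))
        assert p == 1.0 / 100

    def test_null_p_values_center_on_half(self):
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(40):
            table = random_one_way(rng, 6, 3, sd_group=0.0, sd_resid=1.0)
            ps.append(permutation_test(
                table, ModelSpec("m", ("animal_id",)), "animal_id",
                ResamplingSettings(n_permut=20, seed=int(rng.integers(2 ** 31)))))
        assert 0.35 < np.mean(ps) < 0.65

    def test_rejects_tiny_n_permut(self):
        with pytest.raises(SettingsError):
            permutation_test(one_way_table([(0, 1), (2, 3)]),
                             ModelSpec("m", ("animal_id",)), "animal_id",
                             ResamplingSettings(n_permut=1, seed=0))


class TestBootstrap:
    def test_null_data_pile_up_at_zero(self):
        rng = np.random.default_rng(3)
        table = random_one_way(rng, 10, 4, sd_group=0.0, sd_resid=1.0)
        lo, hi = bootstrap_ci(table, ModelSpec("m", ("animal_id",)), "animal_id",
                              ResamplingSettings(n_boot=80, seed=4))
        assert lo == 0.0
        assert hi < 0.6

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        table = random_one_way(rng, 8, 3, sd_group=1.5, sd_resid=1.0)
        spec = ModelSpec("m", ("animal_id",))
        s = ResamplingSettings(n_boot=40, n_permut=10, seed=11)
        assert bootstrap_ci(table, spec, "animal_id", s) == \
            bootstrap_ci(table, spec, "animal_id", s)
        assert permutation_test(table, spec, "animal_id", s) == \
            permutation_test(table, spec, "animal_id", s)
        other = ResamplingSettings(n_boot=40, n_permut=10, seed=12)
        assert bootstrap_ci(table, spec, "animal_id", s) != \
            bootstrap_ci(table, spec, "animal_id", other)


class TestRpt:
    def test_single_factor_consistency(self, fast_settings):
        rng = np.random.default_rng(6)
        table = random_one_way(rng, 8, 4, sd_group=2.0, sd_resid=1.0)
        res = rpt(table, "m", ("animal_id",), settings=fast_settings)["animal_id"]
        fit = fit_vc_lmm(table, ModelSpec("m", ("animal_id",)))
        assert res.R == pytest.approx(point_repeatability(fit, "animal_id"), rel=1e-9)
        assert res.ci[0] <= res.R <= res.ci[1] or res.ci[0] == 0.0
        assert 0 < res.p_lrt <= 1 and 0 < res.p_permut <= 1

    def test_factor_order_invariance(self):
        table = multi_factor_table(seed=7)
        s = ResamplingSettings(n_boot=15, n_permut=5, seed=3)
        a = rpt(table, "m", ("animal_id", "strain", "experiment"), settings=s)
        b = rpt(table, "m", ("experiment", "animal_id", "strain"), settings=s)
        for f in ("animal_id", "strain", "experiment"):
            assert a[f].R == pytest.approx(b[f].R, abs=1e-7)
            assert a[f].ci == pytest.approx(b[f].ci, abs=1e-6)
            assert a[f].p_permut == b[f].p_permut

    def test_result_invariants(self, study_table):
        table, _ = study_table
        s = ResamplingSettings(n_boot=25, n_permut=5, seed=2)
        sub = table.subset("activity_pct", days=(2, 3, 4))
        res = rpt(sub, "activity_pct", ("animal_id",), settings=s)["animal_id"]
        assert 0.0 <= res.R <= 1.0
        assert 0.0 <= res.ci[0] <= res.ci[1] <= 1.0
        assert res.lrt_statistic >= 0.0
        assert res.fit.n_obs == len(sub)


class TestAdjustedRepeatability:
    def test_single_level_covariate_equals_unadjusted(self, fast_settings):
        rng = np.random.default_rng(8)
        table = random_one_way(rng, 8, 4, sd_group=2.0, sd_resid=1.0)  # strain constant
        adj = adjusted_repeatability(table, "m", "animal_id", ("strain",),
                                     settings=fast_settings)
        una = rpt(table, "m", ("animal_id",), settings=fast_settings)["animal_id"]
        assert adj.R == pytest.approx(una.R, rel=1e-9)
        assert adj.ci == pytest.approx(una.ci, abs=1e-9)

    def test_adjustment_removes_strain_variance(self, fast_settings):
        # strain shifts means only: adjusting for it as a fixed covariate
        # removes its share from the denominator relative to the multi-factor
        # decomposition, and strips it out of the conflated single-factor
        # animal component (the slight-reduction effect seen in real data)
        cfg = SyntheticConfig(measure="m", n_days=5, nu=0.0, kappa=1.0,
                              w_day1=1.0, mu=0.0, sigma_a=50.0, sigma_s=120.0,
                              sigma_b=0.0, sigma_e=60.0, seed=21)
        table, _ = generate(cfg)
        adj = adjusted_repeatability(table, "m", "animal_id", ("strain",),
                                     settings=fast_settings)
        single = fit_vc_lmm(table, ModelSpec("m", ("animal_id",)))
        multi = fit_vc_lmm(table, ModelSpec("m", ("animal_id", "strain")))
        r_single = point_repeatability(single, "animal_id")
        r_multi = point_repeatability(multi, "animal_id")
        assert adj.R >= r_multi - 1e-9       # strain share leaves the denominator
        assert adj.R <= r_single + 1e-9      # strain no longer inflates the numerator

    def test_confounded_covariate_warns(self, fast_settings):
        rows = [(f"a{i}", f"s{i}", "e", d, "m",
                 float(i * 3 + [0.0, 0.4, -0.2][d - 1]))
                for i in range(4) for d in (1, 2, 3)]
        table = make_table(rows)
        res = adjusted_repeatability(table, "m", "animal_id", ("strain",),
                                     settings=fast_settings)
        assert any("confounded" in w for w in res.warnings)
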