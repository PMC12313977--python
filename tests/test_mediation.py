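import numpy as np
import pandas as pd
import pytest

from ddmediate.mediation import (
    MediationDesign,
    MediationError,
    MediationResult,
    PathEstimates,
    bootstrap_mediation,
    classify_mediation,
    fit_paths,
    result_to_dict,
)

COVARS = ("age", "sex", "handedness", "education_years", "tiv")


def _make_table(rng, n=155, a=-0.3, b=0.4, c_prime=-0.2, sd_m=1.0, sd_y=1.0,
                tiv_scale=1.0):
    """Linear-Gaussian mediation data with O(1) or custom covariate scales."""
    x = rng.standard_normal(n)
    C = rng.standard_normal((n, 5))
    C[:, 4] *= tiv_scale
    m = a * x + 0.2 * C @ np.ones(5) / max(tiv_scale, 1) + sd_m * rng.standard_normal(n)
    y = c_prime * x + b * m + sd_y * rng.standard_normal(n)
    return pd.DataFrame(
        {"reappraisal": x, "vs_gmv": m, "log10_k": y}
        | {name: C[:, i] for i, name in enumerate(COVARS)}
    )


def _dummy_result(p_ab, p_c_prime, p_c):
    paths = PathEstimates(
        a=-0.002, b=2.047, c=-0.012, c_prime=-0.009, ab=-0.003,
        se_a=0.001, se_b=0.877, se_c=0.006, se_c_prime=0.006, se_ab=0.002,
        p_a=0.012, p_b=0.019, p_c=p_c, p_c_prime=p_c_prime, n=155,
    )
    return MediationResult(
        paths=paths, ab_boot=np.zeros(1000), ci_ab=(-0.006, -0.001),
        ci_level=0.95, p_ab=p_ab, p_a_boot=0.012, p_b_boot=0.019,
        p_c_boot=p_c, p_c_prime_boot=p_c_prime, se_ab_boot=0.002,
        n_boot=1000, seed=0, ci_method="percentile", n_redraws=0,
        covariate_names=COVARS,
    )


class TestFitPaths:
    def test_decomposition_identity_on_random_datasets(self, rng):
        design = MediationDesign()
        for _ in range(25):
            table = _make_table(rng, n=int(rng.integers(60, 200)))
            p = fit_paths(table, design)
            assert abs(p.c - (p.c_prime + p.ab)) < 1e-10

    def test_null_b_gives_null_indirect_effect(self, rng):
        table = _make_table(rng, n=20000, b=0.0)
        p = fit_paths(table, MediationDesign())
        assert abs(p.ab) < 3 * p.se_ab

    def test_mediator_rescaling_leaves_ab_unchanged(self, rng):
        table = _make_table(rng)
        design = MediationDesign()
        p0 = fit_paths(table, design)
        scaled = table.copy()
        s = 37.5
        scaled["vs_gmv"] = scaled["vs_gmv"] * s
        p1 = fit_paths(scaled, design)
        assert p1.a == pytest.approx(p0.a * s, rel=1e-9)
        assert p1.b == pytest.approx(p0.b / s, rel=1e-9)
        assert p1.ab == pytest.approx(p0.ab, rel=1e-9)

    def test_covariate_affine_rescaling_leaves_paths_unchanged(self, rng):
        table = _make_table(rng)
        design = MediationDesign()
        p0 = fit_paths(table, design)
        scaled = table.copy()
        scaled["tiv"] = scaled["tiv"] * 1.5e5 + 1.5e6
        p1 = fit_paths(scaled, design)
        for attr in ("a", "b", "c", "c_prime", "ab"):
            assert getattr(p1, attr) == pytest.approx(getattr(p0, attr), rel=1e-8)

    def test_sign_recovery_of_planted_negative_indirect_effect(self, default_cohort):
        """Study-scale planted paths at n=155 recover sign(ab) < 0 in most
        seeded replicates."""
        from ddmediate.simulate import SimulationConfig, simulate_cohort

        hits = 0
        analyzable = 0
        for i in range(100):
            cohort = simulate_cohort(SimulationConfig(seed=20_000 + i))
            try:
                p = fit_paths(cohort.cohort, MediationDesign())
            except MediationError:
                # rare cohorts draw no left-hander; the constant covariate
                # makes the design rank-deficient and unanalyzable
                continue
            analyzable += 1
            hits += p.ab < 0
        assert analyzable >= 90
        assert hits / analyzable >= 0.80

    def test_rank_deficiency_names_columns(self, rng):
        table = _make_table(rng)
        table["tiv"] = table["age"]
        with pytest.raises(MediationError, match="tiv"):
            fit_paths(table, MediationDesign())

    def test_too_small_sample_rejected(self, rng):
        table = _make_table(rng, n=155).iloc[:7]
        with pytest.raises(MediationError, match="too small"):
            fit_paths(table, MediationDesign())

    def test_design_role_overlap_rejected(self):
        with pytest.raises(MediationError):
            MediationDesign(x_name="reappraisal", m_name="vs_gmv",
                            y_name="log10_k", covariates=("vs_gmv", "age"))


@pytest.mark.filterwarnings("ignore:.*rank-deficient bootstrap.*")
class TestBootstrap:
    def test_same_seed_bit_identical(self, rng):
        table = _make_table(rng)
        design = MediationDesign()
        r1 = bootstrap_mediation(table, design, n_boot=1000, seed=5)
        r2 = bootstrap_mediation(table, design, n_boot=1000, seed=5)
        assert np.array_equal(r1.ab_boot, r2.ab_boot)
        assert result_to_dict(r1) == result_to_dict(r2)

    def test_ci_contains_point_estimate(self, rng):
        table = _make_table(rng)
        r = bootstrap_mediation(table, MediationDesign(), n_boot=2000, seed=3)
        assert r.ci_ab[0] <= r.paths.ab <= r.ci_ab[1]

    def test_duplicated_rows_same_estimate_narrower_ci(self, rng):
        table = _make_table(rng, n=120)
        design = MediationDesign()
        r1 = bootstrap_mediation(table, design, n_boot=2000, seed=3)
        doubled = pd.concat([table, table], ignore_index=True)
        r2 = bootstrap_mediation(doubled, design, n_boot=2000, seed=3)
        assert r2.paths.ab == pytest.approx(r1.paths.ab, abs=1e-12)
        assert (r2.ci_ab[1] - r2.ci_ab[0]) < (r1.ci_ab[1] - r1.ci_ab[0])

    def test_batched_solver_matches_statsmodels(self, rng):
        from ddmediate.mediation import _batched_paths, _design_matrices

        table = _make_table(rng, tiv_scale=1.5e6)
        design = MediationDesign()
        data = design.resolve(table)
        x, m, y, C, _, _ = _design_matrices(data, design)
        idx = np.arange(len(x))[None, :]
        a, b, c, cp, ok = _batched_paths(idx, x, m, y, C)
        p = fit_paths(table, design)
        assert ok[0]
        assert a[0] == pytest.approx(p.a, rel=1e-9)
        assert b[0] == pytest.approx(p.b, rel=1e-9)
        assert c[0] == pytest.approx(p.c, rel=1e-9)
        assert cp[0] == pytest.approx(p.c_prime, rel=1e-9)

    def test_strong_effect_detected(self, rng):
        table = _make_table(rng, n=300, a=-0.8, b=0.8, sd_m=0.5, sd_y=0.5)
        r = bootstrap_mediation(table, MediationDesign(), n_boot=2000, seed=1)
        assert r.p_ab < 0.01
        assert r.ci_ab[1] < 0

    def test_bc_interval_option(self, rng):
        table = _make_table(rng)
        r = bootstrap_mediation(
            table, MediationDesign(), n_boot=1000, seed=2, ci_method="bc"
        )
        assert r.ci_ab[0] < r.ci_ab[1]

    def test_too_few_iterations_rejected(self, rng):
        with pytest.raises(MediationError):
            bootstrap_mediation(_make_table(rng), MediationDesign(), n_boot=100, seed=0)


class TestClassification:
    def test_full_pattern_from_printed_significances(self):
        res = _dummy_result(p_ab=0.041, p_c_prime=0.161, p_c=0.042)
        assert classify_mediation(res, alpha=0.05).startswith("full-pattern")

    def test_non_significant_indirect_effect_is_none(self):
        res = _dummy_result(p_ab=0.5, p_c_prime=0.01, p_c=0.01)
        assert classify_mediation(res).startswith("none")

    def test_significant_direct_and_indirect_is_partial(self):
        res = _dummy_result(p_ab=0.01, p_c_prime=0.01, p_c=0.001)
        assert classify_mediation(res).startswith("partial")

    def test_label_carries_noncausal_framing(self):
        res = _dummy_result(p_ab=0.041, p_c_prime=0.161, p_c=0.042)
        assert "causal" in classify_mediation(res)
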