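"""Genotype coding, design construction, nested F, residual bootstrap, scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mireqtl import (
    BootstrapConfig,
    ContractError,
    DegenerateFitError,
    NestedOLS,
    SnpSpec,
    UntestableSnpError,
    align_cohort,
    bootstrap_null_pvalue,
    build_design,
    encode_genotype,
    f_statistic,
    group_means,
    run_scan,
)
from mireqtl.association import task_seed
from mireqtl.datamodel import CovariateTable, ExpressionMatrix, GenotypeMatrix

from conftest import make_covariates


def indicator_for(calls, model, ids=None):
    ids = ids or [f"s{i:03d}" for i in range(len(calls))]
    return encode_genotype(pd.Series(calls, index=ids, dtype=float, name="rs1"), model)


class TestEncodeGenotype:
    def test_dominant_pools_carriers(self):
        ind = indicator_for([0, 1, 2], "dominant")
        assert ind.g.tolist() == [0, 1, 1]
        assert (ind.n_ref, ind.n_var) == (1, 2)

    def test_recessive_pools_variant_homozygotes(self):
        ind = indicator_for([0, 1, 2], "recessive")
        assert ind.g.tolist() == [0, 0, 1]

    def test_missing_calls_excluded(self):
        ind = indicator_for([0, np.nan, 2, 1], "dominant")
        assert list(ind.g.index) == ["s000", "s002", "s003"]

    def test_monomorphic_is_untestable(self):
        with pytest.raises(UntestableSnpError):
            indicator_for([0, 0, 0, 0], "dominant")
        with pytest.raises(UntestableSnpError):
            indicator_for([0, 1, 1, 0], "recessive")  # no homozygous variant

    def test_bad_call_rejected(self):
        with pytest.raises(ContractError):
            indicator_for([0, 3], "dominant")


class TestBuildDesign:
    def test_dummy_count_arithmetic(self, rng):
        cov = make_covariates(100, rng)  # 2 sexes, 3 races
        ind = indicator_for(rng.binomial(2, 0.4, 100), "dominant",
                            ids=list(cov.index))
        designs = build_design(cov, ind)
        assert designs.X_null.shape == (100, 5)  # 1 + age + sex + 2 race
        assert designs.X_full.shape == (100, 6)

    def test_single_level_contributes_no_column(self, rng):
        cov = make_covariates(50, rng)
        cov["race"] = "white"
        ind = indicator_for(rng.binomial(2, 0.4, 50), "dominant",
                            ids=list(cov.index))
        designs = build_design(cov, ind)
        assert not any(c.startswith("race") for c in designs.null_columns)

    def test_permutation_invariance_of_f(self, rng):
        cov = make_covariates(60, rng)
        calls = rng.binomial(2, 0.4, 60)
        y = rng.normal(size=60)
        ind = indicator_for(calls, "dominant", ids=list(cov.index))
        f1 = f_statistic(y, build_design(cov, ind))
        perm = rng.permutation(60)
        ids_p = [list(cov.index)[i] for i in perm]
        ind_p = encode_genotype(pd.Series(calls[perm], index=ids_p, dtype=float),
                                "dominant")
        f2 = f_statistic(y[perm], build_design(cov.loc[ids_p], ind_p))
        assert f1 == pytest.approx(f2, rel=1e-9)


class TestFStatistic:
    def test_zero_when_y_in_null_space(self, rng):
        cov = make_covariates(40, rng)
        ind = indicator_for(rng.binomial(2, 0.4, 40), "dominant",
                            ids=list(cov.index))
        designs = build_design(cov, ind)
        y = cov["age"].to_numpy() + 3.0  # linear in the null design
        assert f_statistic(y, designs) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_separation_is_degenerate(self, rng):
        cov = make_covariates(40, rng)
        ind = indicator_for(rng.binomial(2, 0.4, 40), "dominant",
                            ids=list(cov.index))
        designs = build_design(cov, ind)
        with pytest.raises(DegenerateFitError):
            f_statistic(ind.g.to_numpy(dtype=float), designs)

    def test_equals_squared_t_from_statsmodels(self, rng):
        import statsmodels.api as sm

        cov = make_covariates(60, rng)
        ind = indicator_for(rng.binomial(2, 0.4, 60), "dominant",
                            ids=list(cov.index))
        designs = build_design(cov, ind)
        y = rng.normal(size=60)
        fit = sm.OLS(y, designs.X_full).fit()
        assert f_statistic(y, designs) == pytest.approx(
            float(fit.tvalues[-1] ** 2), rel=1e-8)

    @given(a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
           b0=st.floats(-10, 10), b1=st.floats(-2, 2))
    @settings(max_examples=20)
    def test_affine_null_space_invariance(self, a, b0, b1):
        rng = np.random.default_rng(7)
        cov = make_covariates(50, rng)
        ind = indicator_for(rng.binomial(2, 0.4, 50), "dominant",
                            ids=list(cov.index))
        designs = build_design(cov, ind)
        y = rng.normal(size=50)
        f1 = f_statistic(y, designs)
        y2 = a * y + designs.X_null @ np.array([b0, b1, 0.0, 0.0, 0.0][:designs.X_null.shape[1]])
        assert f_statistic(y2, designs) == pytest.approx(f1, rel=1e-6)


class TestBootstrap:
    def test_default_replicate_count(self):
        assert BootstrapConfig().n_reps == 10_000

    def test_huge_effect_attains_lower_bound(self, rng):
        cov = make_covariates(80, rng)
        ind = indicator_for(rng.binomial(2, 0.4, 80), "dominant",
                            ids=list(cov.index))
        designs = build_design(cov, ind)
        y = 100.0 * ind.g.to_numpy(dtype=float) + rng.normal(size=80)
        cfg = BootstrapConfig(n_reps=500)
        p, _ = bootstrap_null_pvalue(y, designs, cfg, rng=np.random.default_rng(1))
        assert p == pytest.approx(1 / 501)

    def test_p_resolution_grid(self, rng):
        cov = make_covariates(50, rng)
        ind = indicator_for(rng.binomial(2, 0.4, 50), "dominant",
                            ids=list(cov.index))
        designs = build_design(cov, ind)
        B = 199
        cfg = BootstrapConfig(n_reps=B)
        for trial in range(10):
            y = np.random.default_rng(trial).normal(size=50)
            p, _ = bootstrap_null_pvalue(y, designs, cfg,
                                         rng=np.random.default_rng(trial + 100))
            k = round(p * (B + 1))
            assert 1 <= k <= B + 1 and p == pytest.approx(k / (B + 1))

    def test_close_to_parametric_tail(self, rng):
        cov = make_covariates(60, rng)
        ind = indicator_for(rng.binomial(2, 0.3, 60), "dominant",
                            ids=list(cov.index))
        designs = build_design(cov, ind)
        engine = NestedOLS(designs)
        y = rng.normal(size=60)
        p, f_obs = bootstrap_null_pvalue(y, designs, BootstrapConfig(n_reps=10_000),
                                         rng=np.random.default_rng(5), engine=engine)
        p_param = stats.f.sf(f_obs, 1, engine.dof)
        assert p == pytest.approx(p_param, abs=3 * np.sqrt(p_param * (1 - p_param) / 10_000) + 1e-6)

    def test_leverage_scheme_also_calibrated(self, rng):
        cov = make_covariates(60, rng)
        ind = indicator_for(rng.binomial(2, 0.3, 60), "dominant",
                            ids=list(cov.index))
        designs = build_design(cov, ind)
        y = rng.normal(size=60)
        cfg = BootstrapConfig(n_reps=2000, residual_scheme="leverage")
        p, f_obs = bootstrap_null_pvalue(y, designs, cfg, rng=np.random.default_rng(6))
        p_param = stats.f.sf(f_obs, 1, NestedOLS(designs).dof)
        assert abs(p - p_param) < 0.05


class TestGroupMeans:
    @pytest.mark.parametrize("mean_ref,mean_var,expected", [
        (3.21, 2.25, "Downregulated"),
        (0.64, 0.80, "Upregulated"),
    ])
    def test_direction_from_printed_examples(self, mean_ref, mean_var, expected):
        vals = pd.Series([mean_ref, mean_ref, mean_var, mean_var],
                         index=["a", "b", "c", "d"])
        ind = encode_genotype(pd.Series([0, 0, 1, 2], index=list("abcd"),
                                        dtype=float), "dominant")
        got_ref, got_var, direction = group_means(vals, ind)
        assert (got_ref, got_var) == (pytest.approx(mean_ref), pytest.approx(mean_var))
        assert direction == expected

    def test_tie_labelled_downregulated(self):
        vals = pd.Series([1.0, 1.0], index=["a", "b"])
        ind = encode_genotype(pd.Series([0, 2], index=["a", "b"], dtype=float),
                              "dominant")
        assert group_means(vals, ind)[2] == "Downregulated"


def tiny_cohort(rng, n=80, n_probes=5, effect=None):
    """Aligned cohort with optional planted shift on probe p0 / snp rs1."""
    cov_frame = make_covariates(n, rng)
    ids = list(cov_frame.index)
    calls = rng.binomial(2, 0.4, n).astype(float)
    g = (calls >= 1).astype(float)
    log2 = rng.normal(5.0, 1.0, (n_probes, n))
    if effect:
        log2[0] += effect * g
    values = pd.DataFrame(2.0 ** log2, index=[f"p{i}" for i in range(n_probes)],
                          columns=ids)
    expr = ExpressionMatrix(values, "normal")
    geno = GenotypeMatrix(pd.DataFrame([calls], index=["rs1"], columns=ids))
    cohort, _ = align_cohort({"normal": expr}, geno, CovariateTable(cov_frame))
    return cohort


class TestRunScan:
    def test_no_snps_gives_empty_results(self, rng):
        cohort = tiny_cohort(rng)
        assert run_scan(cohort, [], "normal") == []

    def test_planted_effect_attains_minimum_p(self, rng):
        cohort = tiny_cohort(rng, n=120, n_probes=8, effect=1.5)
        specs = [SnpSpec("rs1", "geneA", "dominant")]
        res = run_scan(cohort, specs, "normal", "colorectal",
                       BootstrapConfig(n_reps=300, master_seed=3))
        best = min(res, key=lambda r: r.p_boot)
        assert best.mirna_id == "p0"
        assert best.p_boot == min(r.p_boot for r in res)

    def test_deterministic_given_master_seed(self, rng):
        cohort = tiny_cohort(rng, n=60)
        specs = [SnpSpec("rs1", "geneA", "dominant")]
        r1 = run_scan(cohort, specs, config=BootstrapConfig(n_reps=200, master_seed=9))
        r2 = run_scan(cohort, specs, config=BootstrapConfig(n_reps=200, master_seed=9))
        assert [(a.p_boot, a.f_obs) for a in r1] == [(b.p_boot, b.f_obs) for b in r2]

    def test_task_seed_stable_across_order(self):
        s1 = task_seed(3, "rs1", "miR-1", "colon", "normal")
        s2 = task_seed(3, "rs1", "miR-1", "colon", "normal")
        s3 = task_seed(3, "rs1", "miR-2", "colon", "normal")
        assert s1.entropy == s2.entropy and s1.entropy != s3.entropy

    def test_monomorphic_snp_skipped_not_fatal(self, rng):
        cohort = tiny_cohort(rng, n=50)
        mono = pd.DataFrame([np.zeros(50)], index=["rs_mono"],
                            columns=cohort.genotypes.sample_ids)
        cohort.genotypes.calls = pd.concat([cohort.genotypes.calls, mono])
        specs = [SnpSpec("rs_mono", "geneB", "dominant"),
                 SnpSpec("rs1", "geneA", "dominant")]
        res = run_scan(cohort, specs, config=BootstrapConfig(n_reps=100))
        assert {r.snp_id for r in res} == {"rs1"}
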