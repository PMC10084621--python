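import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from candigene import de
from candigene.io import ValidationError


def nb_counts(rng, G, n, mu=100.0, phi=0.2):
    r = 1 / phi
    arr = rng.negative_binomial(r, r / (r + mu), size=(G, n))
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(G)],
                        columns=[f"s{j}" for j in range(n)])


class TestFilter:
    def test_all_zero_gene_removed(self):
        counts = pd.DataFrame({"a": [0, 100], "b": [0, 120]}, index=["z", "g"])
        groups = pd.Series(["x", "y"], index=["a", "b"])
        out = de.filter_low_expression(counts, min_samples=1)
        assert list(out.index) == ["g"]

    def test_cpm_arithmetic(self):
        # 100 counts in a library of 1e6 is exactly 100 CPM > 1
        counts = pd.DataFrame(
            {"a": [100, 999900], "b": [100, 999900]}, index=["g", "rest"])
        out = de.filter_low_expression(counts, min_samples=2, min_cpm=1.0)
        assert "g" in out.index

    def test_min_cpm_zero_keeps_everything_nonzero(self):
        counts = pd.DataFrame({"a": [1, 0, 50], "b": [0, 0, 60]},
                              index=["low", "zero", "g"])
        out = de.filter_low_expression(counts, min_samples=1, min_cpm=0.0)
        assert "zero" not in out.index and "low" in out.index

    def test_empty_result_advises(self):
        counts = pd.DataFrame({"a": [0], "b": [0]}, index=["z"])
        with pytest.raises(ValidationError, match="min_cpm"):
            de.filter_low_expression(counts, min_samples=1)


class TestTmm:
    def test_identical_columns_unit_factors(self, rng):
        counts = nb_counts(rng, 500, 1)
        counts = pd.concat([counts] * 4, axis=1)
        counts.columns = list("abcd")
        f = de.tmm_factors(counts)
        np.testing.assert_allclose(f.tmm, 1.0, atol=1e-12)

    def test_pure_depth_difference_absorbed_by_library_size(self, rng):
        counts = nb_counts(rng, 2000, 1, mu=200)
        counts["b"] = counts["s0"] * 2
        counts = counts.rename(columns={"s0": "a"})
        f = de.tmm_factors(counts)
        np.testing.assert_allclose(f.tmm, 1.0, atol=0.02)
        assert np.exp(np.mean(np.log(f.tmm))) == pytest.approx(1.0, abs=1e-8)

    def test_contaminated_sample_factor_matches_direct_recomputation(self, rng):
        """One sample carries 10% high-count contaminant genes; its factor
        must drop below 1 and agree with an independent recomputation of the
        doubly-trimmed weighted mean of M-values."""
        counts = nb_counts(rng, 1000, 3, mu=100, phi=0.1)
        contaminated = counts.copy()
        contaminated.iloc[:100, 2] += 2000  # composition shift in sample s2
        f = de.tmm_factors(contaminated)
        assert f.tmm["s2"] < 1.0

        # independent recomputation (same definition, separate code path)
        lib = contaminated.sum(0).astype(float)
        rel = contaminated.to_numpy(float) / lib.to_numpy()
        uq = np.quantile(np.where(rel > 0, rel, np.nan), 0.75, axis=0)
        ref = int(np.argmin(np.abs(np.nan_to_num(uq) - np.nan_to_num(uq).mean())))
        j = 2
        ok = (rel[:, j] > 0) & (rel[:, ref] > 0)
        m = np.log2(rel[ok, j] / rel[ok, ref])
        a = 0.5 * np.log2(rel[ok, j] * rel[ok, ref])
        yj = contaminated.iloc[:, j].to_numpy(float)[ok]
        yr = contaminated.iloc[:, ref].to_numpy(float)[ok]
        w = (lib.iloc[j] - yj) / (lib.iloc[j] * yj) + (lib.iloc[ref] - yr) / (lib.iloc[ref] * yr)
        keep = ((m >= np.quantile(m, 0.3)) & (m <= np.quantile(m, 0.7))
                & (a >= np.quantile(a, 0.05)) & (a <= np.quantile(a, 0.95)))
        raw = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
        raw_all = np.ones(3)
        raw_all[2] = raw
        expected = raw / np.exp(np.mean(np.log(raw_all)))
        assert f.tmm["s2"] == pytest.approx(expected, abs=0.02)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"a": [0, 0], "b": [1, 2]})
        with pytest.raises(ValidationError, match="zero library"):
            de.tmm_factors(counts)


@pytest.fixture(scope="module")
def null_fixture():
    rng = np.random.default_rng(77)
    counts = nb_counts(rng, 2000, 20, mu=100, phi=0.2)
    groups = pd.Series(["a"] * 10 + ["b"] * 10, index=counts.columns)
    norm = de.tmm_factors(counts)
    return counts, groups, norm


class TestDispersions:
    def test_recovers_true_dispersion(self, null_fixture):
        counts, groups, norm = null_fixture
        model = de.estimate_dispersions(counts, groups, norm)
        assert 0.15 <= model.common <= 0.25

    def test_poisson_data_gives_near_zero_dispersion(self, rng):
        arr = rng.poisson(100.0, size=(2000, 20))
        counts = pd.DataFrame(arr, columns=[f"s{j}" for j in range(20)])
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=counts.columns)
        model = de.estimate_dispersions(counts, groups, de.tmm_factors(counts))
        assert model.common < 0.01

    def test_infinite_prior_collapses_to_common(self, null_fixture):
        counts, groups, norm = null_fixture
        model = de.estimate_dispersions(counts, groups, norm, prior_df=np.inf)
        assert (model.tagwise == model.common).all()

    def test_single_sample_group_rejected(self, rng):
        counts = nb_counts(rng, 50, 3)
        groups = pd.Series(["a", "a", "b"], index=counts.columns)
        with pytest.raises(ValidationError, match="2 samples"):
            de.estimate_dispersions(counts, groups, de.tmm_factors(counts))


def oracle_exact_p(y1, y2, n1, n2, phi):
    """Independent enumeration of the conditional NB two-group split using the
    explicit log-gamma pmf (no scipy distribution objects)."""
    t = y1 + y2
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)

    def log_nb(k, r, m):
        return (gammaln(k + r) - gammaln(r) - gammaln(k + 1)
                + r * np.log(r / (r + m)) + k * np.log(m / (r + m)))

    k = np.arange(t + 1)
    r1, r2 = n1 / phi, n2 / phi
    lp = log_nb(k, r1, n1 * mu) + log_nb(t - k, r2, n2 * mu)
    lp = lp - np.logaddexp.reduce(lp)
    mass = np.exp(lp)
    return float(min(mass[mass <= mass[y1] * (1 + 1e-12)].sum(), 1.0))


class TestExactTest:
    def test_agrees_with_enumeration_oracle(self, rng):
        """Conditional p-values match an independent full enumeration for
        totals up to 200 at 1e-10."""
        for _ in range(60):
            n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            t = int(rng.integers(1, 201))
            y1 = int(rng.integers(0, t + 1))
            phi = float(rng.uniform(0.01, 1.0))
            ours = de.exact_nb_pvalue(y1, t - y1, n1, n2, phi)
            assert ours == pytest.approx(oracle_exact_p(y1, t - y1, n1, n2, phi),
                                         abs=1e-10)

    def test_extreme_split_is_overwhelming_evidence(self):
        """(0,0,0,0) vs (50,60,55,45) at phi = 0.1: p < 1e-6 and a strongly
        negative logFC when the zero group is 'high'."""
        p = de.exact_nb_pvalue(0, 210, 4, 4, 0.1)
        assert p < 1e-6
        counts = pd.DataFrame(
            [[0, 0, 0, 0, 50, 60, 55, 45]],
            index=["g"], columns=[f"s{j}" for j in range(8)])
        stable = pd.DataFrame(np.full((200, 8), 100),
                              index=[f"r{i}" for i in range(200)],
                              columns=counts.columns)
        both = pd.concat([counts, stable])
        norm = de.tmm_factors(both)
        model = de.DispersionModel(common=0.1,
                                   tagwise=pd.Series(0.1, index=both.index),
                                   prior_df=10)
        res = de.exact_test(both, [f"s{j}" for j in range(4)],
                            [f"s{j}" for j in range(4, 8)], norm, model)
        assert res.loc["g", "logFC"] < -5
        assert res.loc["g", "p_value"] < 1e-6

    def test_group_swap_flips_logfc_and_keeps_p(self, rng):
        counts = nb_counts(rng, 200, 12)
        high = [f"s{j}" for j in range(6)]
        low = [f"s{j}" for j in range(6, 12)]
        norm = de.tmm_factors(counts)
        model = de.DispersionModel(common=0.2,
                                   tagwise=pd.Series(0.2, index=counts.index),
                                   prior_df=10)
        a = de.exact_test(counts, high, low, norm, model)
        b = de.exact_test(counts, low, high, norm, model)
        np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-12)
        np.testing.assert_allclose(a["logFC"], -b["logFC"], atol=1e-9)

    def test_count_doubling_leaves_logfc_invariant(self, rng):
        counts = nb_counts(rng, 300, 8, mu=80)
        high = [f"s{j}" for j in range(4)]
        low = [f"s{j}" for j in range(4, 8)]
        model = de.DispersionModel(common=0.2,
                                   tagwise=pd.Series(0.2, index=counts.index),
                                   prior_df=10)
        a = de.exact_test(counts, high, low, de.tmm_factors(counts), model)
        doubled = counts * 2
        b = de.exact_test(doubled, high, low, de.tmm_factors(doubled), model)
        np.testing.assert_allclose(a["logFC"], b["logFC"], atol=0.01)

    def test_null_simulation_calibrated(self, rng):
        """Null NB data (phi 0.2, 10 vs 10, 2000 genes): near-uniform
        p-values and logFC centred at zero."""
        counts = nb_counts(rng, 2000, 20)
        res = de.run_de(counts, [f"s{j}" for j in range(10)],
                        [f"s{j}" for j in range(10, 20)])
        from scipy.stats import kstest
        assert kstest(res["p_value"], "uniform").statistic < 0.05
        assert abs(res["logFC"].median()) < 0.05


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=2,
                    max_size=60))
    @settings(max_examples=50, derandomize=True)
    def test_fdr_is_monotone_step_up_and_order_free(self, pvals):
        p = np.array(pvals)
        fdr = multipletests(p, method="fdr_bh")[1]
        assert (fdr >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        fdr_perm = multipletests(p[perm], method="fdr_bh")[1]
        np.testing.assert_allclose(fdr_perm, fdr[perm], atol=1e-12)
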