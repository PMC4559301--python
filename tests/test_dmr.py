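"""NB GLM testing, dispersion estimation, BH adjustment, gene annotation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import medipdmr as m
from medipdmr.dmr import _irls, _nb_loglik
from medipdmr.windows import WindowCountMatrix
from tests.conftest import toy_samples


# ---------------------------------------------------------------- design

def test_design_has_expected_columns_for_full_study():
    cfg = m.SimConfig(seed=3)
    from medipdmr.simulate import build_sample_sheet
    sheet = build_sample_sheet(cfg)
    X, names = m.build_design(sheet)
    assert names == ["intercept", "group_Hi", "gender_M",
                     "batch_2", "batch_3", "batch_4", "batch_5"]
    assert np.linalg.matrix_rank(X) == 7


def test_design_single_gender_omitted_with_warning():
    sheet = toy_samples(4, 2)
    sheet["gender"] = "F"
    with pytest.warns(UserWarning, match="gender"):
        _, names = m.build_design(sheet)
    assert not any(n.startswith("gender") for n in names)


def test_design_batch_aliased_with_group_raises():
    sheet = toy_samples(4, 2)
    sheet["ip_batch"] = np.where(sheet["group"] == "Hi", 1, 2)
    with pytest.raises(ValueError, match="aliased"):
        m.build_design(sheet)


# ---------------------------------------------------------------- BH

def _bh_bruteforce(p):
    """Direct definitional oracle: q_i = min over p_j >= p_i of n p_j / rank_j."""
    p = np.asarray(p, float)
    n = len(p)
    ranks = {}
    for i, v in enumerate(sorted(p)):
        ranks.setdefault(v, i + 1)  # smallest rank among ties
    sorted_p = sorted(p)
    out = []
    for pi in p:
        cands = [n * pj / (k + 1) for k, pj in enumerate(sorted_p) if pj >= pi]
        out.append(min(1.0, min(cands)))
    return np.array(out)


@pytest.mark.parametrize("p,expected", [
    ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
    ((0.5,), (0.5,)),
    ((0.05, 1.0), (0.10, 1.0)),
])
def test_bh_known_values(p, expected):
    assert np.allclose(m.bh_adjust(p), expected)


def test_bh_matches_bruteforce_and_statsmodels_on_random_vectors():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(11)
    for n in (1, 10, 137, 1000):
        p = rng.uniform(1e-6, 1.0, size=n)
        q = m.bh_adjust(p)
        assert np.allclose(q, _bh_bruteforce(p), atol=1e-12)
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)
        # monotone in p
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        m.bh_adjust([0.0, 0.5])


# ---------------------------------------------------------------- GLM

def _matrix_from_counts(raw, samples):
    windows = m.tile_windows({"chr1": raw.shape[0] * 300}, 300)
    return WindowCountMatrix(windows=windows, raw=raw, samples=samples)


def test_lrt_equals_twice_direct_loglik_difference():
    """LRT statistic == 2 * (independent nbinom logpmf sums) on random windows."""
    rng = np.random.default_rng(21)
    samples = toy_samples(6, 2)
    X, _ = m.build_design(samples)
    raw = rng.negative_binomial(10, 10 / (10 + 30.0), size=(20, len(samples)))
    mat = _matrix_from_counts(raw, samples)
    phi = np.full(20, 0.1)
    off = np.zeros(len(samples))
    beta_f, mu_f, _ = _irls(raw.astype(float), X, off, phi)
    X_red = np.delete(X, 1, axis=1)
    _, mu_r, _ = _irls(raw.astype(float), X_red, off, phi)
    lrt = 2.0 * (_nb_loglik(raw.astype(float), mu_f, phi)
                 - _nb_loglik(raw.astype(float), mu_r, phi))
    r = 1 / 0.1
    for g in range(20):
        ll_f = stats.nbinom.logpmf(raw[g], r, r / (r + mu_f[g])).sum()
        ll_r = stats.nbinom.logpmf(raw[g], r, r / (r + mu_r[g])).sum()
        assert lrt[g] == pytest.approx(2 * (ll_f - ll_r), abs=1e-6)


def test_glm_fit_matches_statsmodels_fixed_dispersion():
    import statsmodels.api as sm
    rng = np.random.default_rng(4)
    samples = toy_samples(8, 2)
    X, _ = m.build_design(samples)
    mu_true = np.exp(X @ np.array([3.0, 0.6, -0.2, 0.1]))
    phi = 0.15
    y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu_true))[None, :]
    beta, _, conv = _irls(y.astype(float), X, np.zeros(len(samples)),
                          np.array([phi]))
    fit = sm.GLM(y[0], X, family=sm.families.NegativeBinomial(alpha=phi)).fit()
    assert conv[0]
    assert np.allclose(beta[0], fit.params, atol=1e-4)


def test_null_window_gives_zero_fc_and_p_near_one():
    samples = toy_samples(6, 2)
    X, _ = m.build_design(samples)
    # identical per-group count distributions
    half = [12, 15, 9, 14, 11, 13]
    raw = np.array([half + half])
    mat = _matrix_from_counts(raw, samples)
    disp = m.DispersionEstimate(common=0.1, tagwise=np.array([0.1]), prior_df=10)
    res = m.test_windows(mat, X, disp)
    assert abs(res["log2fc"].iloc[0]) < 1e-6
    assert res["p"].iloc[0] > 0.99


def test_planted_sign_recovery_on_small_simulation():
    cfg = m.SimConfig(n_chromosomes=2, chrom_length=200_000,
                      n_samples_per_group=12, n_dmr_hypo=15, n_dmr_hyper=10,
                      dmr_log2fc=1.0, bio_sd=0.0, seed=55)
    _, _, matrix, truth, samples = m.simulate_study(cfg)
    norm = m.quantile_normalize(m.filter_windows(matrix))
    X, _ = m.build_design(samples)
    disp = m.estimate_dispersions(norm, X)
    res = m.test_windows(norm, X, disp).set_index(["chrom", "start"])
    planted = truth.planted_dmrs
    hit = res.loc[list(zip(planted["chrom"], planted["start"]))]
    agree = (hit["direction"].to_numpy() == planted["direction"].to_numpy()).mean()
    assert agree >= 0.95


# ---------------------------------------------------------------- dispersion

def test_dispersion_recovery_and_shrinkage_limits():
    cfg = m.SimConfig(n_chromosomes=1, chrom_length=250_000,
                      n_samples_per_group=12, n_dmr_hypo=0, n_dmr_hyper=0,
                      nb_dispersion=0.1, bio_sd=0.0, seed=66)
    _, _, matrix, _, samples = m.simulate_study(cfg)
    norm = m.quantile_normalize(m.filter_windows(matrix))
    X, _ = m.build_design(samples)
    disp = m.estimate_dispersions(norm, X)
    assert 0.08 <= disp.common <= 0.12
    # tagwise lies between the unshrunk estimate and the common value
    lo = np.minimum(disp.unshrunk, disp.common) * 0.8 - 1e-3
    hi = np.maximum(disp.unshrunk, disp.common) * 1.2 + 1e-3
    frac_between = np.mean((disp.tagwise >= lo) & (disp.tagwise <= hi))
    assert frac_between >= 0.95
    # prior_df -> infinity collapses tagwise onto common
    disp_inf = m.estimate_dispersions(norm, X, prior_df=1e9)
    assert np.allclose(disp_inf.tagwise, disp_inf.common, rtol=0.15)


def test_poisson_data_estimates_near_zero_dispersion():
    cfg = m.SimConfig(n_chromosomes=1, chrom_length=150_000,
                      n_samples_per_group=12, n_dmr_hypo=0, n_dmr_hyper=0,
                      nb_dispersion=0.0, bio_sd=0.0, seed=67)
    _, _, matrix, _, samples = m.simulate_study(cfg)
    norm = m.quantile_normalize(m.filter_windows(matrix))
    X, _ = m.build_design(samples)
    disp = m.estimate_dispersions(norm, X)
    assert disp.common <= 0.01


def test_dispersion_refuses_non_integer_counts():
    samples = toy_samples(4, 2)
    X, _ = m.build_design(samples)
    windows = m.tile_windows({"chr1": 300}, 300)
    mat = WindowCountMatrix(windows=windows,
                            raw=np.full((1, len(samples)), 3),
                            samples=samples)
    mat.raw = mat.raw + 0.5
    with pytest.raises(ValueError, match="integer"):
        m.estimate_dispersions(mat, X, offsets=np.zeros(len(samples)))


# ---------------------------------------------------------------- annotation

def _genes(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


def test_nearest_gene_by_tss_distance():
    dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [300]})  # mid 150
    genes = _genes([("chr1", 100, 2000, "gA", 0, "+"),
                    ("chr1", 500, 2500, "gB", 0, "+")])
    out = m.annotate_nearest_gene(dmrs, genes)
    assert out["nearest_gene"].iloc[0] == "gA"
    assert out["tss_distance"].iloc[0] == 50


def test_nearest_gene_minus_strand_uses_end_as_tss():
    dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1200]})  # mid 1050
    genes = _genes([("chr1", 0, 1000, "gMinus", 0, "-"),   # TSS 1000, d=50
                    ("chr1", 1500, 3000, "gPlus", 0, "+")])  # TSS 1500, d=450
    out = m.annotate_nearest_gene(dmrs, genes)
    assert out["nearest_gene"].iloc[0] == "gMinus"


def test_nearest_gene_tie_breaks_lexicographically():
    dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [300]})  # mid 150
    genes = _genes([("chr1", 100, 500, "B", 0, "+"),
                    ("chr1", 200, 600, "A", 0, "+")])
    out = m.annotate_nearest_gene(dmrs, genes)
    assert out["nearest_gene"].iloc[0] == "A"


def test_nearest_gene_none_without_genes_on_chromosome():
    dmrs = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [300]})
    genes = _genes([("chr1", 0, 100, "gA", 0, "+")])
    out = m.annotate_nearest_gene(dmrs, genes)
    assert out["nearest_gene"].iloc[0] is None


# ---------------------------------------------------- direction proportion

def _binom_two_sided_bruteforce(k, n, p0):
    pmf = [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    return sum(v for v in pmf if v <= pmf[k] * (1 + 1e-9))


def test_direction_split_507_345_is_extreme():
    subset = pd.DataFrame({"direction": ["hypo"] * 507 + ["hyper"] * 345})
    n_hypo, n_hyper, p = m.direction_proportion_test(subset, 0.5)
    assert (n_hypo, n_hyper) == (507, 345)
    assert p < 1e-7
    assert p == pytest.approx(_binom_two_sided_bruteforce(507, 852, 0.5), rel=1e-6)


def test_direction_split_balanced_is_null():
    subset = pd.DataFrame({"direction": ["hypo"] * 10 + ["hyper"] * 10})
    assert m.direction_proportion_test(subset, 0.5)[2] == pytest.approx(1.0)


def test_direction_split_matching_background_is_null():
    subset = pd.DataFrame({"direction": ["hypo"] * 30 + ["hyper"] * 70})
    assert m.direction_proportion_test(subset, 0.3)[2] >= 0.99


def test_direction_split_empty_raises():
    with pytest.raises(ValueError):
        m.direction_proportion_test(pd.DataFrame({"direction": []}))
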