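"""GRM, REML, mixed-model scan, inflation factor and region extraction."""

import numpy as np
import pytest
from scipy import stats

from xfert import gwas, simdata
from xfert.geno_qc import GenotypeMatrix, MarkerPanel
from conftest import tiny_config


def female_matrix(codes, chrom="1"):
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    panel = MarkerPanel([f"m{j}" for j in range(m)], [chrom] * m,
                        np.arange(1, m + 1) * 10, ["A"] * m, ["B"] * m)
    return GenotypeMatrix([f"s{i}" for i in range(n)], ["F"] * n, panel,
                          codes)


def random_matrix(rng, n, m, freq=None):
    p = rng.uniform(0.1, 0.9, size=m) if freq is None else np.full(m, freq)
    return female_matrix(rng.binomial(2, p, size=(n, m)))


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def test_grm_matches_hand_computed_oracle():
    codes = [[0, 2], [1, 1], [2, 0]]
    gm = female_matrix(codes)
    got = gwas.compute_grm(gm).values
    X = np.array(codes, dtype=float)
    expected = np.zeros((3, 3))
    for j in range(3):
        for k in range(3):
            acc = 0.0
            for l in range(2):
                p = X[:, l].mean() / 2
                acc += ((X[j, l] - 2 * p) * (X[k, l] - 2 * p)
                        / (2 * p * (1 - p)))
            expected[j, k] = acc / 2
    assert np.allclose(got, expected, atol=1e-12)
    assert np.allclose(got, got.T)


def test_identical_samples_have_offdiagonal_equal_to_diagonal(rng):
    gm = random_matrix(rng, 20, 100)
    codes = gm.codes.copy()
    codes[1] = codes[0]                       # duplicate pair
    gm = female_matrix(codes)
    G = gwas.compute_grm(gm).values
    assert abs(G[0, 1] - G[0, 0]) < 1e-12


def test_grm_skips_monomorphic_markers_and_diagonal_is_near_one(rng):
    gm = random_matrix(rng, 400, 600)
    codes = gm.codes.copy()
    codes[:, 10] = 2                          # monomorphic column
    grm = gwas.compute_grm(female_matrix(codes))
    assert grm.n_skipped_monomorphic == 1
    assert grm.n_markers_used == 599
    assert np.diag(grm.values).mean() == pytest.approx(1.0, abs=0.05)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def test_identity_grm_reduces_to_intercept_only_variance_partition(rng):
    n = 60
    y = rng.normal(2.0, 1.3, n)
    grm = gwas.Grm(np.eye(n), [f"s{i}" for i in range(n)], 1, 0)
    vc = gwas.reml_fit(y, grm)
    # with G = I only the total variance is identified; REML recovers the
    # usual unbiased variance of an intercept-only model
    assert vc.sigma2_g + vc.sigma2_e == pytest.approx(np.var(y, ddof=1),
                                                      rel=1e-6)


def test_constant_phenotype_is_rejected():
    grm = gwas.Grm(np.eye(5), list("abcde"), 1, 0)
    with pytest.raises(ValueError, match="constant"):
        gwas.reml_fit(np.ones(5), grm)


@pytest.fixture(scope="module")
def family_grm():
    """A relatedness matrix with real structure, from a small pedigree."""
    cfg = tiny_config(n_founder_boars=30, n_founder_sows=150,
                      n_markers_per_chrom=300, litter_size=8,
                      causal_alt_freq=0.1, seed=99)
    pop = simdata.simulate_population(cfg)
    keep = pop.ids[np.linspace(0, pop.n_individuals - 1, 500).astype(int)]
    gm = simdata.genotype_matrix(pop, keep)
    return gwas.compute_grm(gm)


def test_reml_recovers_known_variance_ratio(family_grm):
    """Simulate y from known components (h2 = 0.5) and check the mean REML
    heritability over replicates against the truth within 3 MC SDs."""
    grm = family_grm
    d, U = grm.eig()
    rng = np.random.default_rng(5)
    n = grm.n
    h2 = []
    for _ in range(50):
        g = U @ (np.sqrt(0.5 * d) * rng.normal(size=n))
        y = 1.0 + g + rng.normal(0.0, np.sqrt(0.5), n)
        vc = gwas.reml_fit(y, grm)
        h2.append(vc.heritability)
    se = np.std(h2, ddof=1) / np.sqrt(len(h2))
    assert abs(np.mean(h2) - 0.5) <= 3 * se


def test_reml_null_heritability_is_near_zero(family_grm):
    rng = np.random.default_rng(6)
    h2 = [gwas.reml_fit(rng.normal(size=family_grm.n), family_grm).heritability
          for _ in range(20)]
    assert np.mean(h2) < 0.1


# ---------------------------------------------------------------------------
# mixed-model scan
# ---------------------------------------------------------------------------

def dense_gls_oracle(y, X_markers, G, vc):
    """Direct dense-matrix GLS per marker under V = s2g G + s2e I."""
    n = len(y)
    V = vc.sigma2_g * G + vc.sigma2_e * np.eye(n)
    Vi = np.linalg.inv(V)
    out = []
    for x in X_markers.T:
        X = np.column_stack([np.ones(n), x])
        C = np.linalg.inv(X.T @ Vi @ X)
        beta = C @ X.T @ Vi @ y
        se = np.sqrt(C[1, 1])
        chi2 = (beta[1] / se) ** 2
        out.append((beta[1], se, chi2, stats.chi2.sf(chi2, 1)))
    return out


def test_scan_matches_dense_gls_oracle_to_1e10(rng):
    n, m = 30, 5
    gm = random_matrix(rng, n, m)
    Z = rng.normal(size=(n, 40))
    G = Z @ Z.T / 40
    grm = gwas.Grm(G, gm.samples, 40, 0)
    vc = gwas.VarianceComponents(0.3, 0.7, 0.0)
    y = rng.normal(size=n)
    records = gwas.mlma_scan(gm, y, grm, vc)
    for rec, (b, se, chi2, p) in zip(records,
                                     dense_gls_oracle(y, gm.codes.astype(
                                         float), G, vc)):
        assert rec.b == pytest.approx(b, abs=1e-10)
        assert rec.se == pytest.approx(se, abs=1e-10)
        assert rec.chi2 == pytest.approx(chi2, abs=1e-8)
        assert rec.p == pytest.approx(p, rel=1e-8)


def test_scan_with_zero_polygenic_variance_equals_ols(rng):
    n, m = 50, 4
    gm = random_matrix(rng, n, m)
    y = rng.normal(size=n)
    grm = gwas.Grm(np.eye(n), gm.samples, 1, 0)
    vc = gwas.VarianceComponents(0.0, 1.0, 0.0)
    records = gwas.mlma_scan(gm, y, grm, vc)
    for j, rec in enumerate(records):
        x = gm.codes[:, j].astype(float)
        sxx = ((x - x.mean()) ** 2).sum()
        b_ols = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        assert rec.b == pytest.approx(b_ols, abs=1e-10)
        # with unit residual variance the Wald SE is the design-based one
        assert rec.se == pytest.approx(np.sqrt(1.0 / sxx), abs=1e-10)


def test_monomorphic_marker_yields_flagged_record_not_a_crash(rng):
    gm = random_matrix(rng, 20, 3)
    codes = gm.codes.copy()
    codes[:, 1] = 1
    gm = female_matrix(codes)
    grm = gwas.Grm(np.eye(20), gm.samples, 1, 0)
    records = gwas.mlma_scan(gm, np.r_[np.ones(10), np.zeros(10)], grm,
                             gwas.VarianceComponents(0.0, 1.0, 0.0))
    assert records[1].undefined and np.isnan(records[1].b)
    assert not records[0].undefined


def test_missing_genotypes_are_mean_imputed_in_the_scan(rng):
    codes = rng.binomial(2, 0.4, size=(40, 1)).astype(np.int8)
    codes_miss = codes.copy()
    codes_miss[3, 0] = -1
    y = rng.normal(size=40)
    grm = gwas.Grm(np.eye(40), [f"s{i}" for i in range(40)], 1, 0)
    vc = gwas.VarianceComponents(0.0, 1.0, 0.0)
    rec_miss = gwas.mlma_scan(female_matrix(codes_miss), y, grm, vc)[0]
    manual = codes.astype(float)
    manual[3, 0] = np.delete(codes_miss[:, 0], 3).mean()
    b, se, chi2, p = dense_gls_oracle(y, manual, np.eye(40), vc)[0]
    assert rec_miss.b == pytest.approx(b, abs=1e-10)


def test_scan_is_invariant_to_sample_permutation(rng):
    n = 35
    gm = random_matrix(rng, n, 6)
    Z = rng.normal(size=(n, 50))
    G = Z @ Z.T / 50
    y = rng.normal(size=n)
    vc = gwas.VarianceComponents(0.4, 0.6, 0.0)
    recs = gwas.mlma_scan(gm, y, gwas.Grm(G, gm.samples, 50, 0), vc)
    perm = rng.permutation(n)
    gm_p = female_matrix(gm.codes[perm])
    recs_p = gwas.mlma_scan(gm_p, y[perm],
                            gwas.Grm(G[np.ix_(perm, perm)], gm_p.samples,
                                     50, 0), vc)
    for a, b in zip(recs, recs_p):
        assert a.b == pytest.approx(b.b, abs=1e-10)
        assert a.p == pytest.approx(b.p, rel=1e-10)


# ---------------------------------------------------------------------------
# thresholds, lambda, regions
# ---------------------------------------------------------------------------

def test_bonferroni_thresholds_match_reported_values():
    assert gwas.bonferroni_threshold(0.05, 50_649) == pytest.approx(
        9.87e-7, abs=0.005e-7)
    assert gwas.bonferroni_threshold(0.05, 11) == pytest.approx(
        4.5e-3, abs=0.05e-3)
    assert gwas.bonferroni_threshold(0.05, 1) == 0.05
    with pytest.raises(ValueError):
        gwas.bonferroni_threshold(1.5, 10)


def test_lambda_is_one_when_median_chisq_is_the_null_median():
    chi2 = np.array([0.1, 0.2, gwas.CHI2_MEDIAN, 1.0, 2.0])
    p = stats.chi2.sf(chi2, 1)
    assert gwas.inflation_factor(p, "median") == pytest.approx(1.0)


def test_regression_lambda_recovers_a_pure_scaling():
    m = 1000
    expected = stats.chi2.isf((np.arange(1, m + 1) - 0.5) / m, 1)
    p = stats.chi2.sf(2.0 * expected, 1)
    assert gwas.inflation_factor(p, "regression") == pytest.approx(2.0,
                                                                   rel=1e-9)


def test_lambda_on_uniform_pvalues_is_close_to_one(rng):
    p = rng.uniform(size=50_000)
    assert gwas.inflation_factor(p, "regression") == pytest.approx(1.0,
                                                                   abs=0.03)
    assert gwas.inflation_factor(p, "median") == pytest.approx(1.0,
                                                               abs=0.03)
    with pytest.raises(ValueError):
        gwas.inflation_factor([0.5])


def _rec(chrom, pos, p):
    return gwas.AssocRecord(f"{chrom}:{pos}", chrom, pos, 0.1, 0.05,
                            4.0, p)


def test_significant_region_reproduces_the_x_cluster():
    thr = 9.87e-7
    positions = np.linspace(38_600_000, 108_700_000, 18).astype(int)
    records = [_rec("X", int(p), 1e-9) for p in positions]
    records += [_rec("X", 5_000_000, 0.4), _rec("5", 1_000_000, 1e-8)]
    summary = gwas.significant_region(records, thr)
    reg = summary.regions["X"]
    assert (reg.start, reg.end, reg.count) == (38_600_000, 108_700_000, 18)
    assert summary.primary == "X"
    assert [r.chrom for r in summary.scattered] == ["5"]


def test_region_edge_cases():
    assert gwas.significant_region([], 0.05).regions == {}
    one = gwas.significant_region([_rec("2", 500, 1e-9)], 1e-6)
    assert one.regions["2"].start == one.regions["2"].end == 500
    assert one.regions["2"].count == 1 and one.scattered == []


def test_null_qq_points_stay_inside_simultaneous_band(rng):
    m, reps = 500, 100
    band = gwas.qq_band(m, level=0.95, simultaneous=True)
    inside = 0
    for _ in range(reps):
        p = np.sort(rng.uniform(size=m))
        inside += bool(np.all((p >= band["lower"]) & (p <= band["upper"])))
    assert inside >= 0.93 * reps
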