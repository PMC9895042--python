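"""Outlier scan calibration/power and environmental-association Bayes factors."""

import numpy as np
import pytest
from scipy import stats

from beachflow import scan, simdata


@pytest.fixture(scope="module")
def island():
    mat, tags = simdata.simulate_island_matrix(
        n_localities=4, diploids_per_site=12, n_snps=2000,
        fst_locality=0.03, seed=77)
    return mat, tags


# ---------------------------------------------------------------------------
# Bonferroni flag rule
# ---------------------------------------------------------------------------

def test_bonferroni_arithmetic():
    m = 19311
    flags = scan.bonferroni_outliers(
        np.array([1e-4, 1e-7, 1e-9]), np.array([0.2, 0.2, 0.03]), m)
    # 1e-4 * 19311 > 1 -> not flagged; 1e-7 -> adj ~0.0019 flagged;
    # 1e-9 blocked by the MAF gate
    assert list(flags) == [False, True, False]


# ---------------------------------------------------------------------------
# pcadapt-style scan
# ---------------------------------------------------------------------------

def test_null_pvalues_uniform(island):
    mat, _ = island
    res = scan.pcadapt_scan(mat, K=4)
    p = res.table["p"].to_numpy()
    d = stats.kstest(p, "uniform").statistic
    assert d < 0.05
    assert res.inflation == pytest.approx(1.0, abs=0.25)


def test_scan_power_on_spiked_loci(island):
    mat, tags = island
    rng = np.random.default_rng(5)
    spiked_mat, spiked = simdata.spike_outlier_loci(
        mat, mat.samples["habitat"].to_numpy(), tags, 20, 0.6, rng)
    res = scan.pcadapt_scan(spiked_mat, K=4)
    hits = set(res.outliers) & set(spiked)
    assert len(hits) / len(spiked) >= 0.8


def test_scan_invariant_to_column_order_and_allele_flip(island):
    mat, _ = island
    res1 = scan.pcadapt_scan(mat, K=2)
    # flip ref/alt on half the SNPs
    codes = mat.codes.copy()
    flip = np.arange(0, mat.n_snps, 2)
    cols = codes[:, flip]
    codes[:, flip] = np.where(cols >= 0, 2 - cols, -1)
    flipped = simdata.GenotypeMatrix(codes, mat.samples, mat.snp_ids)
    res2 = scan.pcadapt_scan(flipped, K=2)
    assert np.allclose(res1.table["d2"], res2.table["d2"], rtol=1e-8)
    # permute columns
    perm = np.random.default_rng(0).permutation(mat.n_snps)
    pm = simdata.GenotypeMatrix(mat.codes[:, perm], mat.samples,
                                [mat.snp_ids[i] for i in perm])
    res3 = scan.pcadapt_scan(pm, K=2)
    lookup = dict(zip(res3.table["snp_id"], res3.table["d2"]))
    assert np.allclose(res1.table["d2"],
                       [lookup[s] for s in res1.table["snp_id"]], rtol=1e-8)


def test_max_d2_for_component_aligned_snp(rng):
    n = 60
    comp = np.repeat([0.0, 1.0], n // 2) + rng.normal(0, 0.01, n)
    codes = rng.integers(0, 3, (n, 50)).astype(np.int8)
    codes[:, 0] = np.where(comp > 0.5, 2, 0)  # collinear with structure
    mat = simdata.GenotypeMatrix(
        codes,
        __import__("pandas").DataFrame({
            "individual": [f"i{j}" for j in range(n)],
            "locality": 1, "habitat": ["B"] * (n // 2) + ["I"] * (n // 2)}),
        [f"s{j}" for j in range(50)])
    res = scan.pcadapt_scan(mat, K=1)
    assert res.table["d2"].idxmax() == 0


# ---------------------------------------------------------------------------
# population covariance
# ---------------------------------------------------------------------------

def test_pop_covariance_identical_sites():
    rng = np.random.default_rng(2)
    block = rng.integers(0, 3, (6, 200)).astype(np.int8)
    codes = np.vstack([block, block])  # two sites, identical genotypes
    import pandas as pd
    mat = simdata.GenotypeMatrix(
        codes, pd.DataFrame({"individual": [f"i{j}" for j in range(12)],
                             "locality": [1] * 6 + [2] * 6,
                             "habitat": "B"}),
        [f"s{j}" for j in range(200)])
    sites, om = scan.pop_covariance(mat)
    # identical frequencies at every SNP -> deviations vanish
    assert np.abs(om).max() <= 1e-6 + 1e-12


def test_pop_covariance_cluster_sign_pattern():
    mat, _ = simdata.simulate_island_matrix(
        n_localities=2, diploids_per_site=15, n_snps=3000,
        fst_locality=0.1, fst_habitat=0.001, seed=11)
    sites, om = scan.pop_covariance(mat)
    w = np.linalg.eigvalsh(om)
    assert w.min() > 0                      # PSD + ridge
    assert np.allclose(om, om.T)
    # within-locality pairs covary positively, between-locality negatively
    # (frequencies are standardized around the across-site mean)
    i1b, i1i = sites.index("1-B"), sites.index("1-I")
    i2b = sites.index("2-B")
    assert om[i1b, i1i] > om[i1b, i2b]


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def test_bf_orthogonal_frequency_pattern():
    e = np.array([1.0, 0, 1, 0, 1, 0, 1, 0])
    x = np.array([1.0, 1, -1, -1, 1, 1, -1, -1]) * 0.3
    x -= x.mean()
    # x chosen orthogonal to centered e under the identity metric
    assert abs((x * (e - e.mean())).sum()) < 1e-12
    bf = scan.bayes_factor_env(x, e, np.eye(8))
    assert bf <= 1.0 + 1e-6


def test_bf_identity_covariance_matches_closed_form():
    rng = np.random.default_rng(8)
    e = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
    estar = e - e.mean()
    x = 0.8 * estar + rng.normal(0, 0.2, 8)
    hw = 10.0
    bf = scan.bayes_factor_env(x, e, np.eye(8), prior_halfwidth=hw)
    # closed form: L(b) = exp(-(a b^2 - 2 g b)/2) up to shared constants
    a = estar @ estar
    g = x @ estar
    bhat = g / a
    from scipy.stats import norm
    mass = (norm.cdf((hw - bhat) * np.sqrt(a))
            - norm.cdf((-hw - bhat) * np.sqrt(a)))
    closed = (np.sqrt(2 * np.pi / a) / (2 * hw) * mass
              * np.exp(0.5 * g ** 2 / a))
    assert bf == pytest.approx(closed, rel=0.01)


def test_bf_quadrature_grid_stable():
    e = np.array([1.0, 0, 1, 0, 1, 0])
    x = 0.5 * (e - e.mean()) + 0.1
    om = np.eye(6) * 0.5 + 0.1
    b1 = scan.bayes_factor_env(x, e, om, grid_points=2001)
    b2 = scan.bayes_factor_env(x, e, om, grid_points=4001)
    assert b1 == pytest.approx(b2, rel=0.01)


def test_bf_strong_habitat_association():
    e = np.array([1.0, 0, 1, 0, 1, 0, 1, 0])
    estar = e - e.mean()
    x = 2.5 * estar                       # delta_p ~ 0.5 standardized
    om = np.eye(8) * 0.3
    assert scan.bayes_factor_env(x, e, om) > 10


# ---------------------------------------------------------------------------
# replicate consistency
# ---------------------------------------------------------------------------

def test_replicate_consistency_deterministic_counts(island):
    mat, tags = island
    rng = np.random.default_rng(3)
    sp_mat, spiked = simdata.spike_outlier_loci(
        mat, mat.samples["habitat"].to_numpy(), tags, 3, 0.7, rng)
    e = {s: 1.0 if s.endswith("B") else 0.0
         for s in sorted(set(sp_mat.site_labels()))}
    cons, bf = scan.replicate_consistency(
        sp_mat, e, spiked, thinned=sp_mat, n_runs=4, seed=0, resample=False)
    assert set(cons["n_significant"]).issubset({0, 4})  # no stochasticity


def test_replicate_consistency_strong_spike_all_runs(island):
    mat, tags = island
    rng = np.random.default_rng(9)
    sp_mat, spiked = simdata.spike_outlier_loci(
        mat, mat.samples["habitat"].to_numpy(), tags, 2, 0.8, rng)
    e = {s: 1.0 if s.endswith("B") else 0.0
         for s in sorted(set(sp_mat.site_labels()))}
    cons, bf = scan.replicate_consistency(
        sp_mat, e, spiked, thinned=sp_mat, n_runs=5, seed=1)
    assert (cons["n_significant"] == 5).all()


def test_replicate_consistency_null_rate(island):
    mat, _ = island
    e = {s: 1.0 if s.endswith("B") else 0.0
         for s in sorted(set(mat.site_labels()))}
    null_snps = mat.snp_ids[:40]
    cons, bf = scan.replicate_consistency(
        mat, e, null_snps, thinned=mat, n_runs=5, bf_threshold=10.0, seed=2)
    assert cons["n_significant"].mean() < 0.05 * 5
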