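"""Structured-coalescent correctness, dataset generation, phenotype sims."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beachflow import simdata
from beachflow.simdata import DemographicParams, SimConfig


def single_pop(N=1000, mu=1e-8):
    """Effectively panmictic: both demes merge immediately (T_div = 0)."""
    return DemographicParams.nogflow(N, N, N, 0.0, mu=mu)


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bad", [
    dict(model_kind="NOGFLOW", N_beach=0, N_inland=10, N_ancestral=10,
         T_div=100),
    dict(model_kind="NOGFLOW", N_beach=10, N_inland=10, N_ancestral=10,
         T_div=100, m_BI_rec=0.1),
    dict(model_kind="ONEGFLOW", N_beach=10, N_inland=10, N_ancestral=10,
         T_div=100, m_BI_anc=0.1, m_BI_rec=0.2),
    dict(model_kind="TWOGFLOW", N_beach=10, N_inland=10, N_ancestral=10,
         T_div=100, T_recent=200.0),
    dict(model_kind="NOGFLOW", N_beach=10, N_inland=10, N_ancestral=10,
         T_div=float("inf")),
])
def test_invalid_params_rejected(bad):
    with pytest.raises(ValueError):
        DemographicParams(**bad)


def test_backwards_rate_swap():
    p = DemographicParams.twogflow(100, 100, 100, 1000, 100,
                                   m_BI_anc=1e-4, m_IB_anc=2e-4,
                                   m_BI_rec=3e-4, m_IB_rec=4e-4)
    (mb_rec, mi_rec), (mb_anc, mi_anc) = p.backwards_rates()
    # beach lineage jumps backwards at the forwards inland->beach rate
    assert mb_rec == 4e-4 and mi_rec == 3e-4
    assert mb_anc == 2e-4 and mi_anc == 1e-4


# ---------------------------------------------------------------------------
# coalescent closed forms
# ---------------------------------------------------------------------------

def test_pair_tmrca_is_2N():
    # n=2 in one deme, no migration, effectively infinite divergence time
    p = DemographicParams.nogflow(1000, 1000, 1000, 1e12)
    tm, _ = simdata.tmrca_sample(p, 2, 0, 100_000, seed=7)
    assert tm.mean() == pytest.approx(2000.0, rel=0.02)


def test_total_branch_length_harmonic():
    n = 10
    p = DemographicParams.nogflow(1000, 1000, 1000, 1e12)
    _, tl = simdata.tmrca_sample(p, n, 0, 50_000, seed=11)
    expect = 4 * 1000 * sum(1.0 / i for i in range(1, n))
    assert tl.mean() == pytest.approx(expect, rel=0.02)


def test_no_migration_before_divergence():
    p = DemographicParams.nogflow(500, 800, 600, 3000)
    for seed in range(20):
        g = simdata.sample_genealogy(p, 6, 6, seed)
        assert g.n_migrations == 0
        assert g.parent[-1] == -1                    # single MRCA
        assert (g.parent[:-1] >= 0).all()


def test_symmetric_island_tmrca_matches_msprime():
    """Independent oracle: the same two-deme model in msprime."""
    msprime = pytest.importorskip("msprime")
    N, m = 500.0, 5e-4
    p = DemographicParams.onegflow(N, N, N, 1e12, m_BI=m, m_IB=m)
    tm, _ = simdata.tmrca_sample(p, 1, 1, 20_000, seed=3)

    # ploidy-1 msprime: initial_size 2N reproduces the diploid pairwise
    # coalescence rate 1/(2N)
    dem = msprime.Demography()
    dem.add_population(name="b", initial_size=2 * N)
    dem.add_population(name="i", initial_size=2 * N)
    dem.set_migration_rate("b", "i", m)
    dem.set_migration_rate("i", "b", m)
    times = np.array([
        ts.max_root_time for ts in msprime.sim_ancestry(
            samples={"b": 1, "i": 1}, demography=dem, ploidy=1,
            num_replicates=20_000, random_seed=99)
    ])
    se = np.sqrt(tm.var() / len(tm) + times.var() / len(times))
    assert abs(tm.mean() - times.mean()) < 4 * se
    # both agree with the two-island closed form E[T] = 4N + 1/(2m)
    assert tm.mean() == pytest.approx(4 * N + 1 / (2 * m), rel=0.03)


def test_twogflow_zero_migration_equals_nogflow():
    pn = DemographicParams.nogflow(400, 600, 500, 2000)
    pt = DemographicParams.twogflow(400, 600, 500, 2000, 200,
                                    0, 0, 0, 0)
    tn, _ = simdata.tmrca_sample(pn, 6, 6, 10_000, seed=21)
    tt, _ = simdata.tmrca_sample(pt, 6, 6, 10_000, seed=22)
    assert stats.ks_2samp(tn, tt).pvalue > 0.01


def test_class_lengths_single_pop_shape():
    """Unfolded class branch lengths follow E[T_i] = 4N/i."""
    p = DemographicParams.nogflow(1000, 1000, 1000, 1e12)
    T = simdata.class_branch_lengths(p, 8, 0, 100_000, seed=13)[:, 0]
    for i in range(1, 8):
        assert T[i] == pytest.approx(4 * 1000 / i, rel=0.05)


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

def test_zero_mutation_rate_empty_matrix():
    p = DemographicParams.nogflow(100, 100, 100, 100, mu=0.0)
    mat, tags = simdata.simulate_dataset(p, SimConfig(3, 3, n_contigs=20))
    assert mat.n_snps == 0
    assert len(tags.tag_ids) == 20               # all tags exist, 0 SNPs


def test_seed_reproducibility():
    p = single_pop(500, mu=1e-6)
    cfg = SimConfig(4, 4, n_contigs=100, seed=9, missing_rate=0.05)
    m1, t1 = simdata.simulate_dataset(p, cfg)
    m2, t2 = simdata.simulate_dataset(p, cfg)
    assert np.array_equal(m1.codes, m2.codes)
    assert m1.snp_ids == m2.snp_ids
    assert t1.table.equals(t2.table)


def test_pairwise_diversity_is_4Nmu():
    p = single_pop(1000, mu=1e-6)
    cfg = SimConfig(1, 1, n_contigs=10_000, seed=3)
    mat, _ = simdata.simulate_dataset(p, cfg)
    c = mat.codes.sum(axis=0)
    ntot = 4.0
    pi = (2 * c * (ntot - c) / (ntot * (ntot - 1))).sum() / (10_000 * 300)
    assert pi == pytest.approx(4 * 1000 * 1e-6, rel=0.05)


def test_panmictic_fst_near_zero():
    from beachflow.popstruct import wc_fst
    p = single_pop(800, mu=1e-6)
    cfg = SimConfig(8, 8, n_contigs=800, seed=17)
    mat, _ = simdata.simulate_dataset(p, cfg)
    hab = mat.samples["habitat"].to_numpy()
    f = wc_fst(mat.codes[hab == "B"], mat.codes[hab == "I"])
    assert abs(f) < 0.02


def test_folded_single_pop_sfs_shape():
    """Folded SFS of one panmictic sample ~ 1/i + 1/(2n-i)."""
    p = single_pop(1000, mu=1e-6)
    cfg = SimConfig(5, 5, n_contigs=4000, seed=23)
    mat, _ = simdata.simulate_dataset(p, cfg)
    nh = 20
    c = mat.codes.sum(axis=0)
    folded = np.minimum(c, nh - c)
    counts = np.bincount(folded[(c > 0) & (c < nh)], minlength=nh // 2 + 1)
    expect = np.array([0.0] + [1.0 / i + 1.0 / (nh - i)
                               for i in range(1, nh // 2)] + [1.0 / (nh // 2)])
    obs = counts / counts.sum()
    exp = expect / expect.sum()
    # chi-square style closeness across the 10 frequency classes
    assert np.abs(obs[1:] - exp[1:]).max() < 0.03


# ---------------------------------------------------------------------------
# spiked loci
# ---------------------------------------------------------------------------

def make_island(seed=0, n_snps=300):
    return simdata.simulate_island_matrix(n_snps=n_snps, seed=seed)


def test_spike_delta_zero_keeps_frequencies():
    mat, tags = make_island(1)
    rng = np.random.default_rng(4)
    out, spiked = simdata.spike_outlier_loci(
        mat, mat.samples["habitat"].to_numpy(), tags, 10, 0.0, rng)
    f0 = mat.allele_freq()[[mat.snp_ids.index(s) for s in spiked]]
    f1 = out.allele_freq()[[out.snp_ids.index(s) for s in spiked]]
    # redrawn binomially around the same frequency
    assert np.abs(f0 - f1).mean() < 0.1


def test_spike_full_separation():
    # base p = 0.5 and delta 1 -> beach fixed alternate, inland fixed ref
    mat, tags = make_island(2)
    codes = mat.codes.copy()
    codes[: len(codes) // 2] = 1
    codes[len(codes) // 2:] = np.where(codes[len(codes) // 2:] >= 0, 1, -1)
    mat = simdata.GenotypeMatrix(codes, mat.samples, mat.snp_ids)
    rng = np.random.default_rng(5)
    out, spiked = simdata.spike_outlier_loci(
        mat, mat.samples["habitat"].to_numpy(), tags, 5, 1.0, rng)
    hab = out.samples["habitat"].to_numpy()
    for sid in spiked:
        j = out.snp_ids.index(sid)
        assert (out.codes[hab == "B", j] == 2).all()
        assert (out.codes[hab == "I", j] == 0).all()


def test_spike_mean_frequency_gap():
    mat, tags = make_island(3, n_snps=600)
    rng = np.random.default_rng(6)
    out, spiked = simdata.spike_outlier_loci(
        mat, mat.samples["habitat"].to_numpy(), tags, 60, 0.5, rng)
    hab = out.samples["habitat"].to_numpy()
    gaps = []
    for sid in spiked:
        j = out.snp_ids.index(sid)
        gaps.append(out.codes[hab == "B", j].mean() / 2
                    - out.codes[hab == "I", j].mean() / 2)
    # E|p_B - p_I| = 0.5 (clamping pushes a few below, binomial noise around)
    assert np.mean(gaps) == pytest.approx(0.5, abs=0.06)


def test_spike_rejects_too_many_loci():
    mat, tags = make_island(4, n_snps=50)
    with pytest.raises(ValueError):
        simdata.spike_outlier_loci(mat, mat.samples["habitat"].to_numpy(),
                                   tags, 51, 0.2, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def test_phenotypes_deterministic_and_displaced():
    spec = simdata.default_phenotype_spec(n_per_group=10)
    lm1, meta1, col1 = simdata.simulate_phenotypes(spec, 42)
    lm2, meta2, col2 = simdata.simulate_phenotypes(spec, 42)
    assert np.array_equal(lm1, lm2)
    pd.testing.assert_frame_equal(col1, col2)
    beach = meta1["habitat"] == "B"
    gap = lm1[beach].mean(axis=0) - lm1[~beach].mean(axis=0)
    assert np.abs(gap - spec.habitat_displacement).max() < 0.02


def test_phenotypes_zero_noise_identical():
    spec0 = simdata.default_phenotype_spec(5)
    spec = simdata.PhenotypeSimSpec(
        spec0.mean_shape, np.zeros_like(spec0.mean_shape),
        landmark_noise_sd=0.0, n_per_group=5)
    lm, meta, _ = simdata.simulate_phenotypes(spec, 0)
    assert np.ptp(lm, axis=0).max() == 0.0


def test_phenotype_rejects_bad_covariance():
    spec0 = simdata.default_phenotype_spec(5)
    bad = -np.eye(18)
    with pytest.raises(ValueError):
        simdata.PhenotypeSimSpec(spec0.mean_shape, spec0.habitat_displacement,
                                 colour_cov=bad)
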