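"""Matrix filters, thinning, folded-SFS construction, monomorphic arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from beachflow import genomatrix as gm
from beachflow.simdata import MISSING

from conftest import make_matrix, make_tagmap


# ---------------------------------------------------------------------------
# exact heterozygote-excess test vs enumeration oracle
# ---------------------------------------------------------------------------

def levene_pmf(n_ind, n_minor):
    """Full enumeration of P(n_het | allele counts) from first principles:
    P(h) ∝ n! 2^h / (n_AA! h! n_aa!)."""
    probs = {}
    h = n_minor % 2
    while h <= n_minor:
        n_hom_minor = (n_minor - h) // 2
        n_hom_major = n_ind - h - n_hom_minor
        if n_hom_major >= 0:
            w = (math.factorial(n_ind) * 2 ** h
                 / (math.factorial(n_hom_minor) * math.factorial(h)
                    * math.factorial(n_hom_major)))
            probs[h] = w
        h += 2
    z = sum(probs.values())
    return {h: w / z for h, w in probs.items()}


@pytest.mark.parametrize("n_ind,n_minor", [(5, 3), (10, 7), (20, 20),
                                           (25, 13), (15, 2)])
def test_het_excess_matches_enumeration(n_ind, n_minor):
    pmf = levene_pmf(n_ind, n_minor)
    for h_obs in pmf:
        expected = sum(p for h, p in pmf.items() if h >= h_obs)
        got = gm.het_excess_pvalue(h_obs, n_ind, n_minor)
        assert got == pytest.approx(expected, abs=1e-12)


def test_all_heterozygous_site_removed():
    # 20 diploids all heterozygous: extreme excess, exact p < 0.01
    codes = np.ones((20, 1), dtype=np.int8)
    mat = make_matrix(codes)
    out, audit = gm.filter_sites(mat, gm.FilterRules())
    assert out.n_snps == 0
    assert audit.loc[0, "reason"] == "het_excess"
    assert gm.het_excess_pvalue(20, 20, 20) < 0.01


# ---------------------------------------------------------------------------
# call-rate and MAF thresholds
# ---------------------------------------------------------------------------

def test_call_rate_threshold_arithmetic():
    # 93 individuals: 9 missing -> 84/93 = 0.903 kept; 10 missing -> dropped
    codes = np.zeros((93, 2), dtype=np.int8)
    codes[0, 0] = 2  # keep polymorphic-ish, irrelevant for call rate
    codes[:9, 0] = MISSING
    codes[:10, 1] = MISSING
    mat = make_matrix(codes)
    out, audit = gm.filter_sites(mat, gm.FilterRules())
    assert audit.loc[0, "kept"]
    assert not audit.loc[1, "kept"] and audit.loc[1, "reason"] == "call_rate"


def test_maf_floor():
    # 93 diploids, 9/186 copies = 4.8% < 5% floor
    codes = np.zeros((93, 1), dtype=np.int8)
    codes[:9, 0] = 1
    mat = make_matrix(codes)
    out, audit = gm.filter_sites(mat, gm.FilterRules(maf_min=0.05))
    assert out.n_snps == 0 and audit.loc[0, "reason"] == "maf"


def test_all_missing_site_reason():
    codes = np.full((10, 1), MISSING, dtype=np.int8)
    _, audit = gm.filter_sites(make_matrix(codes), gm.FilterRules())
    assert audit.loc[0, "reason"] == "no_data"


def test_filter_idempotent(random_matrix):
    rules = gm.FilterRules(maf_min=0.05)
    once, _ = gm.filter_sites(random_matrix, rules)
    twice, audit = gm.filter_sites(once, rules)
    assert twice.snp_ids == once.snp_ids
    assert audit["kept"].all()


# ---------------------------------------------------------------------------
# thinning
# ---------------------------------------------------------------------------

def test_thin_keeps_lowest_offset():
    codes = np.zeros((4, 3), dtype=np.int8)
    codes[0] = [1, 1, 1]
    mat = make_matrix(codes, snp_ids=["a", "b", "c"])
    tags = make_tagmap(["a", "b", "c"], ["t1", "t1", "t1"], [40, 12, 101])
    out, kept = gm.thin_one_per_tag(mat, tags)
    assert kept == ["b"]


def test_thin_one_snp_per_tag_and_exclusions(rng):
    m = 50
    tag_ids = [f"t{j // 3}" for j in range(m)]
    offsets = rng.permutation(m) % 300
    ids = [f"s{j}" for j in range(m)]
    codes = rng.integers(0, 3, size=(6, m)).astype(np.int8)
    mat = make_matrix(codes, snp_ids=ids)
    tags = make_tagmap(ids, tag_ids, offsets)
    excl = set(ids[::7])
    out, kept = gm.thin_one_per_tag(mat, tags, exclude=excl)
    # brute-force oracle: group by tag, min (offset, id)
    df = tags.table[~tags.table["snp_id"].isin(excl)]
    oracle = set(df.sort_values(["offset", "snp_id"])
                 .groupby("tag_id").head(1)["snp_id"])
    assert set(kept) == oracle
    per_tag = df[df["snp_id"].isin(kept)].groupby("tag_id").size()
    assert (per_tag == 1).all()


# ---------------------------------------------------------------------------
# per-individual trimming
# ---------------------------------------------------------------------------

def test_drop_high_missing_schedule():
    # two sites of 20 and 19 -> trim schedule k=3 and k=2 leaves 17+17
    codes = np.zeros((39, 10), dtype=np.int8)
    for i in range(39):
        codes[i, :i % 5] = MISSING
    mat = make_matrix(codes, localities=[1] * 20 + [4] * 19,
                      habitats=["B"] * 20 + ["B"] * 19)
    out = gm.drop_high_missing_individuals(mat, {"1-B": 3, "4-B": 2})
    labels = out.site_labels()
    assert (labels == "1-B").sum() == 17 and (labels == "4-B").sum() == 17


def test_drop_zero_is_identity(random_matrix):
    out = gm.drop_high_missing_individuals(random_matrix, {"1-B": 0})
    assert out.n_individuals == random_matrix.n_individuals


def test_drop_tie_broken_by_id():
    codes = np.zeros((4, 4), dtype=np.int8)
    codes[1, :2] = MISSING   # ind001: 2 missing
    codes[3, :2] = MISSING   # ind003: 2 missing (tie)
    mat = make_matrix(codes, habitats=["B"] * 4)
    out = gm.drop_high_missing_individuals(mat, {"1-B": 1})
    assert "ind001" not in set(out.samples["individual"])
    assert "ind003" in set(out.samples["individual"])


# ---------------------------------------------------------------------------
# joint folded SFS
# ---------------------------------------------------------------------------

def brute_force_fold(c1, c2, n1h, n2h):
    tot, ncop = c1 + c2, n1h + n2h
    if 2 * tot > ncop:
        return n1h - c1, n2h - c2
    if 2 * tot == ncop and 2 * c1 > n1h:
        return n1h - c1, n2h - c2
    return c1, c2


def test_fold_example_past_half():
    # 4+4 haploid copies, alt copies (3,3): total 6 > 4 -> (1,1)
    arr = np.zeros((5, 5))
    arr[3, 3] = 1
    out = gm.fold_joint(arr)
    assert out[1, 1] == 1 and out.sum() == 1


def test_monomorphic_only_matrix():
    codes = np.zeros((6, 5), dtype=np.int8)
    mat = make_matrix(codes)
    sfs = gm.joint_folded_sfs(mat, mat.samples["habitat"].to_numpy())
    assert sfs.counts.sum() == 0 and sfs.n_monomorphic == 5


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_sfs_equals_per_snp_oracle(seed):
    r = np.random.default_rng(seed)
    n1, n2 = 3, 3
    codes = r.integers(0, 3, size=(n1 + n2, 30)).astype(np.int8)
    mat = make_matrix(codes)
    labels = mat.samples["habitat"].to_numpy()
    sfs = gm.joint_folded_sfs(mat, labels)
    oracle = np.zeros((2 * n1 + 1, 2 * n2 + 1))
    mono = 0
    for j in range(30):
        c1 = int(codes[labels == "B", j].sum())
        c2 = int(codes[labels == "I", j].sum())
        if c1 + c2 == 0 or c1 + c2 == 2 * (n1 + n2):
            mono += 1
            continue
        f1, f2 = brute_force_fold(c1, c2, 2 * n1, 2 * n2)
        oracle[f1, f2] += 1
    assert np.array_equal(sfs.counts, oracle)
    assert sfs.n_monomorphic == mono
    # conservation: all complete-case SNPs accounted for
    assert sfs.counts.sum() + sfs.n_monomorphic == 30


def test_sfs_conservation_with_missingness(random_matrix):
    labels = random_matrix.samples["habitat"].to_numpy()
    sfs = gm.joint_folded_sfs(random_matrix, labels)
    complete = (random_matrix.codes != MISSING).all(axis=0)
    assert sfs.counts.sum() + sfs.n_monomorphic == complete.sum()


# ---------------------------------------------------------------------------
# monomorphic extrapolation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("total,master,filt,n,used,mono", [
    (1_000_000, 50_000, 10_000, 10_000, 200_000, 190_000),
    (600_000, 4_000, 4_000, 150, 600_000, 599_850),   # filtered == master
    (600_000, 4_000, 2_000, 0, 300_000, 300_000),     # n_snps = 0
])
def test_estimate_monomorphic(total, master, filt, n, used, mono):
    est = gm.estimate_monomorphic(total, master, filt, n)
    assert est.used_sites == used
    assert est.n_monomorphic == mono


def test_estimate_monomorphic_zero_master():
    with pytest.raises(ValueError):
        gm.estimate_monomorphic(1000, 0, 0, 0)
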