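"""Genotype-matrix filters, dataset roles, and the joint folded SFS.

The matrix-level cleaning chain applied to GBS SNP calls:

1. per-site filters — call rate >= 0.90, removal of sites with significant
   heterozygote *excess* (one-sided exact Hardy–Weinberg test at the 1%
   level; excess heterozygosity is the signature of collapsed paralogs),
   optional minor-allele-frequency floor;
2. per-individual trimming — drop the individuals with most missing
   genotypes per site sample;
3. thinning to one SNP per tag (lowest offset), optionally excluding a list
   of outlier SNPs first, to build quasi-independent ("INDSNP") datasets;
4. joint folded site-frequency-spectrum construction from complete-case
   SNPs, folded on the global minor allele, plus a monomorphic-site count
   extrapolated from the filtering attrition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import MISSING, GenotypeMatrix, TagMap

__all__ = [
    "FilterRules", "JointFoldedSFS", "MonomorphicEstimate",
    "filter_sites", "thin_one_per_tag", "drop_high_missing_individuals",
    "joint_folded_sfs", "estimate_monomorphic", "het_excess_pvalue",
    "fold_joint",
]


@dataclass(frozen=True)
class FilterRules:
    min_call_rate: float = 0.90
    hwe_alpha: float = 0.01
    maf_min: float | None = None

    def __post_init__(self):
        for name in ("min_call_rate", "hwe_alpha"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.maf_min is not None and not (0.0 < self.maf_min <= 1.0):
            raise ValueError("maf_min must be in (0, 1]")


def het_excess_pvalue(n_het: int, n_ind: int, n_minor: int) -> float:
    """One-sided exact probability of >= ``n_het`` heterozygotes.

    Conditional on ``n_minor`` minor-allele copies among ``n_ind`` diploids
    (Levene's exact distribution): P(h) ∝ n! 2^h / (nAA! h! naa!), h with the
    parity of n_minor.  Small n, so the full enumeration is cheap.
    """
    if n_ind == 0:
        return 1.0
    n_major = 2 * n_ind - n_minor
    if n_minor > n_major:  # symmetric in allele labels
        n_minor, n_major = n_major, n_minor
    lg = math.lgamma
    log_probs = {}
    h = n_minor % 2
    while h <= n_minor:
        n_hom_minor = (n_minor - h) // 2
        n_hom_major = n_ind - h - n_hom_minor
        if n_hom_major >= 0:
            # h-dependent part of log P(h); constants cancel on normalization
            log_probs[h] = (h * math.log(2) - lg(n_hom_minor + 1)
                            - lg(h + 1) - lg(n_hom_major + 1))
        h += 2
    if not log_probs:
        return 1.0
    mx = max(log_probs.values())
    z = {h: math.exp(v - mx) for h, v in log_probs.items()}
    total = sum(z.values())
    obs = sum(v for h, v in z.items() if h >= n_het)
    return min(1.0, obs / total)


def filter_sites(matrix: GenotypeMatrix, rules: FilterRules):
    """Apply per-site filters; returns (filtered matrix, audit DataFrame).

    The audit log has one row per input SNP with the retained flag and the
    first failing rule among {no_data, call_rate, het_excess, maf}.  Columns
    for upstream read-level filters (read depth, alternate-allele strength)
    are carried as empty placeholders so externally filtered call sets can be
    merged into the same schema.
    """
    codes = matrix.codes
    n_ind = matrix.n_individuals
    called = codes != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / n_ind
    n_het = (codes == 1).sum(axis=0)
    alt = np.where(called, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called > 0, alt / (2 * n_called), np.nan)
    maf = np.minimum(p_alt, 1 - p_alt)

    reasons = []
    keep = np.zeros(matrix.n_snps, dtype=bool)
    for j in range(matrix.n_snps):
        if n_called[j] == 0:
            reasons.append("no_data")
            continue
        if call_rate[j] < rules.min_call_rate:
            reasons.append("call_rate")
            continue
        n_minor = int(min(alt[j], 2 * n_called[j] - alt[j]))
        p = het_excess_pvalue(int(n_het[j]), int(n_called[j]), n_minor)
        if p < rules.hwe_alpha:
            reasons.append("het_excess")
            continue
        if rules.maf_min is not None and maf[j] < rules.maf_min:
            reasons.append("maf")
            continue
        reasons.append("")
        keep[j] = True

    audit = pd.DataFrame({
        "snp_id": matrix.snp_ids,
        "kept": keep,
        "reason": reasons,
        "call_rate": call_rate,
        "maf": maf,
        "upstream_avg_depth": pd.NA,   # read-level filters happen upstream
        "upstream_alt_strength": pd.NA,
    })
    kept_ids = [s for s, k in zip(matrix.snp_ids, keep) if k]
    return matrix.subset_snps(kept_ids), audit


def thin_one_per_tag(matrix: GenotypeMatrix, tags: TagMap,
                     exclude=()):
    """Keep the lowest-offset SNP per tag after dropping ``exclude`` ids.

    Tags left empty by the exclusion are dropped.  Returns (matrix', kept ids).
    """
    exclude = set(exclude)
    tab = tags.table[tags.table["snp_id"].isin(set(matrix.snp_ids))]
    tab = tab[~tab["snp_id"].isin(exclude)]
    if tab.empty:
        return matrix.subset_snps([]), []
    idx = tab.sort_values(["tag_id", "offset", "snp_id"]).groupby("tag_id").head(1)
    order = {s: i for i, s in enumerate(matrix.snp_ids)}
    kept = sorted(idx["snp_id"], key=order.get)
    return matrix.subset_snps(kept), kept


def drop_high_missing_individuals(matrix: GenotypeMatrix, per_site_k: dict):
    """Remove the k most-missing individuals per site sample.

    ``per_site_k`` maps site label ('<locality>-<habitat>') to the number of
    individuals to remove; ties on missingness are broken by individual id
    order (the lower id is removed).
    """
    sites = matrix.site_labels()
    miss_counts = (matrix.codes == MISSING).sum(axis=1)
    ids = matrix.samples["individual"].to_numpy()
    keep = np.ones(matrix.n_individuals, dtype=bool)
    for site, k in per_site_k.items():
        members = np.flatnonzero(sites == site)
        if k > len(members):
            raise ValueError(f"k={k} exceeds {len(members)} individuals at {site}")
        if k == 0:
            continue
        order = sorted(members, key=lambda i: (-miss_counts[i], ids[i]))
        keep[order[:k]] = False
    return matrix.subset_individuals(keep)


def fold_joint(arr: np.ndarray) -> np.ndarray:
    """Fold a joint (n1h+1) x (n2h+1) array on the global minor allele.

    Cell (c1, c2) with total count past half the copies is added to its
    mirror (n1h-c1, n2h-c2); the exact-half class keeps the orientation with
    population-1 count <= n1h/2, retaining the original orientation on the
    population-1 tie.  Works for counts or probability mass alike.
    """
    arr = np.asarray(arr, dtype=float)
    n1h = arr.shape[0] - 1
    n2h = arr.shape[1] - 1
    half = (n1h + n2h) / 2.0
    out = np.zeros_like(arr)
    for c1 in range(n1h + 1):
        for c2 in range(n2h + 1):
            if arr[c1, c2] == 0:
                continue
            tot = c1 + c2
            if tot < half:
                out[c1, c2] += arr[c1, c2]
            elif tot > half:
                out[n1h - c1, n2h - c2] += arr[c1, c2]
            else:  # exactly half the copies: orient by population-1 count
                if c1 > n1h / 2.0:
                    out[n1h - c1, n2h - c2] += arr[c1, c2]
                else:
                    out[c1, c2] += arr[c1, c2]
    return out


@dataclass
class JointFoldedSFS:
    """Joint folded SFS: counts[c1, c2] = SNPs with (c1, c2) minor-allele
    copies in populations 1 and 2 (diploid sample sizes n1, n2), plus the
    monomorphic-site count for the composite-likelihood monomorphic class."""

    counts: np.ndarray
    n1: int
    n2: int
    n_monomorphic: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2 * self.n1 + 1, 2 * self.n2 + 1):
            raise ValueError("counts shape must be (2*n1+1, 2*n2+1)")
        if (self.counts < 0).any() or self.n_monomorphic < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_polymorphic(self):
        return float(self.counts.sum())

    def flat_with_monomorphic(self):
        """1-D observation vector: polymorphic cells then the monomorphic
        class (the (0,0) cell is excluded from the polymorphic part)."""
        c = self.counts.copy()
        mono_in_cell = c[0, 0]
        c[0, 0] = 0.0
        return np.concatenate([c.ravel(),
                               [self.n_monomorphic + mono_in_cell]])


def joint_folded_sfs(matrix: GenotypeMatrix, pop_labels,
                     n_monomorphic: int = 0) -> JointFoldedSFS:
    """Build the joint folded SFS from complete-case SNPs of two populations.

    ``pop_labels`` assigns each individual to population 0 or 1 (any two
    distinct labels; sorted order defines pop 1 vs pop 2).  SNPs with any
    missing genotype are excluded; monomorphic complete-case SNPs are added
    to ``n_monomorphic``.
    """
    pop_labels = np.asarray(pop_labels)
    levels = np.unique(pop_labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly two populations, got {levels}")
    in1 = pop_labels == levels[0]
    in2 = pop_labels == levels[1]
    n1, n2 = int(in1.sum()), int(in2.sum())
    codes = matrix.codes
    complete = (codes != MISSING).all(axis=0)
    c1 = codes[in1][:, complete].sum(axis=0)
    c2 = codes[in2][:, complete].sum(axis=0)
    tot = c1 + c2
    ncop = 2 * (n1 + n2)
    poly = (tot > 0) & (tot < ncop)
    mono_extra = int((~poly).sum())
    unfolded = np.zeros((2 * n1 + 1, 2 * n2 + 1))
    np.add.at(unfolded, (c1[poly], c2[poly]), 1.0)
    folded = fold_joint(unfolded)
    return JointFoldedSFS(folded, n1, n2,
                          n_monomorphic=n_monomorphic + mono_extra)


@dataclass(frozen=True)
class MonomorphicEstimate:
    total_sites_sequenced: int
    master_snp_count: int
    filtered_snp_count: int
    used_sites: int
    n_monomorphic: int


def estimate_monomorphic(total_sites: int, master_count: int,
                         filtered_count: int, n_snps: int) -> MonomorphicEstimate:
    """Extrapolate the monomorphic-site count from SNP-filtering attrition.

    The reduction from the master SNP matrix to the filtered set is assumed
    to mirror the reduction from all sequenced sites to the sites actually
    used: used = total * filtered/master (rounded), monomorphic = used -
    n_snps.
    """
    if master_count == 0:
        raise ValueError("master_count must be positive")
    if not (master_count >= filtered_count >= 0 and n_snps >= 0):
        raise ValueError("require master_count >= filtered_count >= 0")
    used = int(round(total_sites * filtered_count / master_count))
    mono = used - n_snps
    if mono < 0:
        raise ValueError("negative monomorphic estimate; check inputs")
    return MonomorphicEstimate(total_sites, master_count, filtered_count,
                               used, mono)
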