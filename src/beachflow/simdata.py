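"""Synthetic-data engine: structured-coalescent genotypes, spiked selected
loci, and phenotype (landmark / colour) samples.

The demographic models describe a beach/inland habitat pair that split from a
single ancestral population ``T_div`` generations ago:

* ``NOGFLOW``   — divergence with no subsequent migration,
* ``ONEGFLOW``  — divergence followed by constant bidirectional migration,
* ``TWOGFLOW``  — divergence followed by two successive migration epochs, the
  rates switching ``T_recent`` generations before the present.

Migration rates are stated *forwards in time*: ``m_BI`` is the per-generation
probability that a lineage in the beach habitat moves to the inland habitat.
The simulator runs backwards, so a lineage currently in deme X jumps to deme Y
at the forwards rate Y->X; the swap is handled internally.

Genotype datasets mimic a genotyping-by-sequencing design: independent 300-bp
tags (one genealogy each, no within-tag recombination), infinite-sites
mutations at rate ``mu`` per site per generation, diploids formed by pairing
haploid samples within a deme, and i.i.d. missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _coalescent

MISSING = -1

MODEL_KINDS = ("NOGFLOW", "ONEGFLOW", "TWOGFLOW")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemographicParams:
    """Full parameter set of the two-deme divergence/gene-flow models.

    Sizes are diploid effective sizes; times are generations before present;
    migration rates are forwards-in-time per-generation per-lineage
    probabilities.  ``years_per_generation`` is reporting-only (default 2.1,
    a wall-lizard estimate).
    """

    model_kind: str
    N_beach: float
    N_inland: float
    N_ancestral: float
    T_div: float
    T_recent: float = 0.0
    m_BI_anc: float = 0.0
    m_IB_anc: float = 0.0
    m_BI_rec: float = 0.0
    m_IB_rec: float = 0.0
    mu: float = 1e-8
    years_per_generation: float = 2.1

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        for name in ("N_beach", "N_inland", "N_ancestral"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 1:
                raise ValueError(f"{name} must be finite and >= 1, got {v}")
        for name in ("m_BI_anc", "m_IB_anc", "m_BI_rec", "m_IB_rec"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not np.isfinite(self.T_div) or self.T_div < 0:
            raise ValueError("T_div must be finite and >= 0")
        if self.mu < 0 or not np.isfinite(self.mu):
            raise ValueError("mu must be finite and >= 0")
        if self.model_kind == "NOGFLOW":
            if any(getattr(self, n) != 0.0 for n in
                   ("m_BI_anc", "m_IB_anc", "m_BI_rec", "m_IB_rec")):
                raise ValueError("NOGFLOW requires all migration rates = 0")
        if self.model_kind == "ONEGFLOW":
            if self.m_BI_anc != self.m_BI_rec or self.m_IB_anc != self.m_IB_rec:
                raise ValueError("ONEGFLOW requires ancient == recent rates")
        if self.model_kind == "TWOGFLOW":
            if not (0.0 < self.T_recent < self.T_div):
                raise ValueError("TWOGFLOW requires 0 < T_recent < T_div")

    @classmethod
    def nogflow(cls, N_beach, N_inland, N_ancestral, T_div, mu=1e-8, **kw):
        return cls("NOGFLOW", N_beach, N_inland, N_ancestral, T_div, mu=mu, **kw)

    @classmethod
    def onegflow(cls, N_beach, N_inland, N_ancestral, T_div, m_BI, m_IB,
                 mu=1e-8, **kw):
        return cls("ONEGFLOW", N_beach, N_inland, N_ancestral, T_div,
                   m_BI_anc=m_BI, m_IB_anc=m_IB, m_BI_rec=m_BI, m_IB_rec=m_IB,
                   mu=mu, **kw)

    @classmethod
    def twogflow(cls, N_beach, N_inland, N_ancestral, T_div, T_recent,
                 m_BI_anc, m_IB_anc, m_BI_rec, m_IB_rec, mu=1e-8, **kw):
        return cls("TWOGFLOW", N_beach, N_inland, N_ancestral, T_div,
                   T_recent=T_recent, m_BI_anc=m_BI_anc, m_IB_anc=m_IB_anc,
                   m_BI_rec=m_BI_rec, m_IB_rec=m_IB_rec, mu=mu, **kw)

    def backwards_rates(self):
        """(beach-lineage jump rate, inland-lineage jump rate) per epoch.

        Backwards-in-time jump rate of a lineage in deme X equals the
        forwards migration rate Y->X.  Returns
        ((mb_rec, mi_rec), (mb_anc, mi_anc)).
        """
        return ((self.m_IB_rec, self.m_BI_rec),
                (self.m_IB_anc, self.m_BI_anc))

    def _kernel_args(self):
        (mb_rec, mi_rec), (mb_anc, mi_anc) = self.backwards_rates()
        t_rec = self.T_recent if self.model_kind == "TWOGFLOW" else 0.0
        return (float(self.N_beach), float(self.N_inland),
                float(self.N_ancestral), float(self.T_div), float(t_rec),
                float(mb_rec), float(mi_rec), float(mb_anc), float(mi_anc))


def study_scale_params() -> DemographicParams:
    """Default study-scale TWOGFLOW parameters.

    Times and migration rates follow the reported locality-level estimates
    (divergence a few 1e5 generations ago; recent epoch ~1e3 generations with
    migration probabilities ~1e-3, ancient-epoch rates orders of magnitude
    lower and inland->beach exceeding beach->inland); effective sizes are not
    reported and are set to 5e4 diploids, which at mu = 1e-8 gives a realistic
    GBS SNP yield of several SNPs per 300-bp tag.
    """
    return DemographicParams.twogflow(
        N_beach=5e4, N_inland=5e4, N_ancestral=5e4,
        T_div=2.5e5, T_recent=1.2e3,
        m_BI_anc=1e-6, m_IB_anc=3.6e-5,
        m_BI_rec=9.8e-4, m_IB_rec=1.1e-3,
        mu=1e-8,
    )


@dataclass(frozen=True)
class SimConfig:
    """Sampling design for one habitat pair."""

    n_diploids_beach: int = 12
    n_diploids_inland: int = 12
    n_contigs: int = 4000
    contig_length: int = 300
    seed: int = 0
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.contig_length < 1:
            raise ValueError("contig_length must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_diploids_beach < 1 or self.n_diploids_inland < 1:
            raise ValueError("need at least one diploid per habitat")


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class TagMap:
    """SNP -> (tag, 0-based offset within the tag contig) assignment."""

    table: pd.DataFrame  # columns: snp_id, tag_id, offset
    contig_length: int = 300
    tag_ids: list = field(default_factory=list)  # all tags, incl. 0-SNP tags

    def __post_init__(self):
        need = {"snp_id", "tag_id", "offset"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"TagMap table needs columns {sorted(need)}")
        if len(self.table) and self.table["offset"].max() >= self.contig_length:
            raise ValueError("offset beyond contig length")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("a SNP may belong to exactly one tag")
        if not self.tag_ids:
            self.tag_ids = sorted(self.table["tag_id"].unique().tolist())

    def tag_of(self, snp_id):
        row = self.table.loc[self.table["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(snp_id)
        return row["tag_id"].iloc[0]

    def subset(self, snp_ids):
        keep = self.table[self.table["snp_id"].isin(set(snp_ids))]
        return TagMap(keep.reset_index(drop=True), self.contig_length,
                      tag_ids=list(self.tag_ids))


@dataclass
class GenotypeMatrix:
    """Diploid genotype codes (0/1/2, -1 = missing), individuals x SNPs.

    ``samples`` carries one row per individual with columns
    ``individual``, ``locality``, ``habitat`` ('B' or 'I').
    """

    codes: np.ndarray
    samples: pd.DataFrame
    snp_ids: list

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.snp_ids)):
            raise ValueError("codes shape inconsistent with samples/snp_ids")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or -1 (missing)")

    @property
    def n_individuals(self):
        return self.codes.shape[0]

    @property
    def n_snps(self):
        return self.codes.shape[1]

    def site_labels(self):
        return (self.samples["locality"].astype(str) + "-"
                + self.samples["habitat"].astype(str)).to_numpy()

    def subset_snps(self, snp_ids):
        order = {s: i for i, s in enumerate(self.snp_ids)}
        cols = [order[s] for s in snp_ids]
        return GenotypeMatrix(self.codes[:, cols], self.samples.copy(),
                              list(snp_ids))

    def subset_individuals(self, keep_mask):
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return GenotypeMatrix(self.codes[keep_mask],
                              self.samples.loc[keep_mask].reset_index(drop=True),
                              list(self.snp_ids))

    def allele_freq(self):
        """Alternate-allele frequency per SNP over called genotypes."""
        called = self.codes != MISSING
        alt = np.where(called, self.codes, 0).sum(axis=0)
        tot = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / tot, np.nan)


# ---------------------------------------------------------------------------
# genealogy sampling
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """Binary coalescent tree over n_b + n_i haploid samples.

    Leaves 0..n_b-1 are beach copies, n_b..n-1 inland; internal nodes follow
    in coalescence order.  ``node_deme`` is the deme each node was created in.
    """

    parent: np.ndarray
    node_time: np.ndarray
    node_deme: np.ndarray
    n_beach: int
    n_inland: int
    n_migrations: int

    @property
    def n_leaves(self):
        return self.n_beach + self.n_inland

    @property
    def tmrca(self):
        return float(self.node_time[-1])

    def branch_lengths(self):
        """Length of the branch above each non-root node."""
        bl = np.zeros(len(self.parent))
        has_parent = self.parent >= 0
        bl[has_parent] = (self.node_time[self.parent[has_parent]]
                          - self.node_time[has_parent])
        return bl

    @property
    def total_branch_length(self):
        return float(self.branch_lengths().sum())

    def leaf_masks(self):
        """Boolean (n_nodes, n_leaves): leaves descending from each node."""
        n = self.n_leaves
        masks = np.zeros((len(self.parent), n), dtype=bool)
        masks[np.arange(n), np.arange(n)] = True
        for child in range(len(self.parent)):  # children precede parents
            p = self.parent[child]
            if p >= 0:
                masks[p] |= masks[child]
        return masks


def sample_genealogy(params: DemographicParams, n_b: int, n_i: int,
                     rng) -> Genealogy:
    """Draw one structured-coalescent genealogy for ``n_b`` beach and ``n_i``
    inland haploid samples under ``params``.  ``rng`` is a
    :class:`numpy.random.Generator` or an integer seed."""
    if n_b < 1 or n_i < 0 or n_b + n_i < 2:
        raise ValueError("need at least two haploid samples, n_b >= 1")
    seed = _seed_from(rng)
    parent, times, demes, _, _, nmig = _coalescent.genealogy_once(
        n_b, n_i, *params._kernel_args(), seed)
    return Genealogy(parent, times, demes, n_b, n_i, int(nmig))


def _seed_from(rng):
    if isinstance(rng, (int, np.integer)):
        return int(rng) % (2**31 - 1)
    return int(rng.integers(0, 2**31 - 1))


def class_branch_lengths(params: DemographicParams, n_b: int, n_i: int,
                         n_sims: int, seed: int) -> np.ndarray:
    """Mean branch length (generations) ancestral to exactly (k_b, k_i)
    sampled copies, over ``n_sims`` genealogies; shape (n_b+1, n_i+1)."""
    T = _coalescent.class_times_batch(n_b, n_i, *params._kernel_args(),
                                      n_sims, int(seed) % (2**31 - 1))
    return T.reshape(n_b + 1, n_i + 1) / n_sims


def tmrca_sample(params: DemographicParams, n_b: int, n_i: int,
                 n_sims: int, seed: int):
    """(tmrca, total_branch_length) draws; Monte-Carlo workhorse for tests."""
    return _coalescent.tmrca_batch(n_b, n_i, *params._kernel_args(),
                                   n_sims, int(seed) % (2**31 - 1))


# ---------------------------------------------------------------------------
# genotype dataset simulation
# ---------------------------------------------------------------------------

def simulate_dataset(params: DemographicParams, config: SimConfig):
    """Simulate a GBS-style genotype dataset for one habitat pair.

    One independent genealogy per 300-bp contig; Poisson(mu * L * total branch
    length) mutations placed on branches proportionally to length, at distinct
    sites within the contig (collisions redrawn); diploids formed by pairing
    consecutive haploids within each deme.  Returns (GenotypeMatrix, TagMap).
    """
    rng = np.random.default_rng(config.seed)
    n_b = 2 * config.n_diploids_beach
    n_i = 2 * config.n_diploids_inland
    n_dip = config.n_diploids_beach + config.n_diploids_inland
    L = config.contig_length

    geno_cols = []
    snp_ids = []
    rows = []
    for tag in range(config.n_contigs):
        g = sample_genealogy(params, n_b, n_i, rng)
        bl = g.branch_lengths()
        total = bl.sum()
        n_mut = rng.poisson(params.mu * L * total) if params.mu > 0 else 0
        if n_mut == 0:
            continue
        if n_mut > L:
            raise ValueError(
                f"contig {tag}: {n_mut} mutations exceed contig length {L}")
        masks = g.leaf_masks()
        branches = rng.choice(len(bl), size=n_mut, p=bl / total)
        offsets = set()
        for b in branches:
            off = int(rng.integers(L))
            while off in offsets:  # collision: redraw the site position
                off = int(rng.integers(L))
            offsets.add(off)
            hap = masks[b].astype(np.int8)
            dip = hap[0::2] + hap[1::2]
            geno_cols.append(dip)
            sid = f"t{tag:05d}_s{off:03d}"
            snp_ids.append(sid)
            rows.append((sid, f"tag{tag:05d}", off))

    codes = (np.stack(geno_cols, axis=1) if geno_cols
             else np.zeros((n_dip, 0), dtype=np.int8))
    if config.missing_rate > 0 and codes.size:
        miss = rng.random(codes.shape) < config.missing_rate
        codes = np.where(miss, MISSING, codes).astype(np.int8)

    samples = pd.DataFrame({
        "individual": ([f"B{i:03d}" for i in range(config.n_diploids_beach)]
                       + [f"I{i:03d}" for i in range(config.n_diploids_inland)]),
        "locality": 1,
        "habitat": (["B"] * config.n_diploids_beach
                    + ["I"] * config.n_diploids_inland),
    })
    tag_table = pd.DataFrame(rows, columns=["snp_id", "tag_id", "offset"])
    all_tags = [f"tag{t:05d}" for t in range(config.n_contigs)]
    tags = TagMap(tag_table, contig_length=L, tag_ids=all_tags)
    # sort SNP columns by (tag, offset) for deterministic, position-ordered ids
    order = np.lexsort((tag_table["offset"].to_numpy(),
                        tag_table["tag_id"].to_numpy())) if len(tag_table) else []
    if len(tag_table):
        codes = codes[:, order]
        snp_ids = [snp_ids[i] for i in order]
        tags.table = tag_table.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(codes, samples, snp_ids), tags


def simulate_study(params: DemographicParams, n_localities: int = 4,
                   diploids_per_site=(12, 9, 14, 10), n_contigs: int = 4000,
                   missing_rate: float = 0.02, seed: int = 0):
    """Four-locality study design: independent habitat pairs sharing one
    demographic model.  Returns {locality: (GenotypeMatrix, TagMap)} with
    locality labels 1..n and ~9-14 genotyped diploids per site."""
    ss = np.random.SeedSequence(seed)
    out = {}
    child = ss.spawn(n_localities)
    for loc in range(1, n_localities + 1):
        n_dip = diploids_per_site[(loc - 1) % len(diploids_per_site)]
        cfg = SimConfig(n_diploids_beach=n_dip, n_diploids_inland=n_dip,
                        n_contigs=n_contigs, missing_rate=missing_rate,
                        seed=int(child[loc - 1].generate_state(1)[0] % (2**31)))
        mat, tags = simulate_dataset(params, cfg)
        mat.samples["locality"] = loc
        mat.samples["individual"] = [f"L{loc}{h}{i:03d}" for i, h in
                                     enumerate(mat.samples["habitat"])]
        out[loc] = (mat, tags)
    return out


def simulate_island_matrix(n_localities=4, diploids_per_site=12, n_snps=5000,
                           fst_locality=0.03, fst_habitat=0.005, seed=0,
                           missing_rate=0.0):
    """Hierarchical allele-frequency generator for structure analyses.

    Ancestral frequencies are uniform on [0.05, 0.95]; locality frequencies
    drift around them (Balding–Nichols beta with F = fst_locality) and the
    B/I site frequencies drift around the locality value (F = fst_habitat);
    genotypes are binomial(2, p).  This emulates an eight-site island survey
    (weak locality structure, even weaker habitat structure) where the
    two-deme coalescent does not apply; used for scan/structure stages.
    """
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.95, n_snps)

    def drift(p, F):
        if F <= 0:
            return np.array(p, copy=True)
        a = p * (1 - F) / F
        b = (1 - p) * (1 - F) / F
        return rng.beta(np.maximum(a, 1e-3), np.maximum(b, 1e-3))

    codes = []
    recs = []
    for loc in range(1, n_localities + 1):
        p_loc = drift(p0, fst_locality)
        for hab in ("B", "I"):
            p_site = drift(p_loc, fst_habitat)
            g = rng.binomial(2, p_site,
                             size=(diploids_per_site, n_snps)).astype(np.int8)
            codes.append(g)
            for i in range(diploids_per_site):
                recs.append((f"L{loc}{hab}{i:03d}", loc, hab))
    codes = np.concatenate(codes, axis=0)
    if missing_rate > 0:
        miss = rng.random(codes.shape) < missing_rate
        codes = np.where(miss, MISSING, codes).astype(np.int8)
    samples = pd.DataFrame(recs, columns=["individual", "locality", "habitat"])
    snp_ids = [f"snp{j:05d}" for j in range(n_snps)]
    mat = GenotypeMatrix(codes, samples, snp_ids)
    tag_table = pd.DataFrame({"snp_id": snp_ids,
                              "tag_id": [f"tag{j:05d}" for j in range(n_snps)],
                              "offset": 0})
    return mat, TagMap(tag_table, contig_length=300)


def spike_outlier_loci(matrix: GenotypeMatrix, habitat_labels, tags: TagMap,
                       n_loci: int, delta_p: float, rng):
    """Inject habitat-differentiated loci: at ``n_loci`` SNPs (one per tag)
    genotypes are redrawn binomially with beach frequency p + delta_p/2 and
    inland frequency p - delta_p/2 (clamped to [0, 1]).  Returns a new matrix
    and the spiked SNP ids."""
    if not (0.0 <= delta_p <= 1.0):
        raise ValueError("delta_p must be in [0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    habitat_labels = np.asarray(habitat_labels)
    tag_groups = tags.table.groupby("tag_id")["snp_id"].first()
    if n_loci > len(tag_groups):
        raise ValueError(f"n_loci={n_loci} exceeds tag count {len(tag_groups)}")
    chosen_tags = rng.choice(tag_groups.index.to_numpy(), size=n_loci,
                             replace=False)
    spiked = [tag_groups[t] for t in chosen_tags]

    codes = matrix.codes.copy()
    col_of = {s: j for j, s in enumerate(matrix.snp_ids)}
    is_beach = habitat_labels == "B"
    freqs = matrix.allele_freq()
    for sid in spiked:
        j = col_of[sid]
        p = freqs[j] if np.isfinite(freqs[j]) else 0.5
        p_b = min(1.0, max(0.0, p + delta_p / 2))
        p_i = min(1.0, max(0.0, p - delta_p / 2))
        miss = codes[:, j] == MISSING
        new = np.where(is_beach, rng.binomial(2, p_b, matrix.n_individuals),
                       rng.binomial(2, p_i, matrix.n_individuals)).astype(np.int8)
        new[miss] = MISSING
        codes[:, j] = new
    return GenotypeMatrix(codes, matrix.samples.copy(), list(matrix.snp_ids)), \
        list(spiked)


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeSimSpec:
    """Landmark and colour generator settings for a two-habitat contrast.

    ``habitat_displacement`` is added to the beach group's mean landmark
    configuration; colours are 6-character RGB means per group with a shared
    covariance."""

    mean_shape: np.ndarray                 # (k, 2)
    habitat_displacement: np.ndarray       # (k, 2)
    landmark_noise_sd: float = 0.01
    colour_mean_beach: np.ndarray = None   # (n_characters * 3,)
    colour_mean_inland: np.ndarray = None
    colour_cov: np.ndarray = None
    n_per_group: int = 25

    def __post_init__(self):
        ms = np.asarray(self.mean_shape, float)
        if ms.ndim != 2 or ms.shape[1] != 2:
            raise ValueError("mean_shape must be (k, 2)")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be >= 0")
        if self.colour_cov is not None:
            c = np.asarray(self.colour_cov, float)
            if not np.allclose(c, c.T):
                raise ValueError("colour_cov must be symmetric")
            w = np.linalg.eigvalsh(c)
            if w.min() < -1e-8:
                raise ValueError("colour_cov must be positive semidefinite")


def default_phenotype_spec(n_per_group=25):
    """Lizard-head-like defaults: a 10-landmark bilaterally symmetric outline,
    a snout-widening beach displacement, and darker beach RGB means."""
    xs = np.array([0.0, 0.3, 0.6, 0.9, 1.0])
    half = np.column_stack([xs, np.array([0.5, 0.45, 0.4, 0.25, 0.0])])
    mean = np.vstack([half, half * np.array([1.0, -1.0])])  # mirrored halves
    disp = np.zeros_like(mean)
    disp[[3, 8], 1] = [0.06, -0.06]  # wider snout at the beach
    n_resp = 18  # 6 characters x RGB
    cm_inland = np.full(n_resp, 60.0)
    cm_beach = np.full(n_resp, 45.0)  # darker dorsa on shingle
    cov = np.eye(n_resp) * 36.0
    return PhenotypeSimSpec(mean, disp, landmark_noise_sd=0.01,
                            colour_mean_beach=cm_beach,
                            colour_mean_inland=cm_inland,
                            colour_cov=cov, n_per_group=n_per_group)


def simulate_phenotypes(spec: PhenotypeSimSpec, rng, n_localities=4):
    """Draw landmark configurations and colour tables for paired B/I groups.

    Returns (landmarks (n_spec, k, 2), colour DataFrame) with ``habitat`` and
    ``locality`` columns; beach specimens get the mean-shape displacement."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    mean = np.asarray(spec.mean_shape, float)
    disp = np.asarray(spec.habitat_displacement, float)
    k = mean.shape[0]
    configs = []
    recs = []
    colours = []
    for loc in range(1, n_localities + 1):
        for hab in ("B", "I"):
            base = mean + (disp if hab == "B" else 0.0)
            noise = rng.normal(0.0, spec.landmark_noise_sd,
                               (spec.n_per_group, k, 2))
            configs.append(base[None, :, :] + noise)
            if spec.colour_cov is not None:
                cm = (spec.colour_mean_beach if hab == "B"
                      else spec.colour_mean_inland)
                colours.append(rng.multivariate_normal(
                    cm, spec.colour_cov, spec.n_per_group))
            for i in range(spec.n_per_group):
                recs.append((f"L{loc}{hab}{i:03d}", loc, hab))
    landmarks = np.concatenate(configs, axis=0)
    meta = pd.DataFrame(recs, columns=["specimen", "locality", "habitat"])
    colour_df = meta.copy()
    if colours:
        cmat = np.concatenate(colours, axis=0)
        cmat = np.clip(cmat, 1e-3, None)  # luminances are positive
        for j in range(cmat.shape[1]):
            ch = "RGB"[j % 3]
            colour_df[f"c{j // 3 + 1}_{ch}"] = cmat[:, j]
    return landmarks, meta, colour_df
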