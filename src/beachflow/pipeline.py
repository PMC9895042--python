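"""Config-driven end-to-end orchestration.

One :func:`run_pipeline` call simulates a four-locality paired-habitat study,
then runs the full analysis chain per stage — matrix filters, joint folded
SFS, gene-flow model comparison with AIC (and optional parametric
bootstrap), selection outlier scan with environmental-association Bayes
factors, population-structure summaries (F_ST, DAPC, sPCA), and phenotype
statistics (GPA + symmetric shape PCA, Pillai MANOVA, ANOVA, DFA) — writing
TSV reports plus a machine-readable JSON manifest of seeds and outputs.

A single global seed fans out to per-stage seeds through named
``numpy.random.SeedSequence`` spawns, so reruns with the same config are
bit-identical.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, demog, genomatrix, io, morpho, mvstats, popstruct, \
    scan as scanmod, simdata

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Per-stage parameter blocks with scaled-down defaults.

    ``sim`` controls the generative model (TWOGFLOW unless overridden);
    dataset roles follow the two-pass convention: model comparison on the
    thinned, outlier-free SNPs (INDSNP role), F_ST/sPCA on the thinned set,
    scans and DAPC on all SNPs (ALLSNP role).
    """

    seed: int = 0
    n_localities: int = 2
    sim: dict = field(default_factory=lambda: dict(
        N=500.0, T_div=4000.0, T_recent=400.0,
        m_BI_anc=1e-5, m_IB_anc=1e-5, m_BI_rec=1e-3, m_IB_rec=1e-3,
        mu=1e-8, n_diploids=12, n_contigs=800, missing_rate=0.02))
    fit: dict = field(default_factory=lambda: dict(
        models=["NOGFLOW", "ONEGFLOW", "TWOGFLOW"], cycles=8,
        sims_per_cycle=2000, n_replicates=2, final_sims=20000))
    bootstrap: dict = field(default_factory=lambda: dict(
        enabled=False, n_boot=10, cycles=5, sims_per_cycle=2000,
        n_replicates=1))
    scan: dict = field(default_factory=lambda: dict(
        K=4, n_island_snps=2000, n_spiked=10, delta_p=0.6, bf_threshold=10.0,
        n_runs=10))
    struct: dict = field(default_factory=lambda: dict(
        spca_rand=199, dapc_pc_grid=[5, 10, 20], dapc_train_sets=30))
    phenotype: dict = field(default_factory=lambda: dict(n_per_group=20))

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            cur = getattr(cfg, key)
            if isinstance(cur, dict):
                cur.update(val)
            else:
                setattr(cfg, key, val)
        return cfg


def _stage_seed(root: int, name: str) -> int:
    h = np.random.SeedSequence([root, abs(hash(name)) % (2**31)])
    return int(h.generate_state(1)[0] % (2**31 - 1))


def _sim_params(cfg: PipelineConfig) -> simdata.DemographicParams:
    s = cfg.sim
    return simdata.DemographicParams.twogflow(
        N_beach=s["N"], N_inland=s["N"], N_ancestral=s["N"],
        T_div=s["T_div"], T_recent=s["T_recent"],
        m_BI_anc=s["m_BI_anc"], m_IB_anc=s["m_IB_anc"],
        m_BI_rec=s["m_BI_rec"], m_IB_rec=s["m_IB_rec"], mu=s["mu"])


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full chain; returns the manifest dict (also written to disk)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    manifest = {"version": __version__, "seed": config.seed, "stages": {},
                "outputs": []}

    def record(stage, **info):
        manifest["stages"][stage] = info

    def save(df, name, **kw):
        path = out / name
        df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)
        manifest["outputs"].append(name)
        return path

    params = _sim_params(config)
    log = lambda msg: print(f"[beachflow] {msg}", file=sys.stderr)

    # -- simulate ----------------------------------------------------------
    seed_sim = _stage_seed(config.seed, "simulate")
    log(f"simulate: {config.n_localities} localities under {params.model_kind}")
    study = simdata.simulate_study(
        params, n_localities=config.n_localities,
        n_contigs=config.sim["n_contigs"],
        diploids_per_site=(config.sim["n_diploids"],),
        missing_rate=config.sim["missing_rate"], seed=seed_sim)
    record("simulate", seed=seed_sim, model=params.model_kind,
           n_localities=config.n_localities)

    # -- filter + SFS + fits per locality ---------------------------------
    rules = genomatrix.FilterRules()
    fit_rows = []
    boot_rows = []
    for loc, (mat, tags) in study.items():
        fmat, audit = genomatrix.filter_sites(mat, rules)
        save(audit, f"loc{loc}_filter_audit.tsv")
        sfs = genomatrix.joint_folded_sfs(
            fmat, fmat.samples["habitat"].to_numpy())
        total_sites = config.sim["n_contigs"] * 300
        est = genomatrix.estimate_monomorphic(
            total_sites, max(mat.n_snps, 1), max(fmat.n_snps, 1),
            int(sfs.n_polymorphic))
        sfs.n_monomorphic = est.n_monomorphic
        io.write_obs_sfs(sfs, out / f"loc{loc}_jointMAFpop1_0.obs")
        manifest["outputs"].append(f"loc{loc}_jointMAFpop1_0.obs")

        seed_fit = _stage_seed(config.seed, f"fit{loc}")
        log(f"fit: locality {loc} ({int(sfs.n_polymorphic)} SNPs)")
        fits = demog.fit_models(
            sfs, tuple(config.fit["models"]), mu=config.sim["mu"],
            cycles=config.fit["cycles"],
            sims_per_cycle=config.fit["sims_per_cycle"],
            n_replicates=config.fit["n_replicates"], seed=seed_fit,
            final_sims=config.fit["final_sims"])
        tab = demog.aic_table(fits)
        tab.insert(0, "locality", loc)
        fit_rows.append(tab)
        record(f"fit_loc{loc}", seed=seed_fit,
               best=str(tab.iloc[0]["model"]),
               delta_aic={r.model: round(float(r.delta_AIC), 2)
                          for r in tab.itertuples()})

        if config.bootstrap["enabled"]:
            bb = config.bootstrap
            ci = demog.parametric_bootstrap(
                fits[tab.iloc[0]["model"]], n_boot=bb["n_boot"],
                n_contigs=config.sim["n_contigs"], cycles=bb["cycles"],
                sims_per_cycle=bb["sims_per_cycle"],
                n_replicates=bb["n_replicates"],
                seed=_stage_seed(config.seed, f"boot{loc}"))
            t = ci.table.copy()
            t.insert(0, "locality", loc)
            boot_rows.append(t)
    save(pd.concat(fit_rows, ignore_index=True), "model_comparison.tsv")
    if boot_rows:
        save(pd.concat(boot_rows, ignore_index=True), "bootstrap_ci.tsv")

    # -- island-wide matrix: scan + structure ------------------------------
    seed_scan = _stage_seed(config.seed, "scan")
    sc = config.scan
    mat8, tags8 = simdata.simulate_island_matrix(
        n_localities=4, n_snps=sc["n_island_snps"], seed=seed_scan)
    rng = np.random.default_rng(seed_scan + 1)
    mat8s, spiked = simdata.spike_outlier_loci(
        mat8, mat8.samples["habitat"].to_numpy(), tags8,
        sc["n_spiked"], sc["delta_p"], rng)
    log(f"scan: {mat8s.n_snps} SNPs, {len(spiked)} spiked")
    res = scanmod.pcadapt_scan(mat8s, K=sc["K"])
    thinned, _ = genomatrix.thin_one_per_tag(mat8s, tags8,
                                             exclude=res.outliers)
    e_by_site = {s: (1.0 if s.endswith("B") else 0.0)
                 for s in sorted(set(mat8s.site_labels()))}
    cand = res.outliers if res.outliers else list(spiked[:3])
    cons, bf = scanmod.replicate_consistency(
        mat8s, e_by_site, cand, thinned=thinned, n_runs=sc["n_runs"],
        bf_threshold=sc["bf_threshold"], seed=seed_scan + 2)
    outtab = res.table.merge(cons, on="snp_id", how="left")
    outtab["spiked"] = outtab["snp_id"].isin(set(spiked))
    save(outtab, "outlier_scan.tsv")
    n_flag = int(res.table["outlier"].sum())
    recall = (len(set(res.outliers) & set(spiked)) / len(spiked)
              if spiked else float("nan"))
    record("scan", seed=seed_scan, n_outliers=n_flag, recall=recall,
           inflation=res.inflation)

    # -- structure ---------------------------------------------------------
    st = config.struct
    seed_struct = _stage_seed(config.seed, "struct")
    log("structure: F_ST / DAPC / sPCA")
    fst = popstruct.pairwise_fst(thinned)
    save(fst, "fst_pairwise.tsv", index=True)
    cv = popstruct.dapc_crossval(mat8s, mat8s.site_labels(),
                                 st["dapc_pc_grid"],
                                 n_train_sets=st["dapc_train_sets"],
                                 seed=seed_struct)
    save(cv, "dapc_crossval.tsv")
    npc = int(cv.loc[cv["chosen"], "n_pcs"].iloc[0])
    scores, varpct, cents = popstruct.dapc_fit(mat8s, mat8s.site_labels(), npc)
    save(scores, "dapc_scores.tsv")
    X = popstruct._impute_center(thinned.codes)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :10] * s[:10]
    net = popstruct.NeighbourNetwork.within_locality(
        thinned.samples["locality"].to_numpy())
    sp = popstruct.spca_tests(pcs, net, n_rand=st["spca_rand"],
                              seed=seed_struct + 1)
    save(pd.DataFrame([sp]), "spca_tests.tsv")
    record("struct", seed=seed_struct, dapc_pcs=npc,
           dapc_df1_pct=float(varpct[0]), **{k: float(v) for k, v in sp.items()})

    # -- phenotypes --------------------------------------------------------
    seed_ph = _stage_seed(config.seed, "phenotype")
    log("phenotypes: GPA / MANOVA / DFA")
    spec = simdata.default_phenotype_spec(config.phenotype["n_per_group"])
    lms, meta, colour = simdata.simulate_phenotypes(
        spec, np.random.default_rng(seed_ph))
    half = spec.mean_shape.shape[0] // 2
    lset = morpho.LandmarkSet(lms, pairs=[(i, i + half) for i in range(half)])
    sym, asym, joint = morpho.symmetry_decompose(lset)
    shp_scores, eig, kpc = morpho.shape_pca_select(sym)
    man_shape = mvstats.two_way_manova_pillai(
        shp_scores, meta["habitat"], meta["locality"],
        names=("habitat", "locality"))
    ccols = [c for c in colour.columns if c.startswith("c")]
    Ylum = np.log10(colour[ccols].to_numpy())
    man_col = mvstats.two_way_manova_pillai(
        Ylum, colour["habitat"], colour["locality"],
        names=("habitat", "locality"))
    cs = np.log(np.array([morpho.centroid_size(c) for c in lms]))
    anova = mvstats.two_way_anova(cs, meta["habitat"], meta["locality"],
                                  names=("habitat", "locality"))
    dfa_res = mvstats.dfa(Ylum, (meta["locality"].astype(str) + "-"
                                 + meta["habitat"]).to_numpy())
    man_shape.terms.insert(0, "analysis", "head_shape")
    man_col.terms.insert(0, "analysis", "luminance")
    save(pd.concat([man_shape.terms, man_col.terms], ignore_index=True),
         "manova.tsv")
    save(anova, "anova_head_size.tsv")
    save(dfa_res.scores, "dfa_luminance_scores.tsv")
    record("phenotype", seed=seed_ph, shape_pcs=kpc,
           habitat_eta2_shape=float(man_shape.term("habitat")["partial_eta2"]),
           habitat_eta2_colour=float(man_col.term("habitat")["partial_eta2"]),
           dfa_df1_pct=float(dfa_res.variance_pct[0]))

    manifest["runtime_s"] = round(time.time() - t_start, 1)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"].append("manifest.json")
    log(f"done in {manifest['runtime_s']}s -> {out}")
    return manifest
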