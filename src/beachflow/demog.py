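"""Composite-likelihood demographic inference on the joint folded SFS.

Three nested divergence models for a habitat pair (no gene flow; one constant
gene-flow epoch; two successive gene-flow epochs) are fitted by simulating the
expected joint folded SFS under candidate parameters (Monte-Carlo over
structured-coalescent genealogies) and maximizing the multinomial composite
log10-likelihood over all SFS cells including the monomorphic class.  Model
choice uses AIC; uncertainty comes from a parametric bootstrap (simulate at
the fitted parameters, rebuild the SFS, refit).

The optimizer is a seeded stochastic coordinate search: random (log-uniform)
starts within bounds, then cyclic per-parameter multiplicative proposals with
a shrinking log-width, accepted only on likelihood improvement — the recorded
best likelihood per replicate is monotone non-decreasing by construction.
The replicate with the smallest deviation from the saturated (maximum
observed) likelihood is reported, mirroring the reference workflow of the
fastsimcoal family without reproducing its internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import DemographicParams, SimConfig, simulate_dataset, \
    class_branch_lengths
from .genomatrix import JointFoldedSFS, fold_joint, joint_folded_sfs

__all__ = [
    "ModelSpec", "ModelFitResult", "BootstrapCI",
    "default_model_spec", "expected_sfs", "composite_log10_likelihood",
    "optimize_model", "aic_table", "delta_aic_from_deviations",
    "relative_probability", "parametric_bootstrap",
]

P_MIN = 1e-10
LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Free parameters, bounds and the AIC parameter count of one model.

    All free parameters are positive and searched on the log scale.  The
    recent epoch is parameterized as ``t_ratio`` = T_recent / T_div in (0, 1)
    so every point in the box is a valid model.  ``k`` is the parameter count
    used in AIC; defaults (4 / 7 / 10) fix the load-bearing differences
    Δk = 3 between successive models while the absolute level is convention.
    """

    kind: str
    param_names: tuple
    lower: np.ndarray
    upper: np.ndarray
    k: int
    mu: float = 1e-8

    def __post_init__(self):
        if len(self.param_names) != len(self.lower) or \
                len(self.lower) != len(self.upper):
            raise ValueError("bounds must match param_names")
        if (np.asarray(self.lower) <= 0).any() or \
                (np.asarray(self.upper) < np.asarray(self.lower)).any():
            raise ValueError("need 0 < lower <= upper")

    @property
    def n_free(self):
        return len(self.param_names)

    def to_params(self, theta) -> DemographicParams:
        d = dict(zip(self.param_names, np.asarray(theta, float)))
        common = dict(N_beach=d["N_beach"], N_inland=d["N_inland"],
                      N_ancestral=d["N_ancestral"], T_div=d["T_div"],
                      mu=self.mu)
        if self.kind == "NOGFLOW":
            return DemographicParams.nogflow(**common)
        if self.kind == "ONEGFLOW":
            return DemographicParams.onegflow(m_BI=d["m_BI"], m_IB=d["m_IB"],
                                              **common)
        return DemographicParams.twogflow(
            T_recent=d["t_ratio"] * d["T_div"],
            m_BI_anc=d["m_BI_anc"], m_IB_anc=d["m_IB_anc"],
            m_BI_rec=d["m_BI_rec"], m_IB_rec=d["m_IB_rec"], **common)


_DEFAULT_K = {"NOGFLOW": 4, "ONEGFLOW": 7, "TWOGFLOW": 10}


def default_model_spec(kind: str, mu: float = 1e-8,
                       n_bounds=(10.0, 1e6), t_bounds=(10.0, 1e7),
                       m_bounds=(1e-7, 0.2), k: int | None = None) -> ModelSpec:
    names = ["N_beach", "N_inland", "N_ancestral", "T_div"]
    lo = [n_bounds[0]] * 3 + [t_bounds[0]]
    hi = [n_bounds[1]] * 3 + [t_bounds[1]]
    if kind == "ONEGFLOW":
        names += ["m_BI", "m_IB"]
        lo += [m_bounds[0]] * 2
        hi += [m_bounds[1]] * 2
    elif kind == "TWOGFLOW":
        names += ["t_ratio", "m_BI_anc", "m_IB_anc", "m_BI_rec", "m_IB_rec"]
        lo += [1e-3] + [m_bounds[0]] * 4
        hi += [0.95] + [m_bounds[1]] * 4
    elif kind != "NOGFLOW":
        raise ValueError(f"unknown model kind {kind!r}")
    return ModelSpec(kind, tuple(names), np.array(lo), np.array(hi),
                     k=_DEFAULT_K[kind] if k is None else k, mu=mu)


# ---------------------------------------------------------------------------
# expected SFS and composite likelihood
# ---------------------------------------------------------------------------

def _fold_domain_mask(n1: int, n2: int) -> np.ndarray:
    """Flat mask of folded-SFS cells that can carry probability mass
    (monomorphic class excluded; appended as one extra True cell)."""
    ones = np.ones((2 * n1 + 1, 2 * n2 + 1))
    dom = fold_joint(ones) > 0
    dom[0, 0] = False
    return np.concatenate([dom.ravel(), [True]])


def expected_sfs(params: DemographicParams, n1: int, n2: int,
                 n_sims: int, seed: int) -> np.ndarray:
    """Monte-Carlo expected folded-SFS probabilities, including the
    monomorphic class as the last entry.

    Per site, the probability of segregating at (k_b, k_i) derived copies is
    mu times the mean branch length ancestral to that class; folding on the
    global minor allele gives the folded cells, and the remainder is the
    monomorphic class.  Zero cells in the achievable fold domain are floored
    at 1e-10 and the vector renormalized.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    T = class_branch_lengths(params, 2 * n1, 2 * n2, n_sims, seed)
    p_unf = params.mu * T
    p_fold = fold_joint(p_unf)
    p_fold[0, 0] = 0.0
    poly = p_fold.ravel()
    p_mono = max(0.0, 1.0 - poly.sum())
    p = np.concatenate([poly, [p_mono]])
    dom = _fold_domain_mask(n1, n2)
    p[dom & (p < P_MIN)] = P_MIN
    return p / p.sum()


def composite_log10_likelihood(obs, probs):
    """(log10 CL, saturated log10 CL, deviation) for observed SFS counts.

    ``obs`` is a JointFoldedSFS or a flat count vector aligned with
    :func:`expected_sfs` output (monomorphic class last).  The saturated
    likelihood uses the observed proportions; deviation = saturated - fit.
    """
    o = obs.flat_with_monomorphic() if isinstance(obs, JointFoldedSFS) \
        else np.asarray(obs, float)
    p = np.asarray(probs, float)
    if o.shape != p.shape:
        raise ValueError(f"shape mismatch {o.shape} vs {p.shape}")
    nz = o > 0
    if (p[nz] <= 0).any():
        raise ValueError("observed count in zero-probability cell; "
                         "expected-SFS floor missing")
    ll = float((o[nz] * np.log10(p[nz])).sum())
    phat = o[nz] / o.sum()
    ll_sat = float((o[nz] * np.log10(phat)).sum())
    return ll, ll_sat, ll_sat - ll


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

@dataclass
class ModelFitResult:
    spec: ModelSpec
    theta: np.ndarray
    params: DemographicParams
    log10_CL: float
    deviation: float
    aic: float
    n1: int
    n2: int
    n_replicates: int
    best_replicate: int
    seed: int
    replicate_deviations: list = field(default_factory=list)


JUMP_CAP = 50.0


def _expected_jumps(params: DemographicParams) -> float:
    """Expected backwards deme jumps per lineage over the divergence span.

    Beyond a handful of jumps the SFS sits at the migration-drift
    equilibrium, so capping this quantity prunes an uninformative (and
    computationally explosive) corner of parameter space."""
    (mb_rec, mi_rec), (mb_anc, mi_anc) = params.backwards_rates()
    t_rec = params.T_recent if params.model_kind == "TWOGFLOW" else 0.0
    return (max(mb_rec, mi_rec) * t_rec
            + max(mb_anc, mi_anc) * (params.T_div - t_rec))


def _repair_jumps(spec, theta, cap=JUMP_CAP):
    """Scale migration rates down until the jump cap holds."""
    theta = np.asarray(theta, float).copy()
    j = _expected_jumps(spec.to_params(theta))
    if j > cap:
        scale = cap / j * 0.99
        for i, name in enumerate(spec.param_names):
            if name.startswith("m_"):
                theta[i] = max(theta[i] * scale, spec.lower[i])
    return theta


def _eval(obs_flat, spec, theta, n1, n2, n_sims, seed):
    params = spec.to_params(theta)
    p = expected_sfs(params, n1, n2, n_sims, seed)
    ll, _, _ = composite_log10_likelihood(obs_flat, p)
    return ll


def optimize_model(obs: JointFoldedSFS, spec: ModelSpec, *,
                   cycles: int = 30, sims_per_cycle: int = 20000,
                   n_replicates: int = 10, seed: int = 0,
                   start_theta=None, warm_starts=(),
                   final_sims: int | None = None) -> ModelFitResult:
    """Fit one model to an observed joint folded SFS.

    Each replicate draws a log-uniform random start within bounds (or starts
    at ``start_theta``; the first replicates may instead start from
    ``warm_starts`` vectors, e.g. embeddings of a simpler nested model's
    fit), then performs ``cycles`` sweeps of cyclic per-parameter
    multiplicative proposals (log-factor uniform in +-log 3, shrinking with
    the cycle index), accepting only improvements in the composite log10
    likelihood.  The replicate with the smallest deviation from the
    saturated likelihood wins, and its likelihood is re-evaluated with
    ``final_sims`` simulations (default 5x ``sims_per_cycle``) on a seed
    derived from ``seed`` alone — so fits of different models run with the
    same ``seed`` are compared on common final randomness.
    """
    obs_flat = obs.flat_with_monomorphic()
    _, ll_sat, _ = composite_log10_likelihood(
        obs_flat, np.maximum(obs_flat / obs_flat.sum(), P_MIN))
    n1, n2 = obs.n1, obs.n2
    log_lo = np.log(spec.lower)
    log_hi = np.log(spec.upper)
    ss = np.random.SeedSequence(seed)
    final_seed = int(np.random.SeedSequence([seed, 2**20]).generate_state(1)[0]
                     % (2**31 - 1))
    best = None
    rep_devs = []
    warm_starts = list(warm_starts)
    candidates = []
    for r, child in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        # common random numbers within a replicate: every likelihood
        # evaluation reuses one simulation seed, so proposals are compared on
        # a fixed Monte-Carlo surface and acceptance is a true hill climb
        sfs_seed = int(rng.integers(2**31 - 1))
        if start_theta is not None:
            theta = np.asarray(start_theta, float).copy()
        elif r < len(warm_starts):
            theta = np.clip(np.asarray(warm_starts[r], float),
                            spec.lower, spec.upper)
        else:
            theta = np.exp(rng.uniform(log_lo, log_hi))
        theta = _repair_jumps(spec, theta)
        ll = _eval(obs_flat, spec, theta, n1, n2, sims_per_cycle, sfs_seed)
        for c in range(cycles):
            # wide sweeps every third cycle help the search cross likelihood
            # ridges (e.g. divergence-time / migration trade-offs)
            base = math.log(10.0) if c % 3 == 0 else math.log(3.0)
            width = base / (1.0 + 0.1 * c)
            for j in range(spec.n_free):
                prop = theta.copy()
                logv = math.log(theta[j]) + rng.uniform(-width, width)
                prop[j] = math.exp(min(max(logv, log_lo[j]), log_hi[j]))
                if _expected_jumps(spec.to_params(prop)) > JUMP_CAP:
                    continue
                ll_prop = _eval(obs_flat, spec, prop, n1, n2, sims_per_cycle,
                                sfs_seed)
                if ll_prop > ll:
                    theta, ll = prop, ll_prop
        dev = ll_sat - ll
        rep_devs.append(dev)
        candidates.append((theta, r))
        if best is None or dev < best[0]:
            best = (dev, ll, theta, r)
    if best is None or not np.isfinite(best[1]):
        raise RuntimeError(f"all replicates non-finite for {spec.kind} "
                           f"(seed={seed})")
    dev, ll, theta, r = best
    nf = 5 * sims_per_cycle if final_sims is None else final_sims
    if nf > 0 and cycles > 0:
        # score every replicate winner (and the raw warm starts, so a
        # nested model's fit is never beaten by its own embedding) on the
        # common final seed; keep the best
        for w, ws in enumerate(warm_starts):
            candidates.append((_repair_jumps(
                spec, np.clip(np.asarray(ws, float), spec.lower, spec.upper)),
                -1 - w))
        ll = -np.inf
        for cand_theta, cand_r in candidates:
            ll_c = _eval(obs_flat, spec, cand_theta, n1, n2, nf, final_seed)
            if ll_c > ll:
                ll, theta, r = ll_c, cand_theta, cand_r
        dev = ll_sat - ll
    aic = 2.0 * spec.k - 2.0 * LN10 * ll
    return ModelFitResult(spec, theta, spec.to_params(theta), ll, dev, aic,
                          n1, n2, n_replicates, r, seed, rep_devs)


def heuristic_start(obs: JointFoldedSFS, spec: ModelSpec) -> np.ndarray:
    """Moment-based starting point from the observed SFS.

    A Watterson-type estimate sets the effective sizes: theta per site =
    S / (a_n * total sites) with a_n the harmonic number for the pooled
    haploid sample, and N = theta / (4 mu).  The divergence time starts at
    2N generations, the epoch ratio at 0.1, and migration rates at 1e-3
    (recent) / 1e-5 (ancient) — generic orders of magnitude for ongoing
    exchange, clipped into bounds.
    """
    n_hap = 2 * (obs.n1 + obs.n2)
    a_n = sum(1.0 / i for i in range(1, n_hap))
    total = obs.n_polymorphic + obs.n_monomorphic
    theta_site = max(obs.n_polymorphic, 1.0) / (a_n * max(total, 1.0))
    N = max(theta_site / (4.0 * spec.mu), spec.lower[0])
    guesses = {"N_beach": N, "N_inland": N, "N_ancestral": N,
               "T_div": 2.0 * N, "t_ratio": 0.1,
               "m_BI": 1e-3, "m_IB": 1e-3,
               "m_BI_rec": 1e-3, "m_IB_rec": 1e-3,
               "m_BI_anc": 1e-5, "m_IB_anc": 1e-5}
    theta = np.array([guesses[p] for p in spec.param_names])
    return np.clip(theta, spec.lower, spec.upper)


def _embed_theta(from_spec: ModelSpec, theta, to_spec: ModelSpec):
    """Embed a simpler model's fit as a starting point of a richer model."""
    d = dict(zip(from_spec.param_names, np.asarray(theta, float)))
    vals = []
    for name, lo in zip(to_spec.param_names, to_spec.lower):
        if name in d:
            vals.append(d[name])
        elif name in ("m_BI", "m_IB"):           # NOGFLOW -> ONEGFLOW
            vals.append(lo)
        elif name == "t_ratio":
            vals.append(0.5)
        elif name.startswith("m_"):              # *_anc / *_rec
            base = d.get("m_" + name.split("_")[1], lo)
            vals.append(max(base, lo))
        else:
            raise KeyError(name)
    return np.array(vals)


def fit_models(obs: JointFoldedSFS, kinds=("NOGFLOW", "ONEGFLOW", "TWOGFLOW"),
               *, mu: float = 1e-8, cycles: int = 30,
               sims_per_cycle: int = 20000, n_replicates: int = 10,
               seed: int = 0, final_sims: int | None = None,
               spec_factory=default_model_spec) -> dict:
    """Fit the model ladder to one observed SFS with warm-start chaining.

    Models are fitted simplest-first; each richer model receives the simpler
    fits (embedded into its parameter space, migration rates entering at the
    bound) as warm starts for its first replicates, so nested models are
    never spuriously out-fitted by their special cases.  All models share
    ``seed`` and hence the common final-evaluation randomness.
    """
    order = sorted(kinds, key=lambda k: _DEFAULT_K[k])
    fits = {}
    for kind in order:
        spec = spec_factory(kind, mu=mu)
        warm = [_embed_theta(fits[k].spec, fits[k].theta, spec)
                for k in order if k in fits]
        warm.append(heuristic_start(obs, spec))
        fits[kind] = optimize_model(
            obs, spec, cycles=cycles, sims_per_cycle=sims_per_cycle,
            n_replicates=n_replicates, seed=seed, warm_starts=warm,
            final_sims=final_sims)
    return fits


# ---------------------------------------------------------------------------
# AIC comparison
# ---------------------------------------------------------------------------

def delta_aic_from_deviations(deviation: float, deviation_best: float,
                              delta_k: int) -> float:
    """ΔAIC of a model versus the best model from likelihood deviations.

    With a shared saturated baseline, ΔAIC = 2 ln(10) (D - D_best) - 2 Δk,
    where Δk = k_best - k (here 3 between successive models, 6 between the
    no-flow and two-epoch models)."""
    return 2.0 * LN10 * (deviation - deviation_best) - 2.0 * delta_k


def aic_table(fits: dict) -> pd.DataFrame:
    """Model-comparison table: deviation, AIC and ΔAIC versus the best model.

    ``fits`` maps model name -> ModelFitResult on the same observed SFS."""
    if len(fits) < 2:
        raise ValueError("need at least two fitted models")
    sizes = {(f.n1, f.n2) for f in fits.values()}
    if len(sizes) != 1:
        raise ValueError("fits compare different observed SFS sample sizes")
    rows = [(name, f.spec.kind, f.spec.k, f.log10_CL, f.deviation, f.aic)
            for name, f in fits.items()]
    df = pd.DataFrame(rows, columns=["model", "kind", "k", "log10_CL",
                                     "deviation", "AIC"])
    df["delta_AIC"] = df["AIC"] - df["AIC"].min()
    return df.sort_values("AIC").reset_index(drop=True)


def relative_probability(delta_aic: float, convention: str = "direct") -> float:
    """Relative model probability from a ΔAIC.

    ``convention='direct'`` uses exp(-ΔAIC), the convention under which a
    ΔAIC of 361.4 corresponds to 1.1e-157; ``'akaike'`` uses the textbook
    exp(-ΔAIC/2).
    """
    if delta_aic < 0:
        raise ValueError("delta_aic must be >= 0")
    if convention == "direct":
        return math.exp(-delta_aic)
    if convention == "akaike":
        return math.exp(-delta_aic / 2.0)
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------

_NATURAL = ("N_beach", "N_inland", "N_ancestral", "T_div", "T_recent",
            "m_BI_anc", "m_IB_anc", "m_BI_rec", "m_IB_rec")


def _natural_vector(params: DemographicParams):
    return np.array([getattr(params, n) for n in _NATURAL])


@dataclass
class BootstrapCI:
    table: pd.DataFrame       # parameter, estimate, lower, upper
    n_boot: int
    n_failures: int
    samples: np.ndarray       # (n_success, n_params) natural-scale refits

    def format_estimates(self, sig=3):
        """Rows rendered as 'estimate (lower, upper)'."""
        def f(x):
            return f"{x:.{sig}g}"
        return {r.parameter: f"{f(r.estimate)} ({f(r.lower)}, {f(r.upper)})"
                for r in self.table.itertuples()}


def parametric_bootstrap(best: ModelFitResult, *, n_boot: int = 100,
                         n_contigs: int = 4000, contig_length: int = 300,
                         total_sites: int | None = None,
                         cycles: int = 50, sims_per_cycle: int = 100000,
                         n_replicates: int = 40, seed: int = 0,
                         alpha: float = 0.05) -> BootstrapCI:
    """Percentile bootstrap CIs by simulate-at-fit / refit-from-fit.

    ``n_boot`` datasets are simulated at the fitted parameters with the
    observed amount of genomic data (``n_contigs`` 300-bp contigs); each
    folded SFS (with its monomorphic class) is refitted starting from the
    fitted values.  Failed refits are recorded and excluded.
    """
    params = best.params
    total = n_contigs * contig_length if total_sites is None else total_sites
    ss = np.random.SeedSequence(seed)
    samples = []
    failures = 0
    for b, child in enumerate(ss.spawn(n_boot)):
        st = child.generate_state(2)
        cfg = SimConfig(n_diploids_beach=best.n1, n_diploids_inland=best.n2,
                        n_contigs=n_contigs, contig_length=contig_length,
                        seed=int(st[0] % (2**31)))
        try:
            mat, _ = simulate_dataset(params, cfg)
            sfs = joint_folded_sfs(mat, mat.samples["habitat"].to_numpy())
            sfs.n_monomorphic = max(0, total - int(sfs.n_polymorphic)
                                    - sfs.n_monomorphic) + sfs.n_monomorphic
            refit = optimize_model(sfs, best.spec, cycles=cycles,
                                   sims_per_cycle=sims_per_cycle,
                                   n_replicates=n_replicates,
                                   seed=int(st[1] % (2**31)),
                                   start_theta=best.theta,
                                   final_sims=sims_per_cycle)
            samples.append(_natural_vector(refit.params))
        except (RuntimeError, ValueError):
            failures += 1
    if not samples:
        raise RuntimeError("every bootstrap refit failed")
    if failures:
        import warnings
        warnings.warn(f"{failures}/{n_boot} bootstrap refits failed; "
                      "CIs computed on the successes")
    arr = np.vstack(samples)
    lo = np.percentile(arr, 100 * alpha / 2, axis=0)
    hi = np.percentile(arr, 100 * (1 - alpha / 2), axis=0)
    est = _natural_vector(params)
    table = pd.DataFrame({"parameter": _NATURAL, "estimate": est,
                          "lower": lo, "upper": hi})
    return BootstrapCI(table, n_boot, failures, arr)
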