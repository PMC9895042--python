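"""Low-level structured-coalescent kernels (numba-compiled).

Two demes ("beach" = 0, "inland" = 1) exchange lineages backwards in time at
per-generation rates that switch at an epoch boundary; beyond the divergence
time all lineages sit in a single ancestral deme.  Pairwise coalescence within
a deme of diploid size N happens at rate 1/(2N) per pair per generation
(continuous-time exponential approximation, valid for m, 1/N << 1).

Rates passed to these kernels are *backwards* jump rates: ``mb`` is the rate at
which a lineage currently in the beach deme jumps to the inland deme, i.e. the
*forwards* inland->beach migration probability.  The forwards/backwards swap is
performed by the caller (see :mod:`beachflow.simdata`).

A lineage's descendant-sample class (k_beach, k_inland) is fixed over its whole
life, so expected branch lengths per SFS class can be accumulated in O(1) per
event: on death (coalescence) each lineage adds its lifetime to the class cell.
"""

import numpy as np
from numba import njit

__all__ = [
    "class_times_batch",
    "genealogy_once",
    "tmrca_batch",
]


@njit(cache=True)
def _sim_core(n_b, n_i, N0, N1, Na, T_div, T_rec,
              mb_rec, mi_rec, mb_anc, mi_anc,
              T_acc, record, parent, time_arr, node_deme):
    """One genealogy.  Accumulates class lifetimes into T_acc (flat
    (n_b+1)*(n_i+1)); if ``record`` also fills parent/time/node_deme arrays.
    Returns (tmrca, total_branch_length, n_migrations).
    """
    n = n_b + n_i
    n_nodes = 2 * n - 1
    width = n_i + 1

    kb = np.zeros(n_nodes, dtype=np.int64)
    ki = np.zeros(n_nodes, dtype=np.int64)
    birth = np.zeros(n_nodes, dtype=np.float64)
    node_of = np.zeros(n_nodes, dtype=np.int64)

    idx0 = np.empty(n_nodes, dtype=np.int64)
    idx1 = np.empty(n_nodes, dtype=np.int64)
    c0 = 0
    c1 = 0
    for j in range(n_b):
        kb[j] = 1
        idx0[c0] = j
        c0 += 1
        node_of[j] = j
        if record:
            node_deme[j] = 0
    for j in range(n_b, n):
        ki[j] = 1
        idx1[c1] = j
        c1 += 1
        node_of[j] = j
        if record:
            node_deme[j] = 1

    next_slot = n
    t = 0.0
    total_len = 0.0
    n_mig = 0

    # epochs: 0 = [0, T_rec) recent rates, 1 = [T_rec, T_div) ancient rates,
    # 2 = [T_div, inf) single ancestral deme
    epoch = 0
    if T_rec <= 0.0:
        epoch = 1

    while c0 + c1 > 1:
        if epoch == 0:
            mb = mb_rec
            mi = mi_rec
            t_end = T_rec
            n0cur = N0
        elif epoch == 1:
            mb = mb_anc
            mi = mi_anc
            t_end = T_div
            n0cur = N0
        else:
            mb = 0.0
            mi = 0.0
            t_end = np.inf
            n0cur = Na

        rc0 = c0 * (c0 - 1) / (4.0 * n0cur)
        rc1 = c1 * (c1 - 1) / (4.0 * N1)
        rm0 = c0 * mb
        rm1 = c1 * mi
        total = rc0 + rc1 + rm0 + rm1

        if total <= 0.0:
            t = t_end
        else:
            dt = np.random.exponential(1.0 / total)
            if t + dt >= t_end and epoch < 2:
                t = t_end
            else:
                t = t + dt
                u = np.random.random() * total
                if u < rc0 or u < rc0 + rc1:
                    # coalescence
                    if u < rc0:
                        lst = idx0
                        cd = c0
                    else:
                        lst = idx1
                        cd = c1
                    j1 = np.random.randint(cd)
                    j2 = np.random.randint(cd - 1)
                    if j2 >= j1:
                        j2 += 1
                    s1 = lst[j1]
                    s2 = lst[j2]
                    T_acc[kb[s1] * width + ki[s1]] += t - birth[s1]
                    T_acc[kb[s2] * width + ki[s2]] += t - birth[s2]
                    total_len += (t - birth[s1]) + (t - birth[s2])
                    s = next_slot
                    next_slot += 1
                    kb[s] = kb[s1] + kb[s2]
                    ki[s] = ki[s1] + ki[s2]
                    birth[s] = t
                    if record:
                        node_of_s = s  # node ids coincide with slots
                        parent[node_of[s1]] = node_of_s
                        parent[node_of[s2]] = node_of_s
                        time_arr[node_of_s] = t
                        node_deme[node_of_s] = 0 if u < rc0 else 1
                    node_of[s] = s
                    # remove j1, j2 (careful with order), append s
                    if j1 > j2:
                        hi = j1
                        lo = j2
                    else:
                        hi = j2
                        lo = j1
                    lst[hi] = lst[cd - 1]
                    lst[lo] = lst[cd - 2]
                    lst[cd - 2] = s
                    if u < rc0:
                        c0 -= 1
                    else:
                        c1 -= 1
                    continue
                elif u < rc0 + rc1 + rm0:
                    # beach lineage jumps (backwards) to inland
                    j = np.random.randint(c0)
                    s = idx0[j]
                    idx0[j] = idx0[c0 - 1]
                    c0 -= 1
                    idx1[c1] = s
                    c1 += 1
                    n_mig += 1
                    continue
                else:
                    j = np.random.randint(c1)
                    s = idx1[j]
                    idx1[j] = idx1[c1 - 1]
                    c1 -= 1
                    idx0[c0] = s
                    c0 += 1
                    n_mig += 1
                    continue

        # reached an epoch boundary without an event
        epoch += 1
        if epoch == 2:
            # merge: all inland lineages move to the ancestral (deme-0) pool
            for j in range(c1):
                idx0[c0] = idx1[j]
                c0 += 1
            c1 = 0

    return t, total_len, n_mig


@njit(cache=True)
def class_times_batch(n_b, n_i, N0, N1, Na, T_div, T_rec,
                      mb_rec, mi_rec, mb_anc, mi_anc, n_sims, seed):
    """Accumulate branch lengths by descendant class over ``n_sims`` genealogies.

    Returns a flat float64 array of length (n_b+1)*(n_i+1): total branch
    length (generations, summed over simulations) ancestral to exactly
    (k_b, k_i) sampled copies.  Cell (n_b, n_i) (the root class) and (0, 0)
    stay zero.
    """
    np.random.seed(seed)
    T_acc = np.zeros((n_b + 1) * (n_i + 1), dtype=np.float64)
    dummy = np.empty(0, dtype=np.int64)
    dummyf = np.empty(0, dtype=np.float64)
    for _ in range(n_sims):
        _sim_core(n_b, n_i, N0, N1, Na, T_div, T_rec,
                  mb_rec, mi_rec, mb_anc, mi_anc,
                  T_acc, False, dummy, dummyf, dummy)
    return T_acc


@njit(cache=True)
def tmrca_batch(n_b, n_i, N0, N1, Na, T_div, T_rec,
                mb_rec, mi_rec, mb_anc, mi_anc, n_sims, seed):
    """TMRCA and total branch length for ``n_sims`` genealogies."""
    np.random.seed(seed)
    out_t = np.empty(n_sims, dtype=np.float64)
    out_l = np.empty(n_sims, dtype=np.float64)
    T_acc = np.zeros((n_b + 1) * (n_i + 1), dtype=np.float64)
    dummy = np.empty(0, dtype=np.int64)
    dummyf = np.empty(0, dtype=np.float64)
    for i in range(n_sims):
        tm, tl, _ = _sim_core(n_b, n_i, N0, N1, Na, T_div, T_rec,
                              mb_rec, mi_rec, mb_anc, mi_anc,
                              T_acc, False, dummy, dummyf, dummy)
        out_t[i] = tm
        out_l[i] = tl
    return out_t, out_l


@njit(cache=True)
def genealogy_once(n_b, n_i, N0, N1, Na, T_div, T_rec,
                   mb_rec, mi_rec, mb_anc, mi_anc, seed):
    """One fully recorded genealogy.

    Returns (parent, time, node_deme, tmrca, total_length, n_migrations).
    Leaves are nodes 0..n_b-1 (beach) and n_b..n-1 (inland); internal nodes
    n..2n-2 in coalescence order; parent[root] = -1.  node_deme is the deme in
    which each node was created.
    """
    np.random.seed(seed)
    n = n_b + n_i
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time_arr = np.zeros(n_nodes, dtype=np.float64)
    node_deme = np.zeros(n_nodes, dtype=np.int64)
    T_acc = np.zeros((n_b + 1) * (n_i + 1), dtype=np.float64)
    tm, tl, nm = _sim_core(n_b, n_i, N0, N1, Na, T_div, T_rec,
                           mb_rec, mi_rec, mb_anc, mi_anc,
                           T_acc, True, parent, time_arr, node_deme)
    return parent, time_arr, node_deme, tm, tl, nm
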