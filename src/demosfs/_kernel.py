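"""Numba kernels for the structured-coalescent simulator.

One genealogy per SNP (free recombination between SNPs). The state is a
set of lineages, each carrying its deme, its descendant-count vector
over demes, and (when the total sample fits in 64 haplotypes) a
descendant bitmask. Events, backward in time:

* within-deme coalescence at rate C(k_d, 2) / (2 N_d) per generation,
* per-lineage migration at the model's backward rates,
* deterministic deme merges at the model's merge times (lineages
  relocated, destination size switched, migration involving either
  deme switched off).

Branch lengths are birth/death time differences, in generations.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _one_tree(sample_sizes, sizes0, mig0,
              ev_times, ev_src, ev_dst, ev_size,
              deme, cfg, msk, birth, blen, parent, act,
              use_mask):
    """Simulate one genealogy in place; returns (n_nodes, root_time).

    Scratch arrays are caller-allocated with 2*n_total - 1 rows.
    """
    nd = sample_sizes.size
    ntot = 0
    for d in range(nd):
        ntot += sample_sizes[d]
    ne = ev_times.size

    sizes = sizes0.copy()
    mig = mig0.copy()
    mout = np.zeros(nd)
    for d in range(nd):
        s = 0.0
        for j in range(nd):
            s += mig[d, j]
        mout[d] = s

    # tips
    idx = 0
    for d in range(nd):
        for _ in range(sample_sizes[d]):
            deme[idx] = d
            for dd in range(nd):
                cfg[idx, dd] = 0
            cfg[idx, d] = 1
            if use_mask:
                msk[idx] = np.uint64(1) << np.uint64(idx)
            else:
                msk[idx] = np.uint64(0)
            birth[idx] = 0.0
            blen[idx] = 0.0
            parent[idx] = -1
            act[idx] = idx
            idx += 1
    n_act = ntot
    n_nodes = ntot

    k = np.zeros(nd, dtype=np.int64)
    for d in range(nd):
        k[d] = sample_sizes[d]

    coal_d = np.zeros(nd)
    t = 0.0
    ev_i = 0
    while n_act > 1:
        tot_coal = 0.0
        for d in range(nd):
            c = 0.5 * k[d] * (k[d] - 1) / (2.0 * sizes[d])
            coal_d[d] = c
            tot_coal += c
        tot_mig = 0.0
        for d in range(nd):
            tot_mig += k[d] * mout[d]
        tot = tot_coal + tot_mig

        t_ev = ev_times[ev_i] if ev_i < ne else np.inf
        if tot <= 0.0:
            dt = np.inf
        else:
            dt = np.random.exponential(1.0 / tot)

        if dt == np.inf and ev_i >= ne:
            break  # disconnected demography; caller validates against this

        if t + dt >= t_ev:
            # apply the merge
            t = t_ev
            src = ev_src[ev_i]
            dst = ev_dst[ev_i]
            for a in range(n_act):
                if deme[act[a]] == src:
                    deme[act[a]] = dst
            k[dst] += k[src]
            k[src] = 0
            sizes[dst] = ev_size[ev_i]
            for j in range(nd):
                mig[src, j] = 0.0
                mig[j, src] = 0.0
                mig[dst, j] = 0.0
                mig[j, dst] = 0.0
            for d in range(nd):
                s = 0.0
                for j in range(nd):
                    s += mig[d, j]
                mout[d] = s
            ev_i += 1
            continue

        t += dt
        u = np.random.random() * tot
        if u < tot_coal:
            # coalescence: pick deme, then an unordered lineage pair in it
            d = 0
            acc = coal_d[0]
            while u >= acc and d < nd - 1:
                d += 1
                acc += coal_d[d]
            r1 = np.random.randint(k[d])
            r2 = np.random.randint(k[d] - 1)
            if r2 >= r1:
                r2 += 1
            ia = -1
            ib = -1
            seen = 0
            for a in range(n_act):
                if deme[act[a]] == d:
                    if seen == r1:
                        ia = a
                    if seen == r2:
                        ib = a
                    seen += 1
            la = act[ia]
            lb = act[ib]
            nn = n_nodes
            deme[nn] = d
            for dd in range(nd):
                cfg[nn, dd] = cfg[la, dd] + cfg[lb, dd]
            msk[nn] = msk[la] | msk[lb]
            birth[nn] = t
            blen[nn] = 0.0
            parent[nn] = -1
            blen[la] = t - birth[la]
            blen[lb] = t - birth[lb]
            parent[la] = nn
            parent[lb] = nn
            # swap-remove both (remove higher position first)
            hi = ia if ia > ib else ib
            lo = ib if ia > ib else ia
            act[hi] = act[n_act - 1]
            n_act -= 1
            act[lo] = act[n_act - 1]
            act[n_act - 1] = nn
            n_nodes += 1
            k[d] -= 1
        else:
            # migration: pick source deme weighted by k_d * mout_d, then lineage, then dest
            u2 = u - tot_coal
            d = 0
            acc = k[0] * mout[0]
            while u2 >= acc and d < nd - 1:
                d += 1
                acc += k[d] * mout[d]
            r = np.random.randint(k[d])
            lin = -1
            seen = 0
            for a in range(n_act):
                if deme[act[a]] == d:
                    if seen == r:
                        lin = act[a]
                        break
                    seen += 1
            u3 = np.random.random() * mout[d]
            j = 0
            acc = mig[d, 0]
            while u3 >= acc and j < nd - 1:
                j += 1
                acc += mig[d, j]
            deme[lin] = j
            k[d] -= 1
            k[j] += 1

    return n_nodes, t


@njit(cache=True)
def sim_expected_weights(n_reps, sample_sizes, sizes0, mig0,
                         ev_times, ev_src, ev_dst, ev_size, seed):
    """Branch-length-weighted joint-SFS expectation.

    Accumulates, over ``n_reps`` genealogies, each branch's length into
    the cell of its descendant-count configuration; the normalized array
    estimates P(config | SNP), since a single infinite-sites mutation
    falls on a branch with probability proportional to its length.
    Returns a flat array over the mixed-radix configuration index
    (C-order over per-deme counts 0..n_d).
    """
    np.random.seed(seed)
    nd = sample_sizes.size
    ntot = int(sample_sizes.sum())
    nmax = 2 * ntot - 1
    deme = np.zeros(nmax, dtype=np.int64)
    cfg = np.zeros((nmax, nd), dtype=np.int32)
    msk = np.zeros(nmax, dtype=np.uint64)
    birth = np.zeros(nmax)
    blen = np.zeros(nmax)
    parent = np.full(nmax, -1, dtype=np.int64)
    act = np.zeros(nmax, dtype=np.int64)

    dims = np.zeros(nd, dtype=np.int64)
    for d in range(nd):
        dims[d] = sample_sizes[d] + 1
    stride = np.ones(nd, dtype=np.int64)
    for d in range(nd - 2, -1, -1):
        stride[d] = stride[d + 1] * dims[d + 1]
    size = stride[0] * dims[0]
    w = np.zeros(size)

    for _ in range(n_reps):
        n_nodes, _root_t = _one_tree(sample_sizes, sizes0, mig0,
                                     ev_times, ev_src, ev_dst, ev_size,
                                     deme, cfg, msk, birth, blen, parent, act,
                                     False)
        for b in range(n_nodes - 1):  # the root branch carries no mutation
            flat = 0
            for d in range(nd):
                flat += cfg[b, d] * stride[d]
            w[flat] += blen[b]
    return w


@njit(cache=True)
def sim_expected_pair_folded(n_reps, sample_sizes, sizes0, mig0,
                             ev_times, ev_src, ev_dst, ev_size, seed,
                             pair_a, pair_b, fold_flat, fold_off, nb_plus1):
    """Branch-length weights accumulated directly into folded pair grids.

    ``fold_flat`` concatenates, per pair, the flat folded-index lookup
    over the pair's (nA+1)x(nB+1) grid; ``fold_off`` gives each pair's
    offset. Returns the concatenation of the folded weight grids —
    algebraically identical to marginalising + folding
    ``sim_expected_weights`` but without materialising the joint array.
    """
    np.random.seed(seed)
    nd = sample_sizes.size
    ntot = int(sample_sizes.sum())
    nmax = 2 * ntot - 1
    deme = np.zeros(nmax, dtype=np.int64)
    cfg = np.zeros((nmax, nd), dtype=np.int32)
    msk = np.zeros(nmax, dtype=np.uint64)
    birth = np.zeros(nmax)
    blen = np.zeros(nmax)
    parent = np.full(nmax, -1, dtype=np.int64)
    act = np.zeros(nmax, dtype=np.int64)

    npairs = pair_a.size
    out = np.zeros(fold_off[npairs])
    for _ in range(n_reps):
        n_nodes, _root_t = _one_tree(sample_sizes, sizes0, mig0,
                                     ev_times, ev_src, ev_dst, ev_size,
                                     deme, cfg, msk, birth, blen, parent, act,
                                     False)
        for b in range(n_nodes - 1):
            w = blen[b]
            for p in range(npairs):
                i = cfg[b, pair_a[p]]
                j = cfg[b, pair_b[p]]
                local = fold_flat[fold_off[p] + i * nb_plus1[p] + j]
                out[fold_off[p] + local] += w
    return out


@njit(cache=True)
def sim_branch_pool(n_reps, sample_sizes, sizes0, mig0,
                    ev_times, ev_src, ev_dst, ev_size, seed, use_mask):
    """All branches of ``n_reps`` genealogies, flattened.

    Returns (branch lengths, per-deme descendant configs, carrier
    bitmasks, number of branches). Sampling SNP mutations from this pool
    with probability proportional to branch length implements the
    infinite-sites conditioning on polymorphism: a genealogy's chance of
    carrying a segregating site is proportional to its total length.
    """
    np.random.seed(seed)
    nd = sample_sizes.size
    ntot = int(sample_sizes.sum())
    nmax = 2 * ntot - 1
    deme = np.zeros(nmax, dtype=np.int64)
    cfg = np.zeros((nmax, nd), dtype=np.int32)
    msk = np.zeros(nmax, dtype=np.uint64)
    birth = np.zeros(nmax)
    blen = np.zeros(nmax)
    parent = np.full(nmax, -1, dtype=np.int64)
    act = np.zeros(nmax, dtype=np.int64)

    nb_max = n_reps * (2 * ntot - 2)
    pool_len = np.zeros(nb_max)
    pool_cfg = np.zeros((nb_max, nd), dtype=np.int32)
    pool_msk = np.zeros(nb_max, dtype=np.uint64)
    pos = 0
    for _ in range(n_reps):
        n_nodes, _root_t = _one_tree(sample_sizes, sizes0, mig0,
                                     ev_times, ev_src, ev_dst, ev_size,
                                     deme, cfg, msk, birth, blen, parent, act,
                                     use_mask)
        for b in range(n_nodes - 1):
            pool_len[pos] = blen[b]
            for d in range(nd):
                pool_cfg[pos, d] = cfg[b, d]
            pool_msk[pos] = msk[b]
            pos += 1
    return pool_len, pool_cfg, pool_msk, pos


@njit(cache=True)
def sim_tree_stats(n_reps, sample_sizes, sizes0, mig0,
                   ev_times, ev_src, ev_dst, ev_size, seed):
    """Per-replicate genealogy summaries for closed-form checks.

    Returns (root times, total branch lengths, flat branch lengths,
    flat branch total-descendant counts, per-replicate offsets into the
    flat arrays).
    """
    np.random.seed(seed)
    nd = sample_sizes.size
    ntot = int(sample_sizes.sum())
    nmax = 2 * ntot - 1
    deme = np.zeros(nmax, dtype=np.int64)
    cfg = np.zeros((nmax, nd), dtype=np.int32)
    msk = np.zeros(nmax, dtype=np.uint64)
    birth = np.zeros(nmax)
    blen = np.zeros(nmax)
    parent = np.full(nmax, -1, dtype=np.int64)
    act = np.zeros(nmax, dtype=np.int64)

    root_t = np.zeros(n_reps)
    total_len = np.zeros(n_reps)
    nb = 2 * ntot - 2
    br_len = np.zeros(n_reps * nb)
    br_cnt = np.zeros(n_reps * nb, dtype=np.int64)
    offsets = np.zeros(n_reps + 1, dtype=np.int64)
    pos = 0
    for rep in range(n_reps):
        n_nodes, rt = _one_tree(sample_sizes, sizes0, mig0,
                                ev_times, ev_src, ev_dst, ev_size,
                                deme, cfg, msk, birth, blen, parent, act,
                                False)
        root_t[rep] = rt
        tl = 0.0
        for b in range(n_nodes - 1):
            tl += blen[b]
            br_len[pos] = blen[b]
            c = 0
            for d in range(nd):
                c += cfg[b, d]
            br_cnt[pos] = c
            pos += 1
        total_len[rep] = tl
        offsets[rep + 1] = pos
    return root_t, total_len, br_len[:pos], br_cnt[:pos], offsets


@njit(cache=True)
def sim_single_tree(sample_sizes, sizes0, mig0,
                    ev_times, ev_src, ev_dst, ev_size, seed):
    """One genealogy with full node arrays (for tree inspection)."""
    np.random.seed(seed)
    nd = sample_sizes.size
    ntot = int(sample_sizes.sum())
    nmax = 2 * ntot - 1
    deme = np.zeros(nmax, dtype=np.int64)
    cfg = np.zeros((nmax, nd), dtype=np.int32)
    msk = np.zeros(nmax, dtype=np.uint64)
    birth = np.zeros(nmax)
    blen = np.zeros(nmax)
    parent = np.full(nmax, -1, dtype=np.int64)
    act = np.zeros(nmax, dtype=np.int64)
    n_nodes, rt = _one_tree(sample_sizes, sizes0, mig0,
                            ev_times, ev_src, ev_dst, ev_size,
                            deme, cfg, msk, birth, blen, parent, act,
                            ntot <= 64)
    return (n_nodes, rt, birth[:n_nodes].copy(), blen[:n_nodes].copy(),
            parent[:n_nodes].copy(), cfg[:n_nodes].copy())
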