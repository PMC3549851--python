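"""JIT-compiled hot path: smaller-half walk driving HDT counter updates.

The pure-Python walk/HDT pair in :mod:`colorwalk` and :mod:`hdt` defines
the semantics; this module is an exact re-statement of the same arithmetic
over flat int64 arrays, fused into one loop so the O(n log^2 n) inner work
runs at native speed.  ``triplet_distance(algorithm="hdt")`` uses it by
default; tests assert bit-identical totals against the Python engine.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .treeio import LeafMap, RootedBinaryTree, leaf_ranges
from .colorwalk import compute_node_info

NONE, RED, BLUE = 0, 1, 2
_KIND_L, _KIND_I, _KIND_C = 0, 1, 2
_CASE_B = 1


@njit(cache=False)
def _recompute(c, bot, top, case, R, B, RR, BB, RBh, BRh, N):
    b = bot[c]
    r1 = R[b]
    b1 = B[b]
    if case[c] == _CASE_B:
        R[c] = r1
        B[c] = b1
        RR[c] = r1 * (r1 - 1) // 2
        BB[c] = b1 * (b1 - 1) // 2
        RBh[c] = 0
        BRh[c] = 0
        N[c] = N[b]
        return
    t = top[c]
    r2 = R[t]
    b2 = B[t]
    R[c] = r1 + r2
    B[c] = b1 + b2
    RR[c] = RR[b] + RR[t]
    BB[c] = BB[b] + BB[t]
    RBh[c] = RBh[t] + RBh[b] + r1 * b2
    BRh[c] = BRh[t] + BRh[b] + b1 * r2
    N[c] = (
        N[b]
        + N[t]
        + (r1 * (r1 - 1) // 2) * b2
        + (b1 * (b1 - 1) // 2) * r2
        + RR[t] * b1
        + BB[t] * r1
        + r1 * RBh[t]
        + b1 * BRh[t]
    )


@njit(cache=False)
def _apply(leaf, col, leaf_comp, par, bot, top, case, R, B, RR, BB, RBh, BRh, N):
    c = leaf_comp[leaf]
    R[c] = 1 if col == RED else 0
    B[c] = 1 if col == BLUE else 0
    c = par[c]
    while c != -1:
        _recompute(c, bot, top, case, R, B, RR, BB, RBh, BRh, N)
        c = par[c]


@njit(cache=False)
def _fused_shared(
    smaller,
    larger,
    lo,
    hi,
    leaf_seq,
    leaf_id,
    root1,
    kind,
    par,
    bot,
    top,
    case,
    leaf_comp,
    root_comp,
):
    ncomp = kind.shape[0]
    R = np.zeros(ncomp, np.int64)
    B = np.zeros(ncomp, np.int64)
    RR = np.zeros(ncomp, np.int64)
    BB = np.zeros(ncomp, np.int64)
    RBh = np.zeros(ncomp, np.int64)
    BRh = np.zeros(ncomp, np.int64)
    N = np.zeros(ncomp, np.int64)

    # entry invariant: every leaf RED (one bottom-up sweep)
    for c in range(ncomp):
        k = kind[c]
        if k == _KIND_L:
            R[c] = 1
        elif k == _KIND_C:
            _recompute(c, bot, top, case, R, B, RR, BB, RBh, BRh, N)

    total = np.int64(0)
    nn = smaller.shape[0]
    stack_node = np.empty(2 * nn + 2, np.int64)
    stack_stage = np.empty(2 * nn + 2, np.int64)
    sp = 0
    stack_node[sp] = root1
    stack_stage[sp] = 0
    sp += 1
    while sp > 0:
        sp -= 1
        v = stack_node[sp]
        stage = stack_stage[sp]
        if smaller[v] < 0:  # leaf: uncolor and return
            _apply(
                leaf_id[v], NONE, leaf_comp, par, bot, top, case,
                R, B, RR, BB, RBh, BRh, N,
            )
            continue
        s = smaller[v]
        if stage == 0:
            for i in range(lo[s], hi[s]):
                _apply(
                    leaf_seq[i], BLUE, leaf_comp, par, bot, top, case,
                    R, B, RR, BB, RBh, BRh, N,
                )
            total += N[root_comp]
            for i in range(lo[s], hi[s]):
                _apply(
                    leaf_seq[i], NONE, leaf_comp, par, bot, top, case,
                    R, B, RR, BB, RBh, BRh, N,
                )
            stack_node[sp] = v
            stack_stage[sp] = 1
            sp += 1
            stack_node[sp] = larger[v]
            stack_stage[sp] = 0
            sp += 1
        else:
            for i in range(lo[s], hi[s]):
                _apply(
                    leaf_seq[i], RED, leaf_comp, par, bot, top, case,
                    R, B, RR, BB, RBh, BRh, N,
                )
            stack_node[sp] = s
            stack_stage[sp] = 0
            sp += 1
    return total


def shared_triplets(t1: RootedBinaryTree, hdt, leaf_map: LeafMap) -> int:
    """Shared-triplet count via the fused walk (t1 colored, hdt over t2)."""
    node_ids = leaf_map.node_ids(t1)
    seq, lo, hi = leaf_ranges(t1, node_ids)
    info = compute_node_info(t1)
    nn = t1.n_nodes
    smaller = np.full(nn, -1, dtype=np.int64)
    larger = np.full(nn, -1, dtype=np.int64)
    for v, ni in info.items():
        smaller[v] = ni.smaller
        larger[v] = ni.larger
    total = _fused_shared(
        smaller,
        larger,
        np.asarray(lo, dtype=np.int64),
        np.asarray(hi, dtype=np.int64),
        np.asarray(seq, dtype=np.int64),
        np.asarray(node_ids, dtype=np.int64),
        np.int64(t1.root),
        hdt.kind,
        hdt.parent,
        hdt.bottom,
        hdt.top,
        hdt.case,
        hdt.leaf_comp,
        np.int64(hdt.root),
    )
    return int(total)


def warm_up() -> None:
    """Trigger JIT compilation on a 3-leaf instance (used before timing)."""
    from .treesim import caterpillar

    t = caterpillar(3)
    lm = LeafMap.from_tree(t)
    from .hdt import HDT

    shared_triplets(t, HDT(t, lm), lm)
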