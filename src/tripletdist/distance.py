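"""Triplet distance between two rooted binary trees.

``triplet_distance`` aligns the leaf sets, then dispatches to one of three
algorithms:

``"hdt"`` (default)
    The O(n log^2 n) algorithm: build the hierarchical decomposition tree
    over the second tree, color every leaf red, then run the smaller-half
    walk over the first tree, harvesting the HDT's compatible-triplet
    count at each internal node.
``"quadratic"``
    O(n^2) explicit-coloring reference.
``"brute"``
    O(n^3) triplet enumeration.

All three return identical integers; the slower two exist as oracles and
for small-input cross-checks (``verify=True`` runs hdt and quadratic and
insists they agree).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

from .colorwalk import smaller_half_walk
from .hdt import HDT, BuildStats
from .oracle import Color, brute_force_shared, quadratic_shared
from .treeio import LeafMap, RootedBinaryTree, align_leaf_ids

__all__ = ["DistanceResult", "triplet_distance", "normalized", "VerificationError"]

ALGORITHMS = ("hdt", "quadratic", "brute")


class VerificationError(RuntimeError):
    """The sub-quadratic algorithm disagreed with the quadratic oracle."""


@dataclass(frozen=True)
class DistanceResult:
    """Outcome of a triplet-distance computation.

    ``distance = C(n,3) - shared``; ``normalized`` is ``distance/C(n,3)``
    (0 for n < 3, where there are no triplets).
    """

    n: int
    shared: int
    distance: int
    normalized: float
    algorithm: str
    stats: BuildStats | None = None


def _shared_hdt(
    t1: RootedBinaryTree,
    t2: RootedBinaryTree,
    lm: LeafMap,
    engine: str,
) -> tuple[int, BuildStats]:
    hdt = HDT(t2, lm)
    if engine == "python":
        hdt.bulk_recolor([Color.RED] * len(lm))
        shared = smaller_half_walk(t1, hdt, lm)
    elif engine == "numba":
        from . import _kernels

        shared = _kernels.shared_triplets(t1, hdt, lm)
    else:
        raise ValueError(f"unknown engine {engine!r}; use 'numba' or 'python'")
    return shared, hdt.stats


def triplet_distance(
    t1: RootedBinaryTree,
    t2: RootedBinaryTree,
    algorithm: str = "hdt",
    *,
    engine: str = "numba",
    swap: bool = False,
    verify: bool = False,
) -> DistanceResult:
    """Compute the triplet distance between ``t1`` and ``t2``.

    Parameters
    ----------
    algorithm
        ``"hdt"``, ``"quadratic"`` or ``"brute"``.
    engine
        For ``"hdt"``: ``"numba"`` (fused JIT kernel, default) or
        ``"python"`` (pure-Python walk with the HDT as counting sink).
    swap
        Exchange the roles of the trees (color ``t2``, decompose ``t1``).
        The distance is symmetric; the flag exercises the mirrored
        configuration.
    verify
        With ``algorithm="hdt"``, also run the quadratic reference and
        raise :class:`VerificationError` on any disagreement.

    Raises
    ------
    LeafSetMismatchError
        If the trees' leaf-label sets differ.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    lm = align_leaf_ids(t1, t2)
    if swap:
        t1, t2 = t2, t1
    n = len(lm)
    total = comb(n, 3)
    stats: BuildStats | None = None
    if n < 3:
        shared = 0
    elif algorithm == "brute":
        shared = brute_force_shared(t1, t2, lm)
    elif algorithm == "quadratic":
        shared = quadratic_shared(t1, t2, lm)
    else:
        shared, stats = _shared_hdt(t1, t2, lm, engine)
        if verify:
            reference = quadratic_shared(t1, t2, lm)
            if reference != shared:
                raise VerificationError(
                    f"hdt shared={shared} but quadratic reference={reference}"
                )
    distance = total - shared
    return DistanceResult(
        n=n,
        shared=shared,
        distance=distance,
        normalized=(distance / total) if n >= 3 else 0.0,
        algorithm=algorithm,
        stats=stats,
    )


def normalized(result: DistanceResult) -> float:
    """Distance rescaled by C(n,3) into [0, 1] (0 when n < 3)."""
    return result.normalized
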