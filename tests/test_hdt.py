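import math
import random
from math import comb

import pytest

from tripletdist import (
    Color,
    Counters,
    TreeSimConfig,
    build_hdt,
    count_compatible,
    leaf_counters,
    merge_counters,
    parse_newick,
    random_binary_tree,
)
from tripletdist.hdt import CASE_A, CASE_B, KIND_C, KIND_I, KIND_L, ZERO_COUNTERS
from tripletdist.treeio import LeafMap


def c2(k):
    return k * (k - 1) // 2


class TestLeafCounters:
    @pytest.mark.parametrize(
        "color,expected",
        [
            (Color.RED, Counters(1, 0, 0, 0, 0, 0, 0)),
            (Color.BLUE, Counters(0, 1, 0, 0, 0, 0, 0)),
            (Color.NONE, ZERO_COUNTERS),
        ],
    )
    def test_values(self, color, expected):
        assert leaf_counters(color) == expected


class TestMergeCounters:
    def test_case_b_collapses_to_one_pendant_subtree(self):
        bottom = Counters(2, 0, 0, 0, 0, 0, 0)
        out = merge_counters(bottom, ZERO_COUNTERS, "b")
        assert out == Counters(2, 0, 1, 0, 0, 0, 0)

    def test_case_a_blue_leaf_below_red_component(self):
        bottom = leaf_counters(Color.BLUE)
        top = Counters(1, 0, 0, 0, 0, 0, 0)
        out = merge_counters(bottom, top, "a")
        assert out == Counters(1, 1, 0, 0, 0, 1, 0)

    def test_case_a_completes_triplets(self):
        # two reds below (same pendant subtree), one blue above
        bottom = Counters(2, 0, 1, 0, 0, 0, 0)
        top = leaf_counters(Color.BLUE)
        out = merge_counters(bottom, top, "a")
        assert out.N == c2(2) * 1  # C(R1,2)*B2
        assert out.rb == 2  # R1*B2

    def test_red_blue_exchange_symmetry(self):
        rng = random.Random(0)
        for _ in range(50):
            r1, b1, r2, b2 = (rng.randrange(5) for _ in range(4))
            bot = Counters(r1, b1, c2(r1), c2(b1), rng.randrange(4), rng.randrange(4), 0)
            top = Counters(r2, b2, c2(r2), c2(b2), rng.randrange(4), rng.randrange(4), 0)
            swapped_bot = Counters(bot.B, bot.R, bot.bb, bot.rr, bot.br, bot.rb, bot.N)
            swapped_top = Counters(top.B, top.R, top.bb, top.rr, top.br, top.rb, top.N)
            out = merge_counters(bot, top, "a")
            out_sw = merge_counters(swapped_bot, swapped_top, "a")
            assert out.N == out_sw.N
            assert (out.R, out.B, out.rr, out.bb, out.rb, out.br) == (
                out_sw.B, out_sw.R, out_sw.bb, out_sw.rr, out_sw.br, out_sw.rb
            )


class TestBuild:
    def test_single_leaf(self):
        h = build_hdt(parse_newick("x;"))
        assert h.root == 0
        assert h.kind[h.root] == KIND_L
        assert h.stats.iterations == []

    def test_two_leaf_trace(self):
        """First pass contracts the root-over-first-leaf edge (inner-node
        capping); the sibling edge is deferred and contracted in a second
        pass by spine extension."""
        h = build_hdt(parse_newick("(a,b);"))
        assert len(h.stats.iterations) == 2
        assert [it.contracted for it in h.stats.iterations] == [1, 1]
        # composed components are created in contraction order
        assert list(h.case[3:]) == [CASE_B, CASE_A]
        assert h.kind[h.root] == KIND_C

    def test_balanced_four_leaf_first_pass(self):
        h = build_hdt(parse_newick("((a,b),(c,d));"))
        it0 = h.stats.iterations[0]
        assert it0.edges == 6 and it0.contracted == 2
        nn = 7  # base components
        assert list(h.case[nn:nn + 2]) == [CASE_B, CASE_B]

    @pytest.mark.parametrize("model", ["yule", "caterpillar", "balanced"])
    @pytest.mark.parametrize("n", [2, 5, 37, 400])
    def test_component_census(self, model, n):
        t = random_binary_tree(TreeSimConfig(n, model, 21))
        h = build_hdt(t)
        kinds = list(h.kind)
        assert kinds.count(KIND_L) == n
        assert kinds.count(KIND_I) == n - 1
        assert kinds.count(KIND_C) == 2 * n - 2
        assert h.stats.n_components == 4 * n - 3

    @pytest.mark.parametrize("n", [10, 100, 1000])
    @pytest.mark.parametrize("model", ["yule", "caterpillar"])
    def test_geometric_contraction_and_height(self, n, model):
        t = random_binary_tree(TreeSimConfig(n, model, 31))
        h = build_hdt(t)
        for it in h.stats.iterations:
            assert it.contracted >= 1  # liveness whenever edges remain
            assert it.edges - it.contracted <= (11 * it.edges) / 12
            assert 3 * it.contracted >= it.contractible
        bound = math.ceil(math.log(2 * n - 2) / math.log(12 / 11))
        assert len(h.stats.iterations) <= bound
        assert h.stats.height <= len(h.stats.iterations) + 1


def _random_hdt(seed):
    rng = random.Random(seed)
    n = rng.randint(3, 30)
    t = random_binary_tree(
        TreeSimConfig(n, rng.choice(["yule", "uniform", "caterpillar"]), seed)
    )
    lm = LeafMap.from_tree(t)
    return t, lm, build_hdt(t, lm), rng


class TestCounterMaintenance:
    def test_all_none_is_all_zero(self):
        t, lm, h, _ = _random_hdt(1)
        h.bulk_recolor([Color.NONE] * len(lm))
        for c in range(h.n_components):
            assert h.counters(c) == ZERO_COUNTERS
        assert h.root_count() == 0

    def test_all_red_has_no_compatible_triplets(self):
        t, lm, h, _ = _random_hdt(2)
        n = len(lm)
        h.bulk_recolor([Color.RED] * n)
        root = h.counters(h.root)
        assert (root.R, root.B, root.N) == (n, 0, 0)

    def test_three_leaf_coloring_trace(self):
        t = parse_newick("((a,b),c);")
        lm = LeafMap.from_tree(t)
        h = build_hdt(t, lm)
        h.set_leaf_color(lm["a"], Color.RED)
        h.set_leaf_color(lm["b"], Color.RED)
        h.set_leaf_color(lm["c"], Color.BLUE)
        assert h.root_count() == 1
        coloring = [Color.NONE] * 3
        coloring[lm["a"]] = coloring[lm["b"]] = Color.RED
        coloring[lm["c"]] = Color.BLUE
        assert h.root_count() == count_compatible(t, coloring, lm)

    def test_recoloring_to_same_color_is_idempotent(self):
        t, lm, h, rng = _random_hdt(3)
        coloring = [Color(rng.randrange(3)) for _ in range(len(lm))]
        h.bulk_recolor(coloring)
        before = [h.counters(c) for c in range(h.n_components)]
        for leaf in range(len(lm)):
            h.set_leaf_color(leaf, coloring[leaf])
        after = [h.counters(c) for c in range(h.n_components)]
        assert before == after

    @pytest.mark.parametrize("seed", range(12))
    def test_incremental_updates_match_oracle(self, seed):
        """root_count tracks count_compatible through random recolorings."""
        t, lm, h, rng = _random_hdt(seed + 100)
        n = len(lm)
        coloring = [Color.NONE] * n
        h.bulk_recolor(coloring)
        for _ in range(60):
            leaf = rng.randrange(n)
            col = Color(rng.randrange(3))
            coloring[leaf] = col
            h.set_leaf_color(leaf, col)
            assert h.root_count() == count_compatible(t, coloring, lm)

    @pytest.mark.parametrize("seed", range(8))
    def test_incremental_equals_bulk(self, seed):
        t, lm, h, rng = _random_hdt(seed + 300)
        n = len(lm)
        coloring = [Color(rng.randrange(3)) for _ in range(n)]
        order = list(range(n))
        rng.shuffle(order)
        for leaf in order:
            h.set_leaf_color(leaf, coloring[leaf])
        incremental = [h.counters(c) for c in range(h.n_components)]
        h2 = build_hdt(t, lm)
        h2.bulk_recolor(coloring)
        assert incremental == [h2.counters(c) for c in range(h2.n_components)]

    @pytest.mark.parametrize("seed", range(5))
    def test_counter_bounds_hold_everywhere(self, seed):
        t, lm, h, rng = _random_hdt(seed + 700)
        n = len(lm)
        h.bulk_recolor([Color(rng.randrange(3)) for _ in range(n)])
        for c in range(h.n_components):
            k = h.counters(c)
            assert k.rr <= c2(k.R) and k.bb <= c2(k.B)
            assert k.rb <= k.R * k.B and k.br <= k.R * k.B
            assert k.N <= comb(k.R + k.B, 3)

    def test_unknown_leaf_rejected(self):
        _, lm, h, _ = _random_hdt(4)
        with pytest.raises(LookupError):
            h.set_leaf_color(len(lm) + 5, Color.RED)
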