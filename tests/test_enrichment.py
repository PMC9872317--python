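"""P-value partitioning, over-representation analysis, category mapping."""

import math

import numpy as np
import pandas as pd
import pytest

from spermre.enrichment import (
    DEFAULT_BOUNDARIES,
    GroupCapacityError,
    assign_group,
    categorize,
    ora,
    partition_by_pvalue,
    proportion_test,
)
from spermre.simulate import SimulationConfig, simulate_gmt


@pytest.mark.parametrize(
    "p, group",
    [
        (0.010, 1), (0.020, 2), (0.046, 6),
        (0.0129, 1), (0.013, 2), (0.023, 2), (0.0231, 3),
        (0.032, 3), (0.041, 4), (0.045, 5), (0.05, 6),
    ],
)
def test_assign_group_boundaries(p, group):
    assert assign_group(p) == group


@pytest.mark.parametrize("p", [0.0, -0.1, 0.051, 1.0])
def test_assign_group_rejects_out_of_range(p):
    with pytest.raises(ValueError):
        assign_group(p)


def _entries(ps, genes=None):
    genes = genes or [f"G{i}" for i in range(len(ps))]
    return pd.DataFrame(
        {"re_id": [f"r{i}" for i in range(len(ps))], "gene": genes,
         "empirical_p": ps}
    )


def test_partition_complete_and_disjoint():
    rng = np.random.default_rng(5)
    ps = 0.05 * (1 - rng.random(500))
    groups = partition_by_pvalue(_entries(ps))
    assert sum(groups.sizes) == 500
    seen = pd.concat(groups.groups)["re_id"]
    assert len(seen) == len(set(seen)) == 500


def test_partition_empty_input():
    groups = partition_by_pvalue(_entries([]))
    assert groups.sizes == [0] * 6


def test_partition_capacity_error_names_group():
    entries = _entries([0.001] * 501, genes=[f"G{i}" for i in range(501)])
    with pytest.raises(GroupCapacityError, match="group 1"):
        partition_by_pvalue(entries, cap=500)


def test_partition_recognized_counts_use_universe():
    entries = _entries([0.001, 0.001, 0.03], genes=["A", "B", "C"])
    groups = partition_by_pvalue(entries, symbol_universe=["A", "C"])
    assert groups.recognized_counts[0] == 1   # only A recognized in group 1
    assert groups.recognized_counts[2] == 1   # C in group 3


def brute_force_upper_tail(k, N, K, n):
    total = math.comb(N, n)
    hi = min(K, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, hi + 1)) / total


def bh_step_up(ps):
    """Independent Benjamini–Hochberg step-up q-values."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, ps[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestORA:
    def setup_method(self):
        self.universe = [f"G{i:04d}" for i in range(1000)]
        self.collection = {
            "HIT_SET": set(self.universe[:20]),
            "OTHER_A": set(self.universe[100:140]),
            "OTHER_B": set(self.universe[500:520]),
        }
        # query of 10 genes, 5 inside HIT_SET
        self.query = self.universe[:5] + self.universe[900:905]

    def test_p_matches_enumeration(self):
        out = ora(self.query, self.collection, self.universe, q_max=1.1)
        row = out.set_index("set_name").loc["HIT_SET"]
        assert row["p"] == pytest.approx(
            brute_force_upper_tail(5, 1000, 20, 10), rel=1e-10)

    def test_min_overlap_suppresses_singletons(self):
        coll = {"ONE": {"G0000", "G0500"}, "HIT": set(self.universe[:20])}
        out = ora(self.universe[:1] + self.universe[10:20], coll, self.universe,
                  q_max=1.1)
        assert "ONE" not in set(out["set_name"])  # k == 1 suppressed

    def test_whole_set_query_ranks_first(self):
        out = ora(list(self.collection["OTHER_B"]), self.collection,
                  self.universe, q_max=1.1)
        assert out.iloc[0]["set_name"] == "OTHER_B"

    def test_q_matches_independent_bh(self):
        rng = np.random.default_rng(17)
        universe = [f"G{i:04d}" for i in range(400)]
        collection = {
            f"S{j}": set(rng.choice(universe, size=rng.integers(5, 40),
                                    replace=False))
            for j in range(15)
        }
        query = list(rng.choice(universe, size=30, replace=False))
        out = ora(query, collection, universe, q_max=1.1, min_overlap=0)
        # recompute every tested p, then BH by the step-up definition
        ps, names = [], []
        qgenes = set(query)
        for name, members in collection.items():
            k = len(qgenes & members)
            ps.append(brute_force_upper_tail(k, len(universe), len(members),
                                             len(query)))
            names.append(name)
        expected_q = dict(zip(names, bh_step_up(ps)))
        got = out.set_index("set_name")["q"]
        for name in got.index:
            assert got[name] == pytest.approx(expected_q[name], rel=1e-9)

    def test_planted_set_recovered(self):
        cfg = SimulationConfig(seed=3)
        genes = [f"G{i:04d}" for i in range(2000)]
        collection, planted, query = simulate_gmt(cfg, genes)
        out = ora(query, collection, genes)
        assert out.iloc[0]["set_name"] == planted
        assert out.iloc[0]["q"] < 0.05

    def test_top_truncation(self):
        out = ora(self.query, self.collection, self.universe, q_max=1.1, top=1)
        assert len(out) == 1

    def test_empty_collection_errors(self):
        with pytest.raises(ValueError):
            ora(self.query, {}, self.universe)


@pytest.mark.parametrize(
    "name, category",
    [
        ("GOBP_PROGRAMMED_CELL_DEATH", "apoptosis"),
        ("HALLMARK_G2M_CHECKPOINT", "cell cycle"),
        ("DACOSTA_UV_RESPONSE_VIA_ERCC3_DN", "DNA damage response"),
        ("REACTOME_CELLULAR_RESPONSES_TO_STIMULI", "cellular stress"),
        ("GOMF_CHROMATIN_BINDING", "gene regulation"),
        ("XYZ_SIGNATURE", "uncategorized"),
        ("GOBP cellular response to stress", "cellular stress"),
    ],
)
def test_categorize_default_map(name, category):
    assert categorize(name) == category


def test_categorize_first_match_wins_and_is_stable():
    # order-preserving reload of the same map gives identical answers
    from spermre.enrichment import DEFAULT_CATEGORY_MAP

    reloaded = tuple(DEFAULT_CATEGORY_MAP)
    for name in ("GOBP_PROGRAMMED_CELL_DEATH", "HALLMARK_G2M_CHECKPOINT"):
        assert categorize(name, reloaded) == categorize(name)


def test_proportion_test_delegates_to_hypergeometric():
    background = [f"G{i}" for i in range(100)]
    annotation = background[:20]
    genes = background[:10]  # fully inside the annotation
    res = proportion_test(genes, annotation, background)
    assert res.x == 10 and res.n1 == 10 and res.n2 == 20 and res.N == 100
    assert res.representation_factor == pytest.approx(10 / (10 * 20 / 100))
    with pytest.raises(ValueError):
        proportion_test([], annotation, background)
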