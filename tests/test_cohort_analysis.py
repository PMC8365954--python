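"""Cohort statistics: presence matrices, Fisher tests, attribution, IFC."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromloop.cohort_analysis import (
    PresenceMatrix,
    anchor_change_attribution,
    build_presence_matrix,
    conservation_profile,
    differential_interactions,
    fisher_exact_presence,
    ifc_score,
)
from chromloop.genome_io import AnchorPair, GenomicInterval


def _pair(chrom, s1, s2, width=500):
    return AnchorPair(
        GenomicInterval(chrom, s1, s1 + width),
        GenomicInterval(chrom, s2, s2 + width),
    )


def _matrix_from_array(arr, samples, groups=None, chrom="chr1"):
    pairs = {}
    keys = []
    for i in range(arr.shape[0]):
        p = _pair(chrom, 1000 * i, 1000 * i + 100_000)
        pairs[p.id] = p
        keys.append(p.id)
    df = pd.DataFrame(arr, index=pd.Index(keys), columns=samples)
    return PresenceMatrix(df, pairs, groups)


def fisher_oracle(a, n_a, b, n_b):
    """Exhaustive enumeration over all tables with fixed margins, in exact
    rational arithmetic."""
    x = a + b
    n = n_a + n_b
    total = Fraction(0)
    tail = Fraction(0)
    obs = Fraction(comb(n_a, a) * comb(n_b, b))
    for k in range(0, min(n_a, x) + 1):
        if x - k > n_b:
            continue
        w = Fraction(comb(n_a, k) * comb(n_b, x - k))
        total += w
        if w <= obs:
            tail += w
    return float(tail / total)


class TestFisher:
    def test_worked_example_two_of_two_vs_zero_of_four(self):
        assert fisher_exact_presence(2, 2, 0, 4) == pytest.approx(1 / 15, abs=1e-15)

    def test_equal_rates_give_one(self):
        assert fisher_exact_presence(2, 4, 2, 4) == 1.0

    def test_degenerate_all_present(self):
        assert fisher_exact_presence(3, 3, 4, 4) == 1.0

    def test_symmetric_under_group_relabeling(self, rng):
        for _ in range(200):
            n_a, n_b = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            a, b = int(rng.integers(0, n_a + 1)), int(rng.integers(0, n_b + 1))
            assert fisher_exact_presence(a, n_a, b, n_b) == pytest.approx(
                fisher_exact_presence(b, n_b, a, n_a), abs=1e-12
            )

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        for _ in range(1000):
            n_a, n_b = int(rng.integers(1, 11)), int(rng.integers(1, 11))
            a, b = int(rng.integers(0, n_a + 1)), int(rng.integers(0, n_b + 1))
            assert fisher_exact_presence(a, n_a, b, n_b) == pytest.approx(
                fisher_oracle(a, n_a, b, n_b), abs=1e-12
            )

    def test_agrees_with_scipy(self, rng):
        for _ in range(200):
            n_a, n_b = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            a, b = int(rng.integers(0, n_a + 1)), int(rng.integers(0, n_b + 1))
            table = [[a, n_a - a], [b, n_b - b]]
            expected = stats.fisher_exact(table, alternative="two-sided")[1]
            assert fisher_exact_presence(a, n_a, b, n_b) == pytest.approx(
                expected, rel=1e-7
            )


class TestPresenceMatrix:
    def test_shared_interaction_row(self):
        p1, p2, p3 = (_pair("chr1", i * 10_000, i * 10_000 + 50_000) for i in range(3))
        universe = [p.left for p in (p1, p2, p3)] + [p.right for p in (p1, p2, p3)]
        preds = {
            "s1": [p1.with_score(0.9), p2.with_score(0.8)],
            "s2": [p1.with_score(0.7), p3.with_score(0.9)],
        }
        m = build_presence_matrix(preds, universe)
        assert m.matrix.shape == (3, 2)
        assert m.matrix.loc[p1.id].tolist() == [1, 1]

    def test_identical_samples_identical_columns(self):
        p1 = _pair("chr1", 0, 60_000)
        universe = [p1.left, p1.right]
        preds = {"a": [p1.with_score(1.0)], "b": [p1.with_score(1.0)]}
        m = build_presence_matrix(preds, universe)
        assert (m.matrix["a"] == m.matrix["b"]).all()

    def test_below_threshold_not_present(self):
        p1 = _pair("chr1", 0, 60_000)
        universe = [p1.left, p1.right]
        m = build_presence_matrix(
            {"a": [p1.with_score(0.4)], "b": [p1.with_score(0.9)]},
            universe,
            thresholds={"a": 0.5, "b": 0.5},
        )
        assert m.matrix.loc[p1.id].tolist() == [0, 1]

    def test_anchor_outside_universe_rejected(self):
        p1 = _pair("chr1", 0, 60_000)
        with pytest.raises(ValueError, match="universe"):
            build_presence_matrix({"a": [p1.with_score(1.0)]}, [p1.left])


class TestConservation:
    def test_all_shared(self):
        m = _matrix_from_array(np.ones((4, 3), dtype=int), ["a", "b", "c"])
        prof = conservation_profile(m)
        assert prof.loc[3] == 1.0 and prof.loc[1] == 0.0

    def test_all_unique(self):
        arr = np.eye(3, dtype=int)
        m = _matrix_from_array(arr, ["a", "b", "c"])
        prof = conservation_profile(m)
        assert prof.loc[1] == 1.0

    def test_matches_row_sum_histogram(self, rng):
        arr = rng.integers(0, 2, size=(200, 5))
        arr = arr[arr.sum(axis=1) > 0]
        m = _matrix_from_array(arr, [f"s{i}" for i in range(5)])
        prof = conservation_profile(m)
        hist = np.bincount(arr.sum(axis=1), minlength=6)[1:] / len(arr)
        assert np.allclose(prof.to_numpy(), hist)
        assert prof.sum() == pytest.approx(1.0)


class TestDifferential:
    def test_planted_difference_detected(self):
        # 10 interactions: first present in group A only, rest everywhere
        arr = np.ones((10, 8), dtype=int)
        arr[0, 4:] = 0
        groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        m = _matrix_from_array(arr, [f"s{i}" for i in range(8)], groups)
        res = differential_interactions(m)
        assert res[0].p_value == pytest.approx(fisher_oracle(4, 4, 0, 4), abs=1e-12)
        assert res[0].direction == "A"
        # degenerate rows get p = 1
        assert all(r.p_value == 1.0 for r in res[1:])

    def test_bh_monotone_in_raw_p(self, rng):
        arr = rng.integers(0, 2, size=(100, 8))
        arr = arr[(arr.sum(axis=1) > 0)]
        groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        m = _matrix_from_array(arr, [f"s{i}" for i in range(8)], groups)
        res = differential_interactions(m)
        order = np.argsort([r.p_value for r in res], kind="stable")
        adj_sorted = np.array([res[i].adjusted_p for i in order])
        assert np.all(np.diff(adj_sorted) >= -1e-12)
        assert all(r.adjusted_p >= r.p_value - 1e-12 for r in res)


class TestAttribution:
    def test_planted_attribution(self):
        # interaction 0: both anchors differential; 1: one; 2: neither
        pairs = [_pair("chr1", i * 100_000, i * 100_000 + 50_000) for i in range(3)]
        samples = [f"s{i}" for i in range(12)]
        groups = {s: ("A" if i < 6 else "B") for i, s in enumerate(samples)}
        arr = np.zeros((3, 12), dtype=int)
        arr[:, :6] = 1  # all three interactions are A-specific
        keys = [p.id for p in pairs]
        m = PresenceMatrix(
            pd.DataFrame(arr, index=pd.Index(keys), columns=samples),
            {p.id: p for p in pairs},
            groups,
        )
        diff = differential_interactions(m)
        assert all(r.adjusted_p <= 0.05 for r in diff)

        anchor_rows = {}
        for i, p in enumerate(pairs):
            for j, anchor in enumerate((p.left, p.right)):
                sig = (i == 0) or (i == 1 and j == 0)
                anchor_rows[anchor.id] = [1 if (k < 6 and sig) else 0 for k in range(12)]
        anchor_df = pd.DataFrame.from_dict(anchor_rows, orient="index", columns=samples)
        counts, labeled = anchor_change_attribution(diff, anchor_df, groups)
        assert counts == {"both": 1, "one-side": 1, "neither": 1}

    def test_counts_partition_significant_set(self, rng):
        pairs = [_pair("chr1", i * 100_000, i * 100_000 + 50_000) for i in range(20)]
        samples = [f"s{i}" for i in range(10)]
        groups = {s: ("A" if i < 5 else "B") for i, s in enumerate(samples)}
        arr = rng.integers(0, 2, size=(20, 10))
        arr[:, 0] = 1
        keys = [p.id for p in pairs]
        m = PresenceMatrix(
            pd.DataFrame(arr, index=pd.Index(keys), columns=samples),
            {p.id: p for p in pairs},
            groups,
        )
        diff = differential_interactions(m)
        anchor_ids = list(dict.fromkeys(
            a.id for p in pairs for a in (p.left, p.right)
        ))
        anchor_df = pd.DataFrame(
            rng.integers(0, 2, size=(len(anchor_ids), 10)),
            index=pd.Index(anchor_ids),
            columns=samples,
        )
        counts, _ = anchor_change_attribution(diff, anchor_df, groups)
        n_sig = sum(1 for r in diff if r.adjusted_p <= 0.05)
        assert sum(counts.values()) == n_sig


class TestIFC:
    def _setup(self):
        # 2 genes; gene1 promoter touched by interactions 0,1; gene2 by 2
        pairs = [
            _pair("chr1", 1000, 80_000),
            _pair("chr1", 1200, 150_000),
            _pair("chr1", 300_000, 420_000),
        ]
        promoters = [
            GenomicInterval("chr1", 900, 2000, annotations=("gene1",)),
            GenomicInterval("chr1", 299_000, 301_000, annotations=("gene2",)),
            GenomicInterval("chr2", 0, 2000, annotations=("gene_orphan",)),
        ]
        samples = ["u1", "u2", "m1", "m2"]
        groups = {"u1": "u", "u2": "u", "m1": "m", "m2": "m"}
        arr = np.array(
            [
                [1, 1, 1, 0],  # int0
                [1, 1, 0, 1],  # int1
                [1, 0, 1, 1],  # int2
            ]
        )
        keys = [p.id for p in pairs]
        m = PresenceMatrix(
            pd.DataFrame(arr, index=pd.Index(keys), columns=samples),
            {p.id: p for p in pairs},
            groups,
        )
        return promoters, m

    def test_hand_computed_ifc(self):
        promoters, m = self._setup()
        with pytest.warns(UserWarning, match="promoter"):
            df, _ = ifc_score(promoters, m, "u", "m")
        g1 = df.set_index("gene").loc["gene1"]
        # gene1 counts: u1=2, u2=2, m1=1, m2=1 -> IFC = 2.0
        assert g1["ifc"] == pytest.approx(2.0)
        g2 = df.set_index("gene").loc["gene2"]
        # gene2 counts: u1=1, u2=0, m1=1, m2=1 -> IFC = 0.5
        assert g2["ifc"] == pytest.approx(0.5)
        assert "gene_orphan" not in set(df["gene"])

    def test_zero_denominator_flagged(self):
        promoters, m = self._setup()
        with pytest.warns(UserWarning):
            df, _ = ifc_score(promoters, m, "u", "m")
        assert df["defined"].all()
        # reverse groups on a matrix where one group never touches gene2
        m.matrix.loc[:, ["m1", "m2"]] = 0
        with pytest.warns(UserWarning):
            df2, _ = ifc_score(promoters, m, "u", "m")
        assert not df2["defined"].any() or np.isnan(df2["ifc"]).any()

    def test_kruskal_wallis_delegation(self):
        promoters, m = self._setup()
        classes = {"gene1": "up", "gene2": "down"}
        with pytest.warns(UserWarning):
            df, kw = ifc_score(promoters, m, "u", "m", expression_classes=classes)
        # two singleton classes: KW is computable and in (0, 1]
        assert kw is None or 0 < kw <= 1
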