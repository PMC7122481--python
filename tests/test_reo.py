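import numpy as np
import pytest

import reosig as rs
from reosig.reo import GenePair, DIRECTION_GT, DIRECTION_LT

from conftest import make_matrix, random_matrix
import _oracles


class TestGenePair:
    def test_canonical_storage(self):
        p = GenePair.of("ZNF1", "ABC")
        assert (p.gene_a, p.gene_b) == ("ABC", "ZNF1")

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError):
            GenePair.of("A", "A")

    def test_non_canonical_direct_construction_rejected(self):
        with pytest.raises(ValueError):
            GenePair("B", "A")


class TestPairOrderStats:
    def test_strict_dominance(self):
        m = make_matrix([[1, 2, 3], [0, 1, 2]], gene_ids=["a", "b"])
        (st,) = rs.pair_order_stats(m)
        assert (st.n_gt, st.n_lt, st.n_tie, st.n_missing) == (3, 0, 0, 0)

    def test_all_ties(self):
        m = make_matrix([[1, 2], [1, 2]], gene_ids=["a", "b"])
        (st,) = rs.pair_order_stats(m)
        assert st.n_tie == 2 and st.n_gt == st.n_lt == 0

    def test_missing_handling(self):
        m = make_matrix([[5, np.nan], [1, 7]], gene_ids=["a", "b"])
        (st,) = rs.pair_order_stats(m)
        assert (st.n_gt, st.n_missing) == (1, 1)
        assert st.n_samples == 2

    def test_counts_sum_to_sample_count(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, 8, 15, missing_rate=0.2, tie_prone=True)
        for st in rs.pair_order_stats(m):
            assert st.n_gt + st.n_lt + st.n_tie + st.n_missing == 15

    def test_single_gene_errors(self):
        m = make_matrix([[1, 2]], gene_ids=["a"])
        with pytest.raises(ValueError):
            list(rs.pair_order_stats(m))

    def test_blocked_union_equals_whole(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 12, 9, missing_rate=0.1)
        whole = list(rs.pair_order_stats(m))
        blocked = []
        for start in range(0, 12, 5):
            blocked.extend(rs.pair_order_stats(m, pair_block=(start, start + 5)))
        assert blocked == whole


class TestFindStablePairs:
    def test_inclusive_boundary_at_95_percent(self):
        # 19 of 20 samples with a > b is exactly 95%: stable (inclusive >=)
        a = np.r_[np.full(19, 2.0), 1.0]
        b = np.r_[np.full(19, 1.0), 2.0]
        m = make_matrix(np.vstack([a, b]), gene_ids=["a", "b"])
        ps = rs.find_stable_pairs(m, threshold=0.95)
        assert len(ps) == 1
        row = ps.table.iloc[0]
        assert row["direction"] == DIRECTION_GT
        assert row["consistency_pos"] == pytest.approx(0.95)

    def test_below_threshold_not_stable(self):
        a = np.r_[np.full(18, 2.0), 1.0, 1.0]
        b = np.r_[np.full(18, 1.0), 2.0, 2.0]
        m = make_matrix(np.vstack([a, b]), gene_ids=["a", "b"])
        assert len(rs.find_stable_pairs(m, threshold=0.95)) == 0

    def test_ties_and_missing_count_against_stability(self):
        # 19/20 greater, 1 tie -> stable; 18 greater + 1 tie + 1 missing -> not
        a = np.r_[np.full(19, 2.0), 1.0]
        b = np.r_[np.full(19, 1.0), 1.0]
        m = make_matrix(np.vstack([a, b]), gene_ids=["a", "b"])
        assert len(rs.find_stable_pairs(m)) == 1
        a2 = np.r_[np.full(18, 2.0), 1.0, np.nan]
        b2 = np.r_[np.full(18, 1.0), 1.0, 1.0]
        m2 = make_matrix(np.vstack([a2, b2]), gene_ids=["a", "b"])
        assert len(rs.find_stable_pairs(m2)) == 0

    def test_threshold_validation(self):
        m = make_matrix([[1, 2], [0, 1]], gene_ids=["a", "b"])
        for bad in (0.5, 0.2, 1.01):
            with pytest.raises(ValueError):
                rs.find_stable_pairs(m, threshold=bad)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_matrix(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 50, 30, missing_rate=0.05, tie_prone=(seed == 2))
        got = rs.find_stable_pairs(m, threshold=0.95)
        expected = _oracles.stable_pairs_brute(m.gene_ids, m.values, 0.95)
        result = {
            (r.gene_a, r.gene_b): r.direction for r in got.table.itertuples()
        }
        assert result == expected

    @pytest.mark.parametrize("block_size", [1, 3, 7, 1000])
    def test_independent_of_block_size(self, block_size):
        rng = np.random.default_rng(17)
        m = random_matrix(rng, 20, 25, missing_rate=0.1)
        base = rs.find_stable_pairs(m, threshold=0.9)
        other = rs.find_stable_pairs(m, threshold=0.9, block_size=block_size)
        assert other.table.equals(base.table)


class TestFindReversalPairs:
    def _stable(self, rows):
        import pandas as pd

        t = pd.DataFrame(rows, columns=["gene_a", "gene_b", "direction", "consistency_pos"])
        t["consistency_neg"] = np.nan
        return rs.REOPairSet(t, kind="stable")

    def test_opposite_directions_included(self):
        pos = self._stable([("a", "b", "GT", 0.98)])
        neg = self._stable([("a", "b", "LT", 0.97)])
        rev = rs.find_reversal_pairs(pos, neg)
        assert len(rev) == 1
        row = rev.table.iloc[0]
        assert row["direction"] == "GT"  # positive-group reference orientation
        assert row["consistency_pos"] == pytest.approx(0.98)
        assert row["consistency_neg"] == pytest.approx(0.97)

    def test_same_direction_excluded(self):
        pos = self._stable([("a", "b", "GT", 1.0)])
        neg = self._stable([("a", "b", "GT", 1.0)])
        assert len(rs.find_reversal_pairs(pos, neg)) == 0

    def test_pair_stable_in_one_group_only_excluded(self):
        pos = self._stable([("a", "b", "GT", 1.0), ("a", "c", "LT", 0.96)])
        neg = self._stable([("a", "b", "LT", 1.0)])
        rev = rs.find_reversal_pairs(pos, neg)
        assert [(r.gene_a, r.gene_b) for r in rev.table.itertuples()] == [("a", "b")]

    def test_symmetric_under_group_exchange_up_to_orientation(self):
        pos = self._stable([("a", "b", "GT", 0.98), ("c", "d", "LT", 0.96)])
        neg = self._stable([("a", "b", "LT", 0.99), ("c", "d", "GT", 1.0)])
        fwd = rs.find_reversal_pairs(pos, neg)
        rev = rs.find_reversal_pairs(neg, pos)
        assert set(zip(fwd.table.gene_a, fwd.table.gene_b)) == set(
            zip(rev.table.gene_a, rev.table.gene_b)
        )
        for (_, f), (_, r) in zip(fwd.table.iterrows(), rev.table.iterrows()):
            assert f["direction"] != r["direction"]
            assert f["consistency_pos"] == r["consistency_neg"]

    def test_planted_reversals_recovered_exactly(self):
        """12 planted pairs at consistency 1 among 200+ background genes."""
        cfg = rs.SyntheticConfig(
            n_genes=224, n_planted_pairs=12, n_pos=60, n_neg=60,
            consistency=1.0, mean_gap=2.0, noise_sd=0.25, seed=42,
        )
        m, labels, truth = rs.generate(cfg)
        pos = rs.find_stable_pairs(
            rs.ExpressionMatrix(m.gene_ids, m.sample_ids[:60], m.values[:, :60])
        )
        neg = rs.find_stable_pairs(
            rs.ExpressionMatrix(m.gene_ids, m.sample_ids[60:], m.values[:, 60:])
        )
        rev = rs.find_reversal_pairs(pos, neg)
        assert set(zip(rev.table.gene_a, rev.table.gene_b)) == truth.planted_pairs()


class TestEncodeProfile:
    def test_encoding_rule(self):
        m = make_matrix([[7, 3], [3, 7]], gene_ids=["a", "b"], sample_ids=["s1", "s2"])
        pairs = rs.find_stable_pairs(
            make_matrix([[7, 8], [3, 4]], gene_ids=["a", "b"])
        )
        prof = rs.encode_profile(m, pairs)
        np.testing.assert_array_equal(prof.values, [[1, 0]])

    def test_absent_gene_encodes_minus_one_everywhere(self):
        train = make_matrix([[7, 8], [3, 4]], gene_ids=["a", "b"])
        pairs = rs.find_stable_pairs(train)
        validation = make_matrix([[1, 2]], gene_ids=["a"])
        prof = rs.encode_profile(validation, pairs)
        np.testing.assert_array_equal(prof.values, [[-1, -1]])

    def test_tie_encodes_zero(self):
        train = make_matrix([[7, 8], [3, 4]], gene_ids=["a", "b"])
        pairs = rs.find_stable_pairs(train)
        tied = make_matrix([[5.0], [5.0]], gene_ids=["a", "b"])
        prof = rs.encode_profile(tied, pairs)
        np.testing.assert_array_equal(prof.values, [[0]])

    def test_matches_per_cell_brute_force(self):
        rng = np.random.default_rng(23)
        m = random_matrix(rng, 10, 8, missing_rate=0.15)
        pos = random_matrix(rng, 10, 12)
        # negation flips every ordering: all stable pairs become reversals
        neg = rs.ExpressionMatrix(pos.gene_ids, pos.sample_ids, -pos.values)
        pairs = rs.find_reversal_pairs(
            rs.find_stable_pairs(pos, 0.9), rs.find_stable_pairs(neg, 0.9)
        )
        assert len(pairs) > 0
        prof = rs.encode_profile(m, pairs)
        by_gene = {g: list(m.values[i]) for i, g in enumerate(m.gene_ids)}
        expected = _oracles.encode_brute(by_gene, m.n_samples, pairs.oriented_pairs())
        np.testing.assert_array_equal(prof.values, np.asarray(expected))

    def test_antisymmetry_under_orientation_swap(self):
        """Flipping a pair's reference direction maps 1<->0, fixes -1."""
        rng = np.random.default_rng(9)
        m = random_matrix(rng, 6, 10, missing_rate=0.2)
        train = random_matrix(rng, 6, 10)
        pairs = rs.find_stable_pairs(train, 0.8)
        assert len(pairs) > 0
        flipped_table = pairs.table.copy()
        flipped_table["direction"] = [
            "LT" if d == "GT" else "GT" for d in flipped_table["direction"]
        ]
        flipped = rs.REOPairSet(flipped_table, kind=pairs.kind)
        p1 = rs.encode_profile(m, pairs)
        p2 = rs.encode_profile(m, flipped)
        # on tie-free cells: 1 <-> 0; missing stays -1 (ties also encode 0,
        # so compare only where no tie occurred)
        a, b = p1.values, p2.values
        assert ((a == -1) == (b == -1)).all()
        nonmissing = a != -1
        ga = [pairs.table.gene_a.iloc[i] for i in range(len(pairs))]
        gb = [pairs.table.gene_b.iloc[i] for i in range(len(pairs))]
        idx = m.gene_index()
        ties = np.vstack(
            [m.values[idx[x]] == m.values[idx[y]] for x, y in zip(ga, gb)]
        )
        mask = nonmissing & ~ties
        assert (a[mask] + b[mask] == 1).all()


class TestMonotoneInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_stats_and_encoding_unchanged_by_monotone_transform(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = random_matrix(rng, 15, 12, missing_rate=0.1)
        distorted = rs.apply_monotone_distortion(m, seed=seed)
        # per-pair order statistics identical
        s1 = list(rs.pair_order_stats(m))
        s2 = list(rs.pair_order_stats(distorted))
        assert s1 == s2
        # stable pair sets identical
        sp1 = rs.find_stable_pairs(m, 0.8)
        sp2 = rs.find_stable_pairs(distorted, 0.8)
        assert sp1.table.equals(sp2.table)
        if len(sp1) > 0:
            p1 = rs.encode_profile(m, sp1)
            p2 = rs.encode_profile(distorted, sp1)
            np.testing.assert_array_equal(p1.values, p2.values)


class TestPairSetIO:
    def test_pair_set_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(31)
        pos = random_matrix(rng, 12, 15)
        neg = rs.ExpressionMatrix(pos.gene_ids, pos.sample_ids, -pos.values)
        rev = rs.find_reversal_pairs(
            rs.find_stable_pairs(pos, 0.9), rs.find_stable_pairs(neg, 0.9)
        )
        assert len(rev) > 0
        rev.write_tsv(tmp_path / "pairs.tsv")
        back = rs.REOPairSet.read_tsv(tmp_path / "pairs.tsv")
        assert back.table.gene_a.tolist() == rev.table.gene_a.tolist()
        assert back.table.direction.tolist() == rev.table.direction.tolist()
        np.testing.assert_allclose(back.table.consistency_pos, rev.table.consistency_pos)

    def test_profile_tsv_round_trip(self, tmp_path):
        prof = rs.REOProfile(
            ["a|b", "c|d"], ["s1", "s2", "s3"], np.array([[1, 0, -1], [0, 0, 1]])
        )
        prof.write_tsv(tmp_path / "prof.tsv")
        back = rs.REOProfile.read_tsv(tmp_path / "prof.tsv")
        assert back.pair_ids == prof.pair_ids
        assert back.sample_ids == prof.sample_ids
        np.testing.assert_array_equal(back.values, prof.values)

    def test_profile_alphabet_enforced(self):
        with pytest.raises(ValueError):
            rs.REOProfile(["a|b"], ["s1"], np.array([[2]]))
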