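import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hotseq.fasta_io import STANDARD_AMINO_ACIDS, ProteinChain
from hotseq.features import (
    DEFAULT_WINDOW_SIZES,
    FeatureConfig,
    N_FEATURES,
    extract_features,
    feature_names,
    one_hot,
    relative_position_quartile,
    window_average,
)
from hotseq.properties import PropertyLookupError

sequences = st.text(alphabet=list(STANDARD_AMINO_ACIDS), min_size=1, max_size=120)


class TestConfig:
    def test_default_feature_count_identity(self, table):
        config = FeatureConfig()
        assert 20 + 1 + 19 + 19 * len(config.window_sizes) == N_FEATURES == 173
        assert len(feature_names(table, config)) == 173

    @pytest.mark.parametrize("bad", [(0, 5), (5, 2), (3, 3)])
    def test_window_sizes_must_strictly_increase(self, bad):
        with pytest.raises(ValueError):
            FeatureConfig(window_sizes=bad)

    def test_one_hot_order_must_be_permutation(self):
        with pytest.raises(ValueError):
            FeatureConfig(one_hot_order=tuple("ACDEFGHIKLMNPQRSTVWW"))


class TestOneHot:
    def test_first_code_lights_first_slot(self):
        config = FeatureConfig()
        vector = one_hot(config.one_hot_order[0], config)
        assert vector[0] == 1.0 and vector.sum() == 1.0

    @pytest.mark.parametrize("aa", STANDARD_AMINO_ACIDS)
    def test_every_encoding_sums_to_one(self, aa):
        assert one_hot(aa).sum() == 1.0

    def test_distinct_codes_differ_in_exactly_two_positions(self):
        assert int(np.sum(one_hot("A") != one_hot("W"))) == 2

    def test_unknown_code_raises(self):
        with pytest.raises(PropertyLookupError):
            one_hot("X")


class TestQuartile:
    def test_first_and_last_residue(self):
        assert relative_position_quartile(1, 100) == 1
        assert relative_position_quartile(100, 100) == 4

    def test_length_eight_enumeration(self):
        # ceil(4*i/8) for i=1..8
        assert [relative_position_quartile(i, 8) for i in range(1, 9)] == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_length_one_chain(self):
        assert relative_position_quartile(1, 1) == 4  # ceil(4*1/1) capped

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            relative_position_quartile(0, 10)
        with pytest.raises(ValueError):
            relative_position_quartile(11, 10)

    @given(st.integers(min_value=1, max_value=500), st.data())
    def test_quartile_always_in_range_and_monotone(self, length, data):
        position = data.draw(st.integers(min_value=1, max_value=length))
        q = relative_position_quartile(position, length)
        assert 1 <= q <= 4
        if position < length:
            assert q <= relative_position_quartile(position + 1, length)


class TestWindowAverage:
    def test_homopolymer_mean_is_the_residue_itself(self, table):
        for window in (1, 2, 50):
            result = window_average("GGGGG", 3, window, table)
            np.testing.assert_allclose(result, table.values_for("G"))

    def test_saturating_window_equals_whole_chain_mean(self, table):
        sequence = "ACDEFGHIKL"
        whole = np.mean([table.values_for(aa) for aa in sequence], axis=0)
        for position in (1, 5, 10):
            np.testing.assert_allclose(window_average(sequence, position, 99, table), whole)

    def test_truncated_window_brute_force(self, table):
        # "ACD", position 1, half-width 2 covers {A, C, D}
        expected = (table.values_for("A") + table.values_for("C") + table.values_for("D")) / 3
        np.testing.assert_allclose(window_average("ACD", 1, 2, table), expected)

    def test_window_nesting_is_monotone_superset(self):
        length, position = 60, 17
        covered = []
        for w in DEFAULT_WINDOW_SIZES:
            lo, hi = max(1, position - w), min(length, position + w)
            covered.append(set(range(lo, hi + 1)))
        for smaller, larger in zip(covered, covered[1:]):
            assert smaller <= larger


class TestExtractFeatures:
    def test_vector_width_and_block_structure(self, table, example_chains):
        frame = extract_features(example_chains[0], table)
        feature_cols = [c for c in frame.columns if c not in ("chain_id", "position", "amino_acid")]
        assert len(feature_cols) == 173
        assert sum(c.startswith("onehot_") for c in feature_cols) == 20
        assert sum(c.startswith("win") for c in feature_cols) == 133
        assert np.isfinite(frame[feature_cols].to_numpy()).all()
        onehot = frame[[c for c in feature_cols if c.startswith("onehot_")]].to_numpy()
        np.testing.assert_allclose(onehot.sum(axis=1), 1.0)
        assert frame["position_quartile"].isin([1, 2, 3, 4]).all()

    def test_positions_one_based_contiguous(self, table, tiny_chain):
        frame = extract_features(tiny_chain, table)
        assert list(frame["position"]) == list(range(1, tiny_chain.length + 1))

    def test_matches_scalar_operations(self, table):
        chain = ProteinChain(chain_id="c", sequence="ACDEFGHIKLMNPQRSTVWY")
        frame = extract_features(chain, table)
        for position in (1, 7, 20):
            row = frame.iloc[position - 1]
            aa = chain.sequence[position - 1]
            np.testing.assert_allclose(
                row[[f"onehot_{x}" for x in FeatureConfig().one_hot_order]].to_numpy(dtype=float),
                one_hot(aa),
            )
            assert row["position_quartile"] == relative_position_quartile(position, 20)
            np.testing.assert_allclose(
                row[[f"win5_{p}" for p in table.property_names]].to_numpy(dtype=float),
                window_average(chain.sequence, position, 5, table),
            )
            np.testing.assert_allclose(
                row[table.property_names].to_numpy(dtype=float), table.values_for(aa)
            )

    def test_homopolymer_rows_differ_only_in_quartile(self, table):
        chain = ProteinChain(chain_id="c", sequence="W" * 40)
        frame = extract_features(chain, table)
        feature_cols = [c for c in frame.columns if c not in ("chain_id", "position", "amino_acid", "position_quartile")]
        block = frame[feature_cols].to_numpy()
        # prefix-sum window means introduce float noise at the last ulp
        np.testing.assert_allclose(block, np.tile(block[0], (len(block), 1)), rtol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(sequences)
    def test_reversal_equivariance(self, table, sequence):
        """Reversing the chain maps residue i to residue L-i+1: windows are
        symmetric so every non-positional feature is preserved. The quartile
        mirrors 1<->4, 2<->3 exactly when L is a multiple of 4 (the ceiling
        rule assigns remainders to earlier quartiles, breaking the mirror for
        other lengths)."""
        forward = extract_features(ProteinChain(chain_id="f", sequence=sequence), table)
        backward = extract_features(ProteinChain(chain_id="b", sequence=sequence[::-1]), table)
        cols = [c for c in forward.columns if c not in ("chain_id", "position", "amino_acid", "position_quartile")]
        np.testing.assert_allclose(
            forward[cols].to_numpy(), backward[cols].to_numpy()[::-1], atol=1e-12
        )
        if len(sequence) % 4 == 0:
            np.testing.assert_array_equal(
                5 - forward["position_quartile"].to_numpy(),
                backward["position_quartile"].to_numpy()[::-1],
            )
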