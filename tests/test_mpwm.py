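"""Model core: format round trips, weight conversion, window scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morpheus import (
    MPWM,
    MPWMError,
    MPWMParseError,
    MPWMValidationError,
    consensus_site,
    max_score,
    parse_mpwm,
    revcomp,
    revcomp_model,
    score_window,
    validate,
    weights_from_frequencies,
    write_mpwm,
)
from morpheus.fixtures import random_weight_model
from morpheus.mpwm import Calibration, DependencyGroup, nt_tuples

from conftest import all_sites, brute_force_score


class TestParse:
    def test_onehot_no_groups(self, onehot_model):
        m = onehot_model
        assert m.length == 3
        assert m.kind == "frequency"
        assert m.groups == []
        assert m.independent_positions == [1, 2, 3]
        assert np.allclose(m.matrix, [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1]])

    def test_dependency_block(self, onehot_frequency_doc):
        block = "dependency: 1,2\n" + "".join(
            f"{t}\t{1 if t == 'AC' else 0}\n" for t in nt_tuples(2)
        )
        m = parse_mpwm(onehot_frequency_doc + block)
        assert len(m.groups) == 1
        assert m.groups[0].positions == (1, 2)
        assert m.independent_positions == [3]
        assert m.groups[0].values["AC"] == 1

    def test_comments_and_blank_lines_ignored(self, onehot_frequency_doc):
        noisy = "# header comment\n\n" + onehot_frequency_doc.replace(
            "matrix:", "matrix:  # start of block\n"
        )
        assert parse_mpwm(noisy) == parse_mpwm(onehot_frequency_doc)

    def test_calibration_headers(self, onehot_frequency_doc):
        doc = onehot_frequency_doc.replace(
            "type:", "a: 2.0\nb: -1.5\nconcentration: 0.3\ntype:"
        )
        m = parse_mpwm(doc)
        assert m.calibration == Calibration(2.0, -1.5, 0.3)

    def test_duplicate_position_across_groups_rejected(self, onehot_frequency_doc):
        block = ""
        for positions in ("1,2", "2,3"):
            block += f"dependency: {positions}\n" + "".join(
                f"{t}\t0.0625\n" for t in nt_tuples(2)
            )
        with pytest.raises(MPWMValidationError, match="duplicate position"):
            parse_mpwm(onehot_frequency_doc + block)

    def test_group_position_out_of_range_rejected(self, onehot_frequency_doc):
        block = "dependency: 1,7\n" + "".join(f"{t}\t0.0625\n" for t in nt_tuples(2))
        with pytest.raises(MPWMValidationError, match="outside"):
            parse_mpwm(onehot_frequency_doc + block)

    def test_wrong_entry_count_rejected(self, onehot_frequency_doc):
        block = "dependency: 1,2\nAA\t1.0\nAC\t0.0\n"
        with pytest.raises(MPWMValidationError, match="expected 16"):
            parse_mpwm(onehot_frequency_doc + block)

    def test_malformed_number_names_line(self):
        doc = "name: x\ntype: weight\nmatrix:\n0 0 0 0\n0 oops 0 0\n"
        with pytest.raises(MPWMParseError, match="line 5"):
            parse_mpwm(doc)

    def test_frequency_sum_checked(self):
        doc = "type: frequency\nmatrix:\n0.5 0.2 0.1 0.1\n"
        with pytest.raises(MPWMValidationError, match="sum"):
            parse_mpwm(doc)


class TestRoundTrip:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        L=st.integers(2, 8),
        n_groups=st.integers(0, 2),
        d=st.sampled_from([2, 3]),
    )
    def test_parse_write_identity(self, seed, L, n_groups, d):
        if n_groups * d > L:
            n_groups = L // d
        m = random_weight_model(L, n_groups, d, seed=seed)
        assert parse_mpwm(write_mpwm(m)) == m

    def test_calibration_round_trips(self, onehot_model):
        onehot_model.calibration = Calibration(1.0, 0.0, None)
        doc = write_mpwm(onehot_model)
        assert "a: 1.0" in doc and "b: 0.0" in doc
        assert parse_mpwm(doc) == onehot_model

    def test_d3_block_has_64_entries(self):
        m = random_weight_model(5, 1, 3, seed=4)
        doc = write_mpwm(m)
        block = doc.split("dependency:")[1]
        assert len([ln for ln in block.splitlines() if "\t" in ln]) == 64


class TestWeights:
    def test_log_ratio_values(self):
        doc = "type: frequency\nmatrix:\n0.5 0.25 0.125 0.125\n"
        w = weights_from_frequencies(parse_mpwm(doc))
        assert np.allclose(
            w.matrix[0], [0.0, math.log(0.5), math.log(0.25), math.log(0.25)]
        )

    def test_uniform_frequencies_give_zero_weights(self):
        doc = "type: frequency\nmatrix:\n0.25 0.25 0.25 0.25\n"
        w = weights_from_frequencies(parse_mpwm(doc))
        assert np.allclose(w.matrix, 0.0)

    def test_uniform_group_gives_zero_weights(self):
        doc = "type: frequency\nmatrix:\n" + "0.25 0.25 0.25 0.25\n" * 2
        doc += "dependency: 1,2\n" + "".join(f"{t}\t0.0625\n" for t in nt_tuples(2))
        w = weights_from_frequencies(parse_mpwm(doc))
        assert all(v == 0.0 for v in w.groups[0].values.values())

    def test_zero_frequency_refused(self, onehot_model):
        with pytest.raises(MPWMError, match="pseudocount"):
            weights_from_frequencies(onehot_model)

    @pytest.mark.parametrize("seed", range(5))
    def test_block_maxima_are_zero(self, seed):
        m = random_weight_model(6, 2, 2, seed=seed)
        for p in m.independent_positions:
            assert m.matrix[p - 1].max() == pytest.approx(0.0, abs=1e-12)
        for g in m.groups:
            assert max(g.values.values()) == pytest.approx(0.0, abs=1e-12)


class TestScoring:
    def test_all_zero_matrix_scores_zero(self):
        m = MPWM("z", "weight", np.zeros((4, 4)))
        assert score_window(m, "ACGT") == 0.0

    def test_consensus_scores_max(self):
        m = random_weight_model(6, 1, 2, seed=11)
        assert score_window(m, consensus_site(m)) == pytest.approx(max_score(m))
        assert max_score(m) == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_oracle_with_group(self):
        m = random_weight_model(4, 1, 2, seed=7)
        for site in all_sites(4):
            assert score_window(m, site) == pytest.approx(
                brute_force_score(m, site), abs=1e-12
            )

    def test_max_score_matches_enumeration_d3(self):
        rng = np.random.default_rng(3)
        matrix = rng.normal(size=(5, 4))
        from conftest import random_group

        m = MPWM("r", "weight", matrix, [random_group(rng, (1, 3, 5))])
        assert max_score(m) == pytest.approx(
            max(score_window(m, s) for s in all_sites(5)), abs=1e-12
        )

    def test_length_mismatch_and_bad_character(self):
        m = random_weight_model(4, 0, seed=0)
        with pytest.raises(MPWMError, match="length"):
            score_window(m, "ACG")
        with pytest.raises(MPWMError, match="disallowed"):
            score_window(m, "ACNN")

    def test_reduction_to_plain_pwm(self):
        """A group holding product-of-marginals weights scores every site
        exactly like the group-free PWM from the same marginals."""
        rng = np.random.default_rng(5)
        freqs = rng.dirichlet(np.ones(4), size=4)
        plain_doc_rows = "\n".join(" ".join(map(str, row)) for row in freqs)
        plain = weights_from_frequencies(
            parse_mpwm(f"type: frequency\nmatrix:\n{plain_doc_rows}\n")
        )
        group_vals = {
            a + b: freqs[0][i] * freqs[2][j]
            for i, a in enumerate("ACGT")
            for j, b in enumerate("ACGT")
        }
        dep = weights_from_frequencies(
            MPWM(
                "dep",
                "frequency",
                freqs,
                [DependencyGroup((1, 3), group_vals)],
            )
        )
        for site in all_sites(4):
            assert score_window(dep, site) == pytest.approx(
                score_window(plain, site), abs=1e-9
            )


class TestRevcomp:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_involution(self, seed):
        m = random_weight_model(5, 1, 2, seed=seed)
        assert revcomp_model(revcomp_model(m)) == m

    def test_score_equivalence_exhaustive(self):
        m = random_weight_model(4, 1, 2, seed=13)
        rc = revcomp_model(m)
        for site in all_sites(4):
            assert score_window(rc, site) == pytest.approx(
                score_window(m, revcomp(site)), abs=1e-12
            )

    def test_palindromic_model_is_fixed_point(self):
        doc = (
            "type: frequency\nmatrix:\n"
            "0.4 0.1 0.2 0.3\n"
            "0.3 0.2 0.1 0.4\n"
        )
        m = parse_mpwm(doc)
        assert revcomp_model(m) == m
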