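"""Bits-matrix validation and Kozak Similarity Score behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kozascan import (
    BitsMatrix,
    CodonContext,
    default_kozak_matrix,
    kss_max,
    kss_score,
    load_bits_matrix,
    write_bits_matrix,
)
from kozascan.kozak_model import (
    MissingMatrixEntryError,
    NegativeHeightError,
    NonNumericHeightError,
    UninformativePositionError,
)


def _frame(heights: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(heights, columns=list("ACGT"))
    df.insert(0, "position", np.arange(1, 21))
    return df


def kss_oracle(context: CodonContext, matrix: BitsMatrix) -> float:
    """Independent brute-force accumulation: dict lookups, explicit loop."""
    table = {
        (p, n): float(matrix.heights[p - 1, j])
        for p in range(1, 21)
        for j, n in enumerate("ACGT")
    }
    denominator = sum(
        max(table[(p, n)] for n in "ACGT") for p in range(1, 21)
    )
    total = 0.0
    for i, base in enumerate(context.upstream_flank):
        total += table[(i + 1, base)]
    for i, base in enumerate(context.downstream_flank):
        total += table[(i + 11, base)]
    return total / denominator


class TestLoadAndValidate:
    def test_all_A_matrix_loads_with_max_20(self):
        heights = np.zeros((20, 4))
        heights[:, 0] = 1.0
        matrix = load_bits_matrix(_frame(heights))
        assert matrix.kss_max == 20.0

    def test_negative_entry_names_position_and_nucleotide(self):
        heights = np.ones((20, 4))
        heights[2, 2] = -0.5  # position 3, G
        with pytest.raises(NegativeHeightError, match="position 3.*G"):
            load_bits_matrix(_frame(heights))

    def test_all_zero_row_rejected(self):
        heights = np.ones((20, 4))
        heights[6, :] = 0.0  # position 7
        with pytest.raises(UninformativePositionError, match="position 7"):
            load_bits_matrix(_frame(heights))

    def test_missing_position_row_rejected(self):
        df = _frame(np.ones((20, 4)))
        with pytest.raises(MissingMatrixEntryError, match=r"\[5\]"):
            load_bits_matrix(df[df["position"] != 5])

    def test_missing_nucleotide_column_rejected(self):
        df = _frame(np.ones((20, 4))).drop(columns=["G"])
        with pytest.raises(MissingMatrixEntryError, match="G"):
            load_bits_matrix(df)

    def test_non_numeric_cell_rejected(self):
        df = _frame(np.ones((20, 4))).astype(object)
        df.loc[3, "C"] = "tall"
        with pytest.raises(NonNumericHeightError, match="position 4.*C"):
            load_bits_matrix(df)

    def test_tsv_round_trip(self, tmp_path, default_matrix):
        path = tmp_path / "matrix.tsv"
        write_bits_matrix(default_matrix, path)
        reloaded = load_bits_matrix(path)
        np.testing.assert_allclose(reloaded.heights, default_matrix.heights)


class TestDefaultMatrix:
    def test_satisfies_invariants(self, default_matrix):
        assert default_matrix.heights.shape == (20, 4)
        assert (default_matrix.heights >= 0).all()
        assert (default_matrix.heights.max(axis=1) > 0).all()
        assert default_matrix.kss_max > 0

    def test_kozak_consensus_structure(self, default_matrix):
        # -3 (flank position 8): purine preference, A or G tallest
        tallest_m3 = "ACGT"[int(np.argmax(default_matrix.heights[7]))]
        assert tallest_m3 in "AG"
        # -1 (flank position 10) and -2 prefer C; +4 (position 11) prefers G
        assert "ACGT"[int(np.argmax(default_matrix.heights[9]))] == "C"
        assert "ACGT"[int(np.argmax(default_matrix.heights[10]))] == "G"

    def test_source_label_records_provenance(self, default_matrix):
        assert "Kozak" in default_matrix.source_label


class TestKssScore:
    def test_boundary_scores(self, toy_matrix):
        assert kss_score(CodonContext("A" * 10, "ATG", "A" * 10), toy_matrix) == 1.0
        assert kss_score(CodonContext("C" * 10, "ATG", "C" * 10), toy_matrix) == 0.0
        assert kss_score(CodonContext("A" * 10, "ATG", "C" * 10), toy_matrix) == 0.5

    def test_kss_max_sums_per_position_maxima(self):
        heights = np.zeros((20, 4))
        heights[:10, 1] = 0.5
        heights[10:, 2] = 1.5
        matrix = BitsMatrix(heights=heights)
        assert kss_max(matrix) == pytest.approx(0.5 * 10 + 1.5 * 10)

    def test_ambiguity_strict_raises_lenient_scores_zero(self, toy_matrix):
        context = CodonContext("AAAAANAAAA", "ATG", "A" * 10)
        with pytest.raises(ValueError, match="position 6"):
            kss_score(context, toy_matrix)
        assert kss_score(context, toy_matrix, ambiguous="zero") == pytest.approx(0.95)

    def test_flank_length_enforced(self):
        with pytest.raises(ValueError):
            CodonContext("A" * 9, "ATG", "A" * 10)
        with pytest.raises(ValueError):
            CodonContext("A" * 10, "AT", "A" * 10)

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_oracle(self, random_matrix_factory, seed):
        rng = np.random.default_rng(seed)
        matrix = random_matrix_factory(rng)
        bases = np.array(list("ACGT"))
        context = CodonContext(
            "".join(bases[rng.integers(0, 4, 10)]),
            "".join(bases[rng.integers(0, 4, 3)]),
            "".join(bases[rng.integers(0, 4, 10)]),
        )
        expected = kss_oracle(context, matrix)
        assert kss_score(context, matrix) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 10_000))
    def test_score_in_unit_interval_and_codon_invariant(
        self, random_matrix_factory, seed
    ):
        rng = np.random.default_rng(seed)
        matrix = random_matrix_factory(rng)
        bases = np.array(list("ACGT"))
        up = "".join(bases[rng.integers(0, 4, 10)])
        down = "".join(bases[rng.integers(0, 4, 10)])
        scores = {
            kss_score(CodonContext(up, codon, down), matrix)
            for codon in ("ATG", "CTG", "AAA", "TTT")
        }
        assert len(scores) == 1  # codon identity contributes nothing
        assert 0.0 <= scores.pop() <= 1.0

    def test_score_one_iff_all_positions_maximal(self, default_matrix):
        consensus = "".join(
            "ACGT"[int(np.argmax(default_matrix.heights[p]))] for p in range(20)
        )
        top = kss_score(
            CodonContext(consensus[:10], "ATG", consensus[10:]), default_matrix
        )
        assert top == pytest.approx(1.0)
        # perturbing any single position away from its maximum lowers the score
        rng = np.random.default_rng(0)
        for p in rng.choice(20, size=5, replace=False):
            flanks = list(consensus)
            order = np.argsort(default_matrix.heights[p])
            flanks[p] = "ACGT"[int(order[0])]
            perturbed = kss_score(
                CodonContext("".join(flanks[:10]), "ATG", "".join(flanks[10:])),
                default_matrix,
            )
            assert perturbed < top

    @given(st.integers(0, 10_000))
    def test_monotone_in_single_position_height(self, random_matrix_factory, seed):
        rng = np.random.default_rng(seed)
        matrix = random_matrix_factory(rng)
        bases = "ACGT"
        up = "".join(bases[i] for i in rng.integers(0, 4, 10))
        down = "".join(bases[i] for i in rng.integers(0, 4, 10))
        p = int(rng.integers(0, 20))
        flanks = list(up + down)
        current = bases.index(flanks[p])
        taller = [
            j for j in range(4) if matrix.heights[p, j] > matrix.heights[p, current]
        ]
        if not taller:
            return
        base_score = kss_score(CodonContext(up, "ATG", down), matrix)
        flanks[p] = bases[taller[0]]
        bumped = kss_score(
            CodonContext("".join(flanks[:10]), "ATG", "".join(flanks[10:])), matrix
        )
        assert bumped > base_score
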