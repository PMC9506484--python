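"""Kozak-context bits matrix and the Kozak Similarity Score (KSS).

The KSS of a codon summarises how closely its flanking nucleotides match
the Kozak consensus context of an optimal eukaryotic start codon.  Twenty
flank positions enter the score: the ten nucleotides immediately 5' of the
codon (positions 1-10, read left to right) and the ten immediately 3'
(positions 11-20, read left to right).  Each position/nucleotide pair
carries a non-negative "height" in bits, in the style of a sequence logo
(observed frequency scaled by the position's information content).  The
score is

    KSS = (1 / KSS_bits_max) * sum_p height(p, nucleotide_p)

where ``KSS_bits_max`` is the largest attainable 20-term sum, i.e. the sum
of the per-position maxima.  KSS therefore lies in [0, 1]; 1 means every
flank position carries the tallest letter of the logo.  The codon's own
three nucleotides never contribute.

The packaged default matrix is built by the standard logo convention from
published Kozak-context nucleotide frequencies; any 20x4 table of
non-negative heights can be substituted via :func:`load_bits_matrix`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

NUCLEOTIDES = "ACGT"
FLANK_LENGTH = 10
N_POSITIONS = 2 * FLANK_LENGTH


class MatrixValidationError(ValueError):
    """Base class for bits-matrix validation failures."""


class MissingMatrixEntryError(MatrixValidationError):
    """A position or nucleotide column required by the 20x4 layout is absent."""


class NonNumericHeightError(MatrixValidationError):
    """A matrix cell could not be interpreted as a number."""


class NegativeHeightError(MatrixValidationError):
    """A matrix cell holds a negative height."""


class UninformativePositionError(MatrixValidationError):
    """All four heights at one position are zero, so it cannot contribute."""


@dataclass(frozen=True)
class BitsMatrix:
    """Per-position, per-nucleotide logo heights (bits) for KSS scoring.

    ``heights`` is a (20, 4) array; row ``p`` holds flank position ``p + 1``
    and columns follow :data:`NUCLEOTIDES` order (A, C, G, T).  Positions
    1-10 are the upstream flank, 11-20 the downstream flank, both read
    left to right in transcript order.
    """

    heights: np.ndarray
    source_label: str = "user-supplied"

    def __post_init__(self) -> None:
        arr = np.asarray(self.heights, dtype=float)
        if arr.shape != (N_POSITIONS, 4):
            raise MissingMatrixEntryError(
                f"bits matrix must be {N_POSITIONS}x4 (positions x ACGT), got {arr.shape}"
            )
        if np.isnan(arr).any():
            p, n = map(int, np.argwhere(np.isnan(arr))[0])
            raise NonNumericHeightError(
                f"non-numeric height at position {p + 1}, nucleotide {NUCLEOTIDES[n]}"
            )
        if (arr < 0).any():
            p, n = map(int, np.argwhere(arr < 0)[0])
            raise NegativeHeightError(
                f"negative height at position {p + 1}, nucleotide {NUCLEOTIDES[n]}"
            )
        zero_rows = np.flatnonzero(arr.max(axis=1) <= 0)
        if zero_rows.size:
            raise UninformativePositionError(
                f"all four heights are zero at position {int(zero_rows[0]) + 1}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "heights", arr)

    def height(self, position: int, nucleotide: str) -> float:
        """Height in bits at 1-based flank ``position`` for ``nucleotide``."""
        return float(self.heights[position - 1, NUCLEOTIDES.index(nucleotide)])

    @property
    def kss_max(self) -> float:
        return float(self.heights.max(axis=1).sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.heights, columns=list(NUCLEOTIDES))
        df.insert(0, "position", np.arange(1, N_POSITIONS + 1))
        return df


@dataclass(frozen=True)
class CodonContext:
    """A codon together with its ten-nucleotide flanks on each side.

    This is the unit the KSS scores.  Flanks must be exactly 10 nt, the
    codon exactly 3 nt, all in transcript (5'->3') order.
    """

    upstream_flank: str
    codon: str
    downstream_flank: str

    def __post_init__(self) -> None:
        if len(self.upstream_flank) != FLANK_LENGTH:
            raise ValueError(
                f"upstream flank must be {FLANK_LENGTH} nt, got {len(self.upstream_flank)}"
            )
        if len(self.downstream_flank) != FLANK_LENGTH:
            raise ValueError(
                f"downstream flank must be {FLANK_LENGTH} nt, got {len(self.downstream_flank)}"
            )
        if len(self.codon) != 3:
            raise ValueError(f"codon must be 3 nt, got {len(self.codon)}")

    @property
    def flanks(self) -> str:
        """The 20 scored nucleotides, upstream then downstream."""
        return self.upstream_flank + self.downstream_flank


def load_bits_matrix(
    source: Union[str, Path, io.TextIOBase, pd.DataFrame],
    source_label: str | None = None,
) -> BitsMatrix:
    """Read and validate a bits matrix from a TSV table (or DataFrame).

    The table needs a ``position`` column with values 1..20 and one column
    per nucleotide A, C, G, T holding non-negative heights in bits.
    Comment lines starting with ``#`` are ignored.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        label = source_label or "in-memory table"
    else:
        df = pd.read_csv(source, sep="\t", comment="#")
        label = source_label or str(source)
    df.columns = [str(c).strip() for c in df.columns]
    if "position" not in df.columns:
        raise MissingMatrixEntryError("matrix table lacks a 'position' column")
    for nuc in NUCLEOTIDES:
        if nuc not in df.columns:
            raise MissingMatrixEntryError(f"matrix table lacks a column for nucleotide {nuc}")

    heights = np.full((N_POSITIONS, 4), np.nan)
    seen: set[int] = set()
    for _, row in df.iterrows():
        try:
            pos = int(row["position"])
        except (TypeError, ValueError) as exc:
            raise NonNumericHeightError(f"non-integer position label {row['position']!r}") from exc
        if not 1 <= pos <= N_POSITIONS:
            raise MissingMatrixEntryError(f"position {pos} outside 1..{N_POSITIONS}")
        if pos in seen:
            raise MissingMatrixEntryError(f"duplicate row for position {pos}")
        seen.add(pos)
        for j, nuc in enumerate(NUCLEOTIDES):
            try:
                value = float(row[nuc])
            except (TypeError, ValueError) as exc:
                raise NonNumericHeightError(
                    f"non-numeric height at position {pos}, nucleotide {nuc}: {row[nuc]!r}"
                ) from exc
            if value < 0:
                raise NegativeHeightError(
                    f"negative height at position {pos}, nucleotide {nuc}: {value}"
                )
            heights[pos - 1, j] = value
    missing = sorted(set(range(1, N_POSITIONS + 1)) - seen)
    if missing:
        raise MissingMatrixEntryError(f"missing rows for positions {missing}")
    return BitsMatrix(heights=heights, source_label=label)


def write_bits_matrix(matrix: BitsMatrix, path: Union[str, Path]) -> None:
    """Write a matrix as the TSV layout :func:`load_bits_matrix` reads."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(
            "# kozascan bits matrix; positions 1-10 = upstream flank (5'->3'), "
            "11-20 = downstream flank (5'->3')\n"
            f"# source: {matrix.source_label}\n"
        )
        matrix.to_frame().to_csv(handle, sep="\t", index=False)


# Kozak-context nucleotide frequencies (A, C, G, T) for the 20 flank
# positions.  Positions 1-10 correspond to Kozak coordinates -10..-1,
# positions 11-20 to +4..+13 (the codon occupies +1..+3).  Values for
# -9..+6 are adapted from the classic vertebrate Kozak-context
# compilation (GCCGCCACC..ATG..G consensus); distal positions carry the
# mild GC skew of vertebrate mRNA with no strong preference.
_DEFAULT_FLANK_FREQS: Mapping[int, tuple[float, float, float, float]] = {
    1: (0.22, 0.30, 0.28, 0.20),   # -10
    2: (0.20, 0.26, 0.36, 0.18),   # -9  G
    3: (0.21, 0.36, 0.25, 0.18),   # -8  C
    4: (0.21, 0.36, 0.25, 0.18),   # -7  C
    5: (0.19, 0.25, 0.40, 0.16),   # -6  G
    6: (0.21, 0.39, 0.22, 0.18),   # -5  C
    7: (0.18, 0.44, 0.22, 0.16),   # -4  C
    8: (0.46, 0.10, 0.34, 0.10),   # -3  A/G purine
    9: (0.24, 0.42, 0.17, 0.17),   # -2  C
    10: (0.20, 0.43, 0.22, 0.15),  # -1  C
    11: (0.20, 0.18, 0.47, 0.15),  # +4  G
    12: (0.23, 0.37, 0.22, 0.18),  # +5  C
    13: (0.23, 0.32, 0.26, 0.19),  # +6
    14: (0.23, 0.28, 0.28, 0.21),
    15: (0.23, 0.28, 0.28, 0.21),
    16: (0.23, 0.28, 0.28, 0.21),
    17: (0.23, 0.28, 0.28, 0.21),
    18: (0.23, 0.28, 0.28, 0.21),
    19: (0.23, 0.28, 0.28, 0.21),
    20: (0.23, 0.28, 0.28, 0.21),
}

_DEFAULT_SOURCE_LABEL = (
    "kozascan default: sequence-logo heights (frequency x information content) "
    "from published vertebrate Kozak-context nucleotide frequencies"
)


def default_kozak_matrix() -> BitsMatrix:
    """The packaged default Kozak bits matrix.

    Heights follow the sequence-logo convention: at each position,
    height(n) = freq(n) * IC, with IC = 2 + sum_n freq(n) log2 freq(n)
    bits.  The frequencies are a published Kozak-context compilation, so
    the matrix reflects the canonical GCC GCC ACC | ATG | G preference
    (purine at -3, G at +4).  Scores from this matrix are comparable
    across sequences but are not numerically identical to scores from any
    other group's matrix; supply your own table via
    :func:`load_bits_matrix` to reproduce external scores.
    """
    freqs = np.array([_DEFAULT_FLANK_FREQS[p] for p in range(1, N_POSITIONS + 1)])
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    heights = freqs * info[:, None]
    return BitsMatrix(heights=heights, source_label=_DEFAULT_SOURCE_LABEL)


def kss_max(matrix: BitsMatrix) -> float:
    """Maximum attainable 20-position bits sum (the KSS denominator)."""
    return matrix.kss_max


def kss_score(
    context: CodonContext, matrix: BitsMatrix, *, ambiguous: str = "error"
) -> float:
    """Kozak Similarity Score of a codon context, in [0, 1].

    Positions 1-10 read the upstream flank left to right, positions 11-20
    the downstream flank; the codon itself contributes nothing.

    ``ambiguous`` controls flank characters outside A/C/G/T: ``"error"``
    (default) raises ValueError, ``"zero"`` scores them as 0 bits.
    Silent zero-scoring can hide data problems, hence the strict default.
    """
    if ambiguous not in ("error", "zero"):
        raise ValueError(f"ambiguous must be 'error' or 'zero', got {ambiguous!r}")
    total = 0.0
    for p, base in enumerate(context.flanks, start=1):
        j = NUCLEOTIDES.find(base)
        if j < 0:
            if ambiguous == "error":
                raise ValueError(
                    f"flank position {p} holds {base!r}, outside the A/C/G/T alphabet"
                )
            continue
        total += matrix.heights[p - 1, j]
    return total / matrix.kss_max
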