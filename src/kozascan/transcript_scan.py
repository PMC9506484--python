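"""Annotated mRNA transcripts and candidate start-codon enumeration.

A :class:`TranscriptRecord` is an mRNA-sense sequence with the annotated
start of its main coding sequence (the canonical translation initiation
codon, TIC).  Candidate TICs are ATG plus the nine near-cognate codons
(Hamming distance 1 from ATG); enumeration walks every offset, so all
three reading frames are covered.

Coordinates are 0-based half-open internally; user-facing tables use
1-based inclusive positions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional

from .kozak_model import FLANK_LENGTH, CodonContext

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def near_cognate_set() -> frozenset[str]:
    """The nine codons at Hamming distance exactly 1 from ATG."""
    return frozenset(
        c
        for c in ("".join(t) for t in product("ACGT", repeat=3))
        if sum(a != b for a, b in zip(c, "ATG")) == 1
    )


def common_near_cognate_set() -> frozenset[str]:
    """The four near-cognate codons with the most stable ribosome pairing.

    CTG, GTG, ACG and TTG initiate far more often than the other five
    near-cognates; restricting a scan to them trades recall for precision.
    """
    return frozenset({"CTG", "GTG", "ACG", "TTG"})


DEFAULT_CANDIDATE_CODONS: frozenset[str] = near_cognate_set() | {"ATG"}


class ScanRegion(enum.Enum):
    """Which part of the transcript to enumerate candidates in."""

    FULL = "full"
    #: every codon starting strictly before the main TIC, any frame,
    #: including codons that overlap the main TIC boundary
    UPSTREAM_OF_MAIN_TIC = "upstream"
    #: codons lying entirely within the 5'UTR
    UTR5 = "utr5"


class TranscriptRegion(enum.Enum):
    UTR5 = "UTR5"
    CDS = "CDS"
    UTR3 = "UTR3"


@dataclass(frozen=True)
class TranscriptRecord:
    """An mRNA-sense transcript with its annotated main TIC.

    ``main_tic_start`` is the 0-based index of the first nucleotide of the
    annotated main initiation codon; the codon there is recorded as-is and
    not forced to be ATG (some genes initiate their annotated product at a
    near-cognate codon, and malformed annotations must stay representable).
    ``cds_end`` is the 0-based exclusive end of the CDS, if known.
    """

    id: str
    sequence: str
    main_tic_start: int
    cds_end: Optional[int] = None
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not 0 <= self.main_tic_start <= len(seq) - 3:
            raise ValueError(
                f"{self.id}: main_tic_start {self.main_tic_start} outside "
                f"[0, {len(seq) - 3}] for a {len(seq)} nt sequence"
            )
        if self.cds_end is not None:
            if self.cds_end <= self.main_tic_start:
                raise ValueError(f"{self.id}: cds_end must exceed main_tic_start")
            if self.cds_end > len(seq):
                raise ValueError(f"{self.id}: cds_end {self.cds_end} beyond sequence end")
            if (self.cds_end - self.main_tic_start) % 3:
                raise ValueError(f"{self.id}: CDS length not divisible by 3")

    @property
    def main_codon(self) -> str:
        return self.sequence[self.main_tic_start : self.main_tic_start + 3]

    @property
    def utr5(self) -> str:
        return self.sequence[: self.main_tic_start]


@dataclass
class CandidateTIC:
    """One enumerated candidate initiation codon.

    ``kss`` stays ``None`` until scored; candidates lacking a full
    10-nt flank on either side are flagged via ``has_full_flanks`` and
    left unscored by default.
    """

    transcript_id: str
    position: int
    codon: str
    region: TranscriptRegion
    is_atg: bool
    is_near_cognate: bool
    has_full_flanks: bool
    kss: Optional[float] = None


class InsufficientFlankError(ValueError):
    """A codon too close to a sequence end to have full 10-nt flanks."""


def extract_context(transcript: TranscriptRecord, position: int) -> CodonContext:
    """The 10 nt / codon / 10 nt window at a 0-based codon start."""
    seq = transcript.sequence
    if position < FLANK_LENGTH or position + 3 + FLANK_LENGTH > len(seq):
        raise InsufficientFlankError(
            f"{transcript.id}: codon at {position} lacks full {FLANK_LENGTH} nt flanks "
            f"(sequence length {len(seq)})"
        )
    return CodonContext(
        upstream_flank=seq[position - FLANK_LENGTH : position],
        codon=seq[position : position + 3],
        downstream_flank=seq[position + 3 : position + 3 + FLANK_LENGTH],
    )


def _classify_region(transcript: TranscriptRecord, position: int) -> TranscriptRegion:
    if position < transcript.main_tic_start:
        return TranscriptRegion.UTR5
    if transcript.cds_end is not None and position >= transcript.cds_end:
        return TranscriptRegion.UTR3
    return TranscriptRegion.CDS


def enumerate_candidates(
    transcript: TranscriptRecord,
    region: ScanRegion = ScanRegion.FULL,
    codon_filter: Iterable[str] = DEFAULT_CANDIDATE_CODONS,
) -> list[CandidateTIC]:
    """Every position (all three frames) whose 3-mer is in ``codon_filter``.

    ``UPSTREAM_OF_MAIN_TIC`` keeps codons starting strictly before the
    main TIC — a scanning ribosome reaches those first even when the codon
    overlaps the main TIC boundary.  ``UTR5`` keeps only codons entirely
    inside the 5'UTR.  The list is ordered by position.
    """
    wanted = frozenset(c.upper() for c in codon_filter)
    if not wanted:
        raise ValueError("codon_filter must not be empty")
    seq = transcript.sequence
    main = transcript.main_tic_start
    if region is ScanRegion.FULL:
        lo, hi = 0, len(seq) - 3
    elif region is ScanRegion.UPSTREAM_OF_MAIN_TIC:
        lo, hi = 0, main - 1
    else:
        lo, hi = 0, main - 3
    out: list[CandidateTIC] = []
    for pos in range(lo, hi + 1):
        codon = seq[pos : pos + 3]
        if codon not in wanted:
            continue
        out.append(
            CandidateTIC(
                transcript_id=transcript.id,
                position=pos,
                codon=codon,
                region=_classify_region(transcript, pos),
                is_atg=codon == "ATG",
                is_near_cognate=codon in near_cognate_set(),
                has_full_flanks=(
                    pos >= FLANK_LENGTH and pos + 3 + FLANK_LENGTH <= len(seq)
                ),
            )
        )
    return out


def score_candidates(candidates, transcript, matrix, *, ambiguous="error"):
    """Fill ``kss`` in place for every fully-flanked candidate; returns them."""
    from .kozak_model import kss_score

    for cand in candidates:
        if cand.has_full_flanks:
            context = extract_context(transcript, cand.position)
            cand.kss = kss_score(context, matrix, ambiguous=ambiguous)
    return candidates


def utr5_length(transcript: TranscriptRecord) -> int:
    """Number of nucleotides strictly before the main TIC."""
    return transcript.main_tic_start
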