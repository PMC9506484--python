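import numpy as np
import pytest
from hypothesis import settings

from kozascan import (
    BitsMatrix,
    PeptideEvidence,
    TranscriptRecord,
    default_kozak_matrix,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_matrix() -> BitsMatrix:
    return default_kozak_matrix()


@pytest.fixture(scope="session")
def toy_matrix() -> BitsMatrix:
    """height(A) = 1 at every position, all else 0, so kss_max = 20."""
    heights = np.zeros((20, 4))
    heights[:, 0] = 1.0
    return BitsMatrix(heights=heights, source_label="toy all-A")


@pytest.fixture(scope="session")
def random_matrix_factory():
    """Random valid matrices: non-negative heights with positive row maxima."""

    def make(rng: np.random.Generator) -> BitsMatrix:
        heights = rng.uniform(0.0, 2.0, size=(20, 4))
        # occasionally zero some cells, keeping each row's max positive
        mask = rng.random(size=(20, 4)) < 0.2
        heights[mask] = 0.0
        heights[np.arange(20), rng.integers(0, 4, size=20)] += 0.05
        return BitsMatrix(heights=heights, source_label="random")

    return make


@pytest.fixture(scope="session")
def random_transcript_factory():
    """Random transcripts with a valid annotated main ATG."""

    def make(rng: np.random.Generator, length: int) -> TranscriptRecord:
        bases = np.array(list("ACGT"))
        seq = list(bases[rng.integers(0, 4, size=length)])
        main = int(rng.integers(13, length - 15))
        seq[main : main + 3] = list("ATG")
        return TranscriptRecord(
            id=f"rand{length}", sequence="".join(seq), main_tic_start=main
        )

    return make


# ----------------------------------------------------------------------
# Hand-traced peptide-evidence fixture.  Layout (0-based):
#   0-9    CCCCCCCCCC                   filler
#   10     ATG TGG GTT TGG GTC          upstream ATG TIC; encodes MWVWV
#   25-27  CCC                          spacer
#   28     CTG                          near-cognate TIC (in frame with main)
#   31     GGT CAC CAT AAA CTT          encodes GHHKL
#   46     AAA                          NOT a candidate codon
#   49     GAT GAA TTT ATC AAG          encodes DEFIK
#   64-66  CCC                          spacer
#   67     ATG CGT AAT GAT TGT TAA      main CDS; encodes MRNDC, then stop
#   85-94  CCCCCCCCCC                   3'UTR filler
# (67-28) % 3 == 0 and (67-10) % 3 == 0 with no intervening in-frame stop,
# so both upstream TICs would extend the main protein N-terminally.
PEPTIDE_FIXTURE_SEQ = (
    "CCCCCCCCCC"
    "ATGTGGGTTTGGGTC"
    "CCC"
    "CTG"
    "GGTCACCATAAACTT"
    "AAA"
    "GATGAATTTATCAAG"
    "CCC"
    "ATGCGTAATGATTGTTAA"
    "CCCCCCCCCC"
)


@pytest.fixture(scope="session")
def peptide_transcript() -> TranscriptRecord:
    return TranscriptRecord(
        id="pepfix",
        sequence=PEPTIDE_FIXTURE_SEQ,
        main_tic_start=67,
        cds_end=85,
        gene="FIX1",
    )


@pytest.fixture(scope="session")
def peptide_evidence_six() -> list[PeptideEvidence]:
    """Six evidences exercising every filter branch (hand-traced).

    Expected with default flags: kept = ATG@10, CTG@28, ATG@67 (three
    unique TICs); excluded = DEFIK (AAA upstream) + WWWWW (unmapped).
    With drop_atg: kept = CTG@28 only.
    """
    return [
        PeptideEvidence("MRNDC", "pepfix", acetylated=False, source="ms"),   # main ATG
        PeptideEvidence("GHHKL", "pepfix", acetylated=True, source="ms"),    # CTG via cleavage
        PeptideEvidence("DEFIK", "pepfix", acetylated=True, source="ms"),    # AAA -> excluded
        PeptideEvidence("WWWWW", "pepfix", acetylated=False, source="ms"),   # unmapped
        PeptideEvidence("GHHKL", "pepfix", acetylated=True, source="ribo"),  # duplicate
        PeptideEvidence("MWVWV", "pepfix", acetylated=False, source="ms"),   # upstream ATG
    ]
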