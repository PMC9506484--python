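"""Inferring initiation codons from N-terminal peptide evidence.

Mass-spectrometry and ribosome-profiling studies report the N-terminal
peptide of a translated product.  Matching that peptide against the three
forward-frame translations of a transcript localises the product; the
initiation codon (TIC) is then inferred with one complication: the
initiator methionine is often excised co-translationally.  The rules:

* a peptide starting with M maps directly onto its TIC — the matched
  first codon is the TIC (and must be ATG, since only ATG encodes M in a
  plain frame translation);
* a peptide without a leading M whose N terminus is acetylated most
  likely lost its initiator Met, so the TIC is the codon immediately
  5' of the match, in frame — provided that codon is ATG or near-cognate.
  If it is not, more than the Met was probably cleaved and the inference
  is unreliable, so the evidence is excluded rather than searched further
  upstream.

Kept TICs are classified by their relation to the annotated main CDS:
in-frame upstream starts without an intervening stop extend the main
protein N-terminally; out-of-frame or stop-separated upstream starts
begin novel upstream products; starts after the main TIC begin novel
downstream products.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from Bio.Seq import Seq

from .transcript_scan import (
    STOP_CODONS,
    TranscriptRecord,
    near_cognate_set,
)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
MIN_PEPTIDE_LENGTH = 5  # shorter matches localise unreliably

_CANDIDATE_CODONS = near_cognate_set() | {"ATG"}

# exclusion reasons (stable strings for reports and tests)
REASON_UNMAPPED = "unmapped"
REASON_SHORT = "peptide below minimum length"
REASON_NO_TRANSCRIPT = "transcript not found"
REASON_M_NON_NEAR = "M-initial peptide at non-near-cognate codon"
REASON_BOTH_CONDITIONS = "both exclusion conditions met"
REASON_NO_UPSTREAM = "no upstream codon"
REASON_STRICT_NON_ACETYL = "non-M peptide without acetylation (strict mode)"
REASON_ATG_DROPPED = "ATG TIC (dropped by flag)"


class ProductClass(enum.Enum):
    N_EXTENSION = "N_EXTENSION"
    NOVEL_UPSTREAM = "NOVEL_UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    MAIN = "MAIN"


class Status(enum.Enum):
    KEPT = "KEPT"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class PeptideEvidence:
    """One observed N-terminal peptide attributed to a transcript."""

    peptide: str
    transcript_id: str
    acetylated: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        pep = self.peptide.upper()
        object.__setattr__(self, "peptide", pep)
        if not pep:
            raise ValueError("peptide must be non-empty")
        bad = set(pep) - AMINO_ACIDS
        if bad:
            raise ValueError(f"peptide contains non-amino-acid characters {sorted(bad)}")


@dataclass
class MappedTIC:
    """A TIC inferred from one peptide match (or a recorded exclusion)."""

    transcript_id: str
    position: int
    codon: str
    met_cleaved: bool
    status: Status
    product_class: Optional[ProductClass] = None
    exclusion_reason: str = ""


def translate_frames(sequence: str, *, lenient: bool = False) -> tuple[str, str, str]:
    """Translations of the three forward frames (offsets 0, 1, 2).

    Stop codons render as ``*``; trailing partial codons are dropped.
    Characters outside A/C/G/T raise unless ``lenient``, in which case the
    affected codons translate as ``X``.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        if not lenient:
            raise ValueError(f"sequence contains non-A/C/G/T characters {sorted(bad)}")
        seq = "".join(c if c in "ACGT" else "N" for c in seq)
    frames = []
    for offset in range(3):
        sub = seq[offset : offset + 3 * ((len(seq) - offset) // 3)]
        frames.append(str(Seq(sub).translate()))
    return tuple(frames)


def map_peptide(
    evidence: PeptideEvidence, transcript: TranscriptRecord, *, lenient: bool = False
) -> list[int]:
    """0-based nucleotide starts of every exact forward-frame match.

    An empty list means the peptide could not be placed on this
    transcript; callers normally discard such evidence.
    """
    positions: list[int] = []
    frames = translate_frames(transcript.sequence, lenient=lenient)
    for offset, protein in enumerate(frames):
        start = protein.find(evidence.peptide)
        while start != -1:
            positions.append(offset + 3 * start)
            start = protein.find(evidence.peptide, start + 1)
    return sorted(positions)


def infer_tic(
    match_position: int,
    evidence: PeptideEvidence,
    transcript: TranscriptRecord,
    *,
    strict_acetylation: bool = False,
) -> MappedTIC:
    """Apply the Met-cleavage rules to one peptide match.

    ``strict_acetylation`` restricts the cleaved-Met inference to
    acetylated peptides (acetylation is the direct evidence that the
    observed residue was the mature N terminus); by default the same
    upstream-codon logic is applied to non-acetylated M-less peptides too.
    """
    seq = transcript.sequence
    codon_here = seq[match_position : match_position + 3]
    if evidence.peptide[0] == "M":
        kept = codon_here in _CANDIDATE_CODONS
        return MappedTIC(
            transcript_id=transcript.id,
            position=match_position,
            codon=codon_here,
            met_cleaved=False,
            status=Status.KEPT if kept else Status.EXCLUDED,
            exclusion_reason="" if kept else REASON_M_NON_NEAR,
        )
    if strict_acetylation and not evidence.acetylated:
        return MappedTIC(
            transcript_id=transcript.id,
            position=match_position,
            codon=codon_here,
            met_cleaved=False,
            status=Status.EXCLUDED,
            exclusion_reason=REASON_STRICT_NON_ACETYL,
        )
    if match_position - 3 < 0:
        return MappedTIC(
            transcript_id=transcript.id,
            position=match_position,
            codon=codon_here,
            met_cleaved=False,
            status=Status.EXCLUDED,
            exclusion_reason=REASON_NO_UPSTREAM,
        )
    codon_up = seq[match_position - 3 : match_position]
    kept = codon_up in _CANDIDATE_CODONS
    return MappedTIC(
        transcript_id=transcript.id,
        position=match_position - 3,
        codon=codon_up,
        met_cleaved=True,
        status=Status.KEPT if kept else Status.EXCLUDED,
        exclusion_reason="" if kept else REASON_BOTH_CONDITIONS,
    )


def classify_product(tic: MappedTIC, transcript: TranscriptRecord) -> ProductClass:
    """Relate a kept TIC to the annotated main CDS start."""
    main = transcript.main_tic_start
    pos = tic.position
    if pos == main:
        return ProductClass.MAIN
    if pos > main:
        return ProductClass.DOWNSTREAM
    if (main - pos) % 3 == 0:
        # in frame with the CDS; a stop between would terminate the
        # extension before it reaches the main protein
        for q in range(pos + 3, main, 3):
            if transcript.sequence[q : q + 3] in STOP_CODONS:
                return ProductClass.NOVEL_UPSTREAM
        return ProductClass.N_EXTENSION
    return ProductClass.NOVEL_UPSTREAM


def apply_filters(
    evidence_list: Iterable[PeptideEvidence],
    transcripts: Mapping[str, TranscriptRecord],
    *,
    drop_atg: bool = False,
    strict_acetylation: bool = False,
    min_peptide_length: int = MIN_PEPTIDE_LENGTH,
) -> tuple[list[MappedTIC], list[MappedTIC]]:
    """Run the full evidence pipeline and partition into kept / excluded.

    Unmapped or rule-violating evidence lands in ``excluded`` with a
    reason; kept TICs are deduplicated on (transcript, position, codon) so
    counts refer to unique TICs.  ``drop_atg`` moves ATG-initiated TICs to
    ``excluded``, isolating the noncanonical ones.  Output order is
    independent of input order (sorted by transcript then position).
    """
    kept: dict[tuple[str, int, str], MappedTIC] = {}
    excluded: list[MappedTIC] = []

    def _excluded_stub(ev: PeptideEvidence, reason: str) -> MappedTIC:
        return MappedTIC(
            transcript_id=ev.transcript_id,
            position=-1,
            codon="",
            met_cleaved=False,
            status=Status.EXCLUDED,
            exclusion_reason=reason,
        )

    for ev in evidence_list:
        transcript = transcripts.get(ev.transcript_id)
        if transcript is None:
            excluded.append(_excluded_stub(ev, REASON_NO_TRANSCRIPT))
            continue
        if len(ev.peptide) < min_peptide_length:
            excluded.append(_excluded_stub(ev, REASON_SHORT))
            continue
        matches = map_peptide(ev, transcript)
        if not matches:
            excluded.append(_excluded_stub(ev, REASON_UNMAPPED))
            continue
        for pos in matches:
            tic = infer_tic(pos, ev, transcript, strict_acetylation=strict_acetylation)
            if tic.status is Status.EXCLUDED:
                excluded.append(tic)
                continue
            if drop_atg and tic.codon == "ATG":
                tic.status = Status.EXCLUDED
                tic.exclusion_reason = REASON_ATG_DROPPED
                excluded.append(tic)
                continue
            tic.product_class = classify_product(tic, transcript)
            kept.setdefault((tic.transcript_id, tic.position, tic.codon), tic)

    kept_list = sorted(kept.values(), key=lambda t: (t.transcript_id, t.position))
    excluded.sort(key=lambda t: (t.transcript_id, t.position, t.exclusion_reason))
    return kept_list, excluded
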