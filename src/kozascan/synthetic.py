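"""Synthetic transcript cohorts with planted initiation codons.

The generator emulates the data the rest of the package analyses,
without any download: mRNA-like transcripts with a 5'UTR of log-normal
length, a stop-free CDS opened by an ATG in strong Kozak context and
closed by a stop codon, a short 3'UTR, and optionally planted upstream
TICs whose flanking context is pushed toward the Kozak consensus by a
single continuous knob.

Context sampling is a per-position softmax over logo heights: nucleotide
``n`` at position ``p`` is drawn with probability proportional to
``exp(concentration * h(p, n) / max_n h(p, n))``.  Concentration 0 gives
uniform background; as it grows the per-position consensus letter
dominates, so the expected KSS rises continuously from ~0.55 (uniform)
toward 1.  Normalising by the per-position maximum makes the knob
comparable across matrices of different absolute bit scales.

Two 5'UTR-length regimes matter for cohort comparisons: a long-UTR
"cancer-like" regime (median 205 nt) and a short-UTR "non-cancer-like"
regime (median 112 nt), matching the medians reported for genes with and
without upstream noncanonical TIC involvement in cancer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .kozak_model import FLANK_LENGTH, BitsMatrix, default_kozak_matrix
from .peptide_map import PeptideEvidence
from .transcript_scan import STOP_CODONS, TranscriptRecord, near_cognate_set

_BASES = np.array(list("ACGT"))
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]
# a planted codon plus both flanks spans 23 nt; keeping codon starts at
# least this far apart guarantees planted contexts never overwrite each
# other or the main-TIC context
_CONTEXT_SPAN = 2 * FLANK_LENGTH + 3


class CohortSpecError(ValueError):
    """The requested cohort cannot be generated as specified."""


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of one synthetic cohort.

    ``utr_length_median`` / ``utr_length_spread`` parameterise a
    log-normal 5'UTR length (median in nt, spread = sd of log length);
    log-normal keeps lengths positive and right-skewed like real UTRs.
    ``planted_tic_codons`` are planted at uniform random 5'UTR positions,
    non-overlapping, each with a context sampled at
    ``context_concentration``; the main ATG context uses
    ``main_context_concentration``.
    """

    n_transcripts: int
    utr_length_median: float = 205.0
    utr_length_spread: float = 0.6
    cds_length_range: tuple[int, int] = (300, 1800)
    planted_tic_codons: tuple[str, ...] = ()
    context_concentration: float = 12.0
    main_context_concentration: float = 8.0
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    utr3_length_range: tuple[int, int] = (30, 120)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise CohortSpecError("n_transcripts must be >= 1")
        if self.utr_length_median <= 0:
            raise CohortSpecError("utr_length_median must be > 0")
        if abs(sum(self.background_composition) - 1.0) > 1e-9:
            raise CohortSpecError("background_composition must sum to 1")
        if self.context_concentration < 0 or self.main_context_concentration < 0:
            raise CohortSpecError("concentrations must be >= 0")
        for codon in self.planted_tic_codons:
            if len(codon) != 3 or set(codon) - set("ACGT"):
                raise CohortSpecError(f"invalid planted codon {codon!r}")


@dataclass(frozen=True)
class PlantedTIC:
    position: int
    codon: str


@dataclass(frozen=True)
class TranscriptTruth:
    transcript_id: str
    main_tic_start: int
    planted: tuple[PlantedTIC, ...]
    context_concentration: float


@dataclass(frozen=True)
class GroundTruth:
    records: tuple[TranscriptTruth, ...]

    def for_transcript(self, transcript_id: str) -> TranscriptTruth:
        for rec in self.records:
            if rec.transcript_id == transcript_id:
                return rec
        raise KeyError(transcript_id)


def sample_context(
    matrix: BitsMatrix, concentration: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Draw a (upstream, downstream) 10+10 nt flank pair.

    Per position, P(n) ∝ exp(concentration * h(n) / max h); concentration
    0 is uniform, large values converge on the consensus flanks.
    """
    h = matrix.heights
    scaled = h / h.max(axis=1, keepdims=True)
    logits = concentration * scaled
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    draws = [rng.choice(4, p=probs[p]) for p in range(2 * FLANK_LENGTH)]
    flanks = "".join(_BASES[d] for d in draws)
    return flanks[:FLANK_LENGTH], flanks[FLANK_LENGTH:]


def _background(rng: np.random.Generator, n: int, comp) -> np.ndarray:
    if n <= 0:
        return np.array([], dtype="<U1")
    return _BASES[rng.choice(4, size=n, p=np.asarray(comp, dtype=float))]


def _draw_utr_length(rng, spec: SyntheticCohortSpec, minimum: int, index: int) -> int:
    mu = np.log(spec.utr_length_median)
    for _ in range(1000):
        length = int(round(float(rng.lognormal(mu, spec.utr_length_spread))))
        if length >= minimum:
            return length
    raise CohortSpecError(
        f"transcript {index}: could not draw a 5'UTR >= {minimum} nt from "
        f"median {spec.utr_length_median}, spread {spec.utr_length_spread}"
    )


def _place_planted(rng, utr_len: int, k: int, index: int) -> list[int]:
    """k planted codon starts in [10, utr_len - 23], pairwise >= 23 apart."""
    lo, hi = FLANK_LENGTH, utr_len - _CONTEXT_SPAN
    if k == 0:
        return []
    if hi < lo or (hi - lo) < (k - 1) * _CONTEXT_SPAN:
        raise CohortSpecError(
            f"transcript {index}: 5'UTR of {utr_len} nt too short for {k} planted TICs"
        )
    for _ in range(200):
        positions = sorted(rng.integers(lo, hi + 1, size=k))
        if all(
            b - a >= _CONTEXT_SPAN for a, b in zip(positions, positions[1:])
        ):
            return [int(p) for p in positions]
    # dense fallback: evenly spaced feasible placement
    step = (hi - lo) // max(k - 1, 1) if k > 1 else 0
    return [lo + i * max(step, _CONTEXT_SPAN) for i in range(k)]


def generate_cohort(
    spec: SyntheticCohortSpec, matrix: Optional[BitsMatrix] = None
) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Generate a cohort and its ground truth, reproducibly from the seed."""
    if matrix is None:
        matrix = default_kozak_matrix()
    rng = np.random.default_rng(spec.seed)
    k = len(spec.planted_tic_codons)
    min_utr = FLANK_LENGTH if k == 0 else FLANK_LENGTH + _CONTEXT_SPAN * k

    transcripts: list[TranscriptRecord] = []
    truths: list[TranscriptTruth] = []
    for i in range(spec.n_transcripts):
        utr_len = _draw_utr_length(rng, spec, min_utr, i)
        cds_lo, cds_hi = spec.cds_length_range
        cds_len = 3 * int(rng.integers(cds_lo // 3, max(cds_hi // 3, cds_lo // 3 + 1)))
        # ATG + body long enough to hold the 10-nt downstream context + stop
        cds_len = max(cds_len, 45)
        utr3_len = int(rng.integers(spec.utr3_length_range[0], spec.utr3_length_range[1] + 1))

        utr = _background(rng, utr_len, spec.background_composition)
        n_body = cds_len // 3 - 2
        body = list(rng.choice(_NON_STOP_CODONS, size=n_body))
        stop = str(rng.choice(sorted(STOP_CODONS)))
        utr3 = _background(rng, utr3_len, spec.background_composition)

        # plant upstream TICs with their contexts
        planted: list[PlantedTIC] = []
        for pos, codon in zip(
            _place_planted(rng, utr_len, k, i), spec.planted_tic_codons
        ):
            up, down = sample_context(matrix, spec.context_concentration, rng)
            utr[pos - FLANK_LENGTH : pos] = list(up)
            utr[pos : pos + 3] = list(codon)
            utr[pos + 3 : pos + 3 + FLANK_LENGTH] = list(down)
            planted.append(PlantedTIC(position=pos, codon=codon))

        # main ATG context: upstream flank ends the 5'UTR; downstream
        # flank overwrites CDS nt +4..+13, rejection-sampled so the three
        # fully covered body codons stay stop-free
        for _ in range(200):
            main_up, main_down = sample_context(
                matrix, spec.main_context_concentration, rng
            )
            cov = [main_down[0:3], main_down[3:6], main_down[6:9]]
            if not any(c in STOP_CODONS for c in cov):
                break
        utr[utr_len - FLANK_LENGTH : utr_len] = list(main_up)
        body_seq = list("".join(body))
        body_seq[: FLANK_LENGTH] = list(main_down)
        # the codon straddling the flank boundary may have become a stop
        for q in range(0, len(body_seq) - 2, 3):
            if "".join(body_seq[q : q + 3]) in STOP_CODONS:
                body_seq[q + 2] = "C"

        sequence = "".join(utr) + "ATG" + "".join(body_seq) + stop + "".join(utr3)
        tid = f"synth{i:05d}"
        transcripts.append(
            TranscriptRecord(
                id=tid,
                sequence=sequence,
                main_tic_start=utr_len,
                cds_end=utr_len + cds_len,
            )
        )
        truths.append(
            TranscriptTruth(
                transcript_id=tid,
                main_tic_start=utr_len,
                planted=tuple(planted),
                context_concentration=spec.context_concentration,
            )
        )
    return transcripts, GroundTruth(records=tuple(truths))


def generate_peptide_evidence(
    truth: GroundTruth,
    transcripts: Sequence[TranscriptRecord],
    cleave_met_fraction: float = 1.0,
    rng: int | np.random.Generator = 0,
    *,
    peptide_length: int = 8,
    n_decoys: int = 0,
) -> list[PeptideEvidence]:
    """Peptide evidence implied by the planted TICs.

    Each planted TIC yields the N-terminal peptide of its product:
    initiator Met (regardless of the codon's identity) followed by the
    downstream in-frame translation up to ``peptide_length`` residues or
    the first stop.  With probability ``cleave_met_fraction`` the Met is
    excised and the evidence marked acetylated — the branch that forces
    the upstream-codon inference.  ``n_decoys`` injects acetylated
    Met-less peptides whose upstream codon is neither ATG nor
    near-cognate; these must be excluded by the filter rules.
    """
    from Bio.Seq import Seq

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    by_id = {t.id: t for t in transcripts}
    candidate_codons = near_cognate_set() | {"ATG"}
    evidence: list[PeptideEvidence] = []

    for rec in truth.records:
        transcript = by_id[rec.transcript_id]
        for planted in rec.planted:
            tail_nt = transcript.sequence[
                planted.position + 3 : planted.position + 3 + 3 * (peptide_length - 1)
            ]
            tail_nt = tail_nt[: 3 * (len(tail_nt) // 3)]
            tail = str(Seq(tail_nt).translate())
            if "*" in tail:
                tail = tail[: tail.index("*")]
            peptide = "M" + tail
            cleaved = bool(rng.random() < cleave_met_fraction)
            if cleaved:
                peptide = peptide[1:]
            if len(peptide) < 5:
                continue  # too close to a stop to yield usable evidence
            evidence.append(
                PeptideEvidence(
                    peptide=peptide,
                    transcript_id=rec.transcript_id,
                    acetylated=cleaved,
                    source="synthetic",
                )
            )

    made = 0
    attempts = 0
    while made < n_decoys and attempts < 200 * max(n_decoys, 1):
        attempts += 1
        transcript = by_id[
            truth.records[int(rng.integers(len(truth.records)))].transcript_id
        ]
        main = transcript.main_tic_start
        cds_end = transcript.cds_end or len(transcript.sequence)
        n_codons = (cds_end - main) // 3
        if n_codons < peptide_length + 3:
            continue
        j = int(rng.integers(2, n_codons - peptide_length - 1))
        pos = main + 3 * j
        upstream_codon = transcript.sequence[pos - 3 : pos]
        if upstream_codon in candidate_codons:
            continue
        pep_nt = transcript.sequence[pos : pos + 3 * peptide_length]
        pep = str(Seq(pep_nt).translate())
        if "*" in pep or pep[0] == "M" or len(pep) < 5:
            continue
        evidence.append(
            PeptideEvidence(
                peptide=pep,
                transcript_id=transcript.id,
                acetylated=True,
                source="synthetic-decoy",
            )
        )
        made += 1
    return evidence
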