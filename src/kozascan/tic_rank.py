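"""KSS-based ordinal ranking of candidate initiation codons.

A candidate's rank says how its Kozak Similarity Score compares with the
other candidates of the same pool: rank 1 is the highest-scoring codon in
the pool, so at most one candidate per transcript can be rank 1.  Two
pool kinds mirror how noncanonical and canonical TICs are assessed:

* ``upstream_all`` — every ATG and near-cognate codon starting before the
  annotated main TIC (the pool a noncanonical upstream TIC competes in);
* ``full_atg`` — every ATG in the whole transcript (the pool the
  annotated canonical ATG competes in).

Ranks are ordinal (a permutation of 1..pool size); exact KSS ties — which
occur when two codons share identical flanks — are broken in favour of
the 5'-most codon, the one a scanning ribosome reaches first.
Competition ("1-2-2-4") ranking is available via ``method``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .kozak_model import BitsMatrix
from .transcript_scan import (
    DEFAULT_CANDIDATE_CODONS,
    CandidateTIC,
    ScanRegion,
    TranscriptRecord,
    enumerate_candidates,
    score_candidates,
)


@dataclass(frozen=True)
class RankedCandidate:
    candidate: CandidateTIC
    rank: int
    pool_size: int
    pool_kind: str = "upstream_all"


def rank_candidates(
    candidates: Iterable[CandidateTIC],
    *,
    pool_kind: str = "upstream_all",
    method: str = "ordinal",
) -> list[RankedCandidate]:
    """Rank scored candidates by KSS descending, 5'-most first on ties.

    ``method="ordinal"`` (default) assigns the unique ranks 1..pool_size;
    ``method="competition"`` gives exact KSS ties a shared (minimum) rank.
    Candidates must already carry a ``kss``.
    """
    pool = list(candidates)
    for cand in pool:
        if cand.kss is None:
            raise ValueError(
                f"candidate at {cand.position} in {cand.transcript_id} is unscored"
            )
    pool.sort(key=lambda c: (-c.kss, c.position))
    n = len(pool)
    ranked: list[RankedCandidate] = []
    last_kss: Optional[float] = None
    last_rank = 0
    for i, cand in enumerate(pool, start=1):
        if method == "competition" and cand.kss == last_kss:
            rank = last_rank
        else:
            rank = i
        ranked.append(RankedCandidate(cand, rank, n, pool_kind))
        last_kss, last_rank = cand.kss, rank
    return ranked


def rank_upstream(
    transcript: TranscriptRecord,
    matrix: BitsMatrix,
    codon_filter: Iterable[str] = DEFAULT_CANDIDATE_CODONS,
    *,
    method: str = "ordinal",
) -> list[RankedCandidate]:
    """Rank every fully-flanked ATG/near-cognate codon upstream of the main TIC.

    Candidates without full 10-nt flanks are excluded from the pool (they
    cannot be scored); an empty pool gives an empty list.
    """
    candidates = [
        c
        for c in enumerate_candidates(
            transcript, ScanRegion.UPSTREAM_OF_MAIN_TIC, codon_filter
        )
        if c.has_full_flanks
    ]
    score_candidates(candidates, transcript, matrix)
    return rank_candidates(candidates, pool_kind="upstream_all", method=method)


class CanonicalRankError(ValueError):
    """rank_canonical preconditions violated."""


def rank_full_atg(
    transcript: TranscriptRecord, matrix: BitsMatrix, *, method: str = "ordinal"
) -> list[RankedCandidate]:
    """Rank every fully-flanked ATG of the whole transcript."""
    candidates = [
        c
        for c in enumerate_candidates(transcript, ScanRegion.FULL, {"ATG"})
        if c.has_full_flanks
    ]
    score_candidates(candidates, transcript, matrix)
    return rank_candidates(candidates, pool_kind="full_atg", method=method)


def rank_canonical(
    transcript: TranscriptRecord, matrix: BitsMatrix, *, method: str = "ordinal"
) -> RankedCandidate:
    """Rank of the annotated main ATG among all ATGs of its transcript."""
    if transcript.main_codon != "ATG":
        raise CanonicalRankError(
            f"{transcript.id}: main TIC codon is {transcript.main_codon}, not ATG; "
            "rank it with rank_upstream semantics instead"
        )
    ranked = rank_full_atg(transcript, matrix, method=method)
    try:
        return rank_of(transcript.main_tic_start, ranked, as_record=True)
    except KeyError as exc:
        raise CanonicalRankError(
            f"{transcript.id}: main ATG at {transcript.main_tic_start} lacks full "
            "flanks and cannot be ranked"
        ) from exc


def rank_of(position: int, ranked: list[RankedCandidate], *, as_record: bool = False):
    """Rank (or full record) of the pool member starting at ``position``."""
    for rc in ranked:
        if rc.candidate.position == position:
            return rc if as_record else rc.rank
    raise KeyError(f"no ranked candidate at position {position}")
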