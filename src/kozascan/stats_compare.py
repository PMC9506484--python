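"""Distributional comparisons: KSS groups, 5'UTR lengths, positions.

The comparisons are one-sided Mann–Whitney U tests of whether one group
is stochastically greater than the other.  For small pooled samples
(n1 + n2 <= 16) the p-value is exact, by enumerating all C(n1+n2, n1)
group labelings; otherwise the normal approximation is used with midrank
tie correction and a 0.5 continuity correction.  U is reported for the
first group, counting tied pairs as 1/2.

A random-codon baseline — a handful of uniformly drawn fully-flanked
codons per transcript — anchors the KSS scale: candidate start codons in
good Kozak context should score well above it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from scipy.stats import norm as _norm

from .kozak_model import BitsMatrix, kss_score
from .kozak_model import FLANK_LENGTH
from .transcript_scan import (
    DEFAULT_CANDIDATE_CODONS,
    TranscriptRecord,
    extract_context,
    utr5_length,
)

logger = logging.getLogger(__name__)

EXACT_LIMIT = 16  # pooled size at or below which the exact test runs


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a one-sided Mann–Whitney comparison of two groups."""

    group_names: tuple[str, str]
    n: tuple[int, int]
    medians: tuple[float, float]
    u_statistic: float
    p_value_one_sided: float
    alternative: str = "first group stochastically greater"
    outlier_removed: bool = False
    method: str = "normal-approximation"


@dataclass(frozen=True)
class PositionalSummary:
    """Where identified TICs sit within their transcripts (cohort level)."""

    distances_to_5prime: tuple[int, ...]
    upstream_candidate_counts: tuple[int, ...]
    first_atg_is_canonical_fraction: float
    median_transcript_length: float
    median_utr5_length: float
    median_upstream_candidates: float


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x vs y with tied pairs counted 1/2, via midranks."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)


def mann_whitney_one_sided(
    x: Sequence[float],
    y: Sequence[float],
    group_names: tuple[str, str] = ("x", "y"),
    *,
    exact_limit: int = EXACT_LIMIT,
) -> ComparisonResult:
    """Test H1: ``x`` stochastically greater than ``y``.

    Exact enumeration when n1 + n2 <= ``exact_limit`` (p = fraction of
    labelings with U at least as large as observed); otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)

    if n1 + n2 <= exact_limit:
        offset = n1 * (n1 + 1) / 2
        count = 0
        for idx in combinations(range(n1 + n2), n1):
            u_perm = ranks[list(idx)].sum() - offset
            if u_perm >= u_obs - 1e-9:
                count += 1
        p = count / comb(n1 + n2, n1)
        method = "exact-enumeration"
    else:
        mean = n1 * n2 / 2
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3) - tie_counts).sum())
        var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 0.5  # every observation tied: no evidence either way
        else:
            z = (u_obs - mean - 0.5) / np.sqrt(var)
            p = float(_norm.sf(z))
        method = "normal-approximation"

    return ComparisonResult(
        group_names=group_names,
        n=(n1, n2),
        medians=(float(np.median(x)), float(np.median(y))),
        u_statistic=u_obs,
        p_value_one_sided=p,
        method=method,
    )


def sample_baseline(
    transcripts: Iterable[TranscriptRecord],
    matrix: BitsMatrix,
    per_transcript: int = 4,
    seed: int | np.random.Generator = 0,
) -> list[float]:
    """KSS of ``per_transcript`` random fully-flanked codons per transcript.

    Positions are drawn uniformly without replacement from the codon
    starts with full 10-nt flanks; transcripts too short to host any are
    skipped with a warning.  Deterministic for a fixed seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    scores: list[float] = []
    for transcript in transcripts:
        hi = len(transcript.sequence) - 3 - FLANK_LENGTH  # last valid start
        if hi < FLANK_LENGTH:
            logger.warning(
                "transcript %s too short for any fully-flanked codon; skipped",
                transcript.id,
            )
            continue
        positions = np.arange(FLANK_LENGTH, hi + 1)
        k = min(per_transcript, len(positions))
        chosen = rng.choice(positions, size=k, replace=False)
        for pos in sorted(int(p) for p in chosen):
            scores.append(kss_score(extract_context(transcript, pos), matrix))
    return scores


def compare_kss_groups(
    noncanonical: Sequence[float],
    canonical: Sequence[float],
    remove_lowest_noncanonical: bool = False,
) -> ComparisonResult:
    """One-sided test that noncanonical TIC scores exceed canonical ones.

    ``remove_lowest_noncanonical`` drops the single smallest noncanonical
    value before testing — a deliberate, flagged outlier removal, never
    automatic — so both the with- and without-outlier p-values are
    obtainable.
    """
    nc = list(noncanonical)
    if remove_lowest_noncanonical:
        if len(nc) < 2:
            raise ValueError("cannot remove the outlier from a singleton group")
        nc.remove(min(nc))
    result = mann_whitney_one_sided(nc, canonical, ("noncanonical", "canonical"))
    return ComparisonResult(
        **{
            **result.__dict__,
            "outlier_removed": remove_lowest_noncanonical,
        }
    )


def compare_utr_lengths(
    group_a: Iterable[TranscriptRecord],
    group_b: Iterable[TranscriptRecord],
    group_names: tuple[str, str] = ("group_a", "group_b"),
) -> ComparisonResult:
    """One-sided test that group_a transcripts have longer 5'UTRs."""
    a = [utr5_length(t) for t in group_a]
    b = [utr5_length(t) for t in group_b]
    return mann_whitney_one_sided(a, b, group_names)


def summarize_positions(tics, transcripts) -> PositionalSummary:
    """Positional statistics of identified TICs across a cohort.

    For each TIC: its distance from the transcript 5' end and the number
    of ATG or near-cognate codons (any frame) starting strictly before
    it.  Cohort-wide: the fraction of transcripts whose 5'-most ATG is
    the annotated canonical TIC, and median transcript / 5'UTR lengths.

    ``transcripts`` maps transcript id -> TranscriptRecord.
    """
    distances: list[int] = []
    counts: list[int] = []
    for tic in tics:
        transcript = transcripts[tic.transcript_id]
        distances.append(tic.position)
        seq = transcript.sequence
        counts.append(
            sum(
                1
                for q in range(0, tic.position)
                if seq[q : q + 3] in DEFAULT_CANDIDATE_CODONS
            )
        )
    first_atg_canonical = []
    for transcript in transcripts.values():
        first = transcript.sequence.find("ATG")
        if first != -1:
            first_atg_canonical.append(first == transcript.main_tic_start)
    lengths = [len(t.sequence) for t in transcripts.values()]
    utrs = [utr5_length(t) for t in transcripts.values()]
    return PositionalSummary(
        distances_to_5prime=tuple(distances),
        upstream_candidate_counts=tuple(counts),
        first_atg_is_canonical_fraction=(
            float(np.mean(first_atg_canonical)) if first_atg_canonical else 0.0
        ),
        median_transcript_length=float(np.median(lengths)) if lengths else 0.0,
        median_utr5_length=float(np.median(utrs)) if utrs else 0.0,
        median_upstream_candidates=float(np.median(counts)) if counts else 0.0,
    )


def plot_comparison(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str],
    path,
    *,
    bins: int = 30,
    xlabel: str = "value",
) -> None:
    """Overlaid histogram of the two compared groups (density scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(x, bins=bins, alpha=0.6, density=True, label=labels[0])
    ax.hist(y, bins=bins, alpha=0.6, density=True, label=labels[1])
    ax.set_xlabel(xlabel)
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
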