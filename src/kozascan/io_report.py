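"""File I/O and the color-coded candidate-codon annotation report.

Transcripts come in either as FASTA plus a sidecar annotation TSV
(columns ``transcript_id``, ``main_tic_start_1based``, optionally
``cds_end_1based`` and ``gene``) or as GenBank flat files whose CDS
feature supplies the main TIC; both routes produce identical
:class:`~kozascan.transcript_scan.TranscriptRecord` objects.  All output
tables are UTF-8 TSV with a commented header recording tool version,
matrix provenance and parameters.

The annotation report renders a transcript with every fully-flanked
candidate codon highlighted, tagged with its 1-based position, KSS to
three decimals, and one of five color bins (blue, teal, green, orange,
red — low to high KSS).
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from . import __version__
from .kozak_model import BitsMatrix
from .peptide_map import MappedTIC, PeptideEvidence
from .stats_compare import ComparisonResult
from .tic_rank import RankedCandidate
from .transcript_scan import (
    DEFAULT_CANDIDATE_CODONS,
    CandidateTIC,
    ScanRegion,
    TranscriptRecord,
    enumerate_candidates,
    score_candidates,
)

PathLike = Union[str, Path]

DEFAULT_BIN_EDGES: tuple[float, float, float, float] = (0.50, 0.62, 0.72, 0.80)
COLOR_BINS: tuple[str, ...] = ("blue", "teal", "green", "orange", "red")


def _comment_header(**params) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# kozascan {__version__} {kv}\n"


# ---------------------------------------------------------------- transcripts


def read_transcripts(
    fasta: Optional[PathLike] = None,
    annotation: Optional[PathLike] = None,
    genbank: Optional[PathLike] = None,
) -> list[TranscriptRecord]:
    """Load transcripts from FASTA + annotation TSV, or from GenBank.

    Annotation coordinates are 1-based inclusive on disk and converted to
    the internal 0-based half-open convention here.
    """
    if genbank is not None:
        if fasta is not None or annotation is not None:
            raise ValueError("give either genbank OR fasta+annotation, not both")
        return _read_genbank(genbank)
    if fasta is None or annotation is None:
        raise ValueError("need both fasta and annotation paths")
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    table = pd.read_csv(annotation, sep="\t", comment="#")
    required = {"transcript_id", "main_tic_start_1based"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        tid = str(row["transcript_id"])
        if tid not in sequences:
            raise ValueError(f"annotation references id {tid!r} absent from FASTA")
        main = int(row["main_tic_start_1based"]) - 1
        cds_end = None
        if "cds_end_1based" in table.columns and pd.notna(row.get("cds_end_1based")):
            cds_end = int(row["cds_end_1based"])  # 1-based inclusive == 0-based exclusive
        gene = None
        if "gene" in table.columns and pd.notna(row.get("gene")):
            gene = str(row["gene"])
        records.append(
            TranscriptRecord(
                id=tid,
                sequence=sequences[tid],
                main_tic_start=main,
                cds_end=cds_end,
                gene=gene,
            )
        )
    return records


def _read_genbank(path: PathLike) -> list[TranscriptRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        cds = [f for f in rec.features if f.type == "CDS"]
        if not cds:
            raise ValueError(f"GenBank record {rec.id} has no CDS feature")
        if len(cds) > 1:
            raise ValueError(
                f"GenBank record {rec.id} has {len(cds)} CDS features; "
                "split the record or choose one"
            )
        feature = cds[0]
        gene = feature.qualifiers.get("gene", [None])[0]
        records.append(
            TranscriptRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                main_tic_start=int(feature.location.start),
                cds_end=int(feature.location.end),
                gene=gene,
            )
        )
    return records


def write_transcripts(
    records: Iterable[TranscriptRecord], fasta: PathLike, annotation: PathLike
) -> None:
    """Write the FASTA + annotation TSV pair that read_transcripts reads."""
    records = list(records)
    with open(fasta, "w", encoding="utf-8") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                handle.write(rec.sequence[i : i + 70] + "\n")
    rows = [
        {
            "transcript_id": rec.id,
            "main_tic_start_1based": rec.main_tic_start + 1,
            "cds_end_1based": rec.cds_end if rec.cds_end is not None else "",
            "gene": rec.gene or "",
        }
        for rec in records
    ]
    with open(annotation, "w", encoding="utf-8") as handle:
        handle.write(_comment_header(table="transcript-annotation"))
        pd.DataFrame(rows).to_csv(handle, sep="\t", index=False)


# --------------------------------------------------------------- TSV outputs


def write_candidates_tsv(
    candidates: Iterable[CandidateTIC], path: PathLike, *, matrix_label: str = ""
) -> None:
    rows = [
        {
            "transcript_id": c.transcript_id,
            "position_1based": c.position + 1,
            "codon": c.codon,
            "region": c.region.value,
            "is_atg": c.is_atg,
            "is_near_cognate": c.is_near_cognate,
            "has_full_flanks": c.has_full_flanks,
            "kss": f"{c.kss:.3f}" if c.kss is not None else "",
        }
        for c in candidates
    ]
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_comment_header(table="candidates", matrix=repr(matrix_label)))
        pd.DataFrame(
            rows,
            columns=[
                "transcript_id", "position_1based", "codon", "region",
                "is_atg", "is_near_cognate", "has_full_flanks", "kss",
            ],
        ).to_csv(handle, sep="\t", index=False)


def write_ranks_tsv(
    ranked: Iterable[RankedCandidate], path: PathLike, *, matrix_label: str = ""
) -> None:
    rows = [
        {
            "transcript_id": rc.candidate.transcript_id,
            "position_1based": rc.candidate.position + 1,
            "codon": rc.candidate.codon,
            "kss": f"{rc.candidate.kss:.3f}",
            "rank": rc.rank,
            "pool_size": rc.pool_size,
            "pool_kind": rc.pool_kind,
        }
        for rc in ranked
    ]
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_comment_header(table="ranks", matrix=repr(matrix_label)))
        pd.DataFrame(
            rows,
            columns=[
                "transcript_id", "position_1based", "codon", "kss",
                "rank", "pool_size", "pool_kind",
            ],
        ).to_csv(handle, sep="\t", index=False)


def write_mapped_tics_tsv(tics: Iterable[MappedTIC], path: PathLike) -> None:
    rows = [
        {
            "transcript_id": t.transcript_id,
            "position_1based": t.position + 1 if t.position >= 0 else "",
            "codon": t.codon,
            "product_class": t.product_class.value if t.product_class else "",
            "met_cleaved": t.met_cleaved,
            "status": t.status.value,
            "exclusion_reason": t.exclusion_reason,
        }
        for t in tics
    ]
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_comment_header(table="mapped-tics"))
        pd.DataFrame(
            rows,
            columns=[
                "transcript_id", "position_1based", "codon", "product_class",
                "met_cleaved", "status", "exclusion_reason",
            ],
        ).to_csv(handle, sep="\t", index=False)


def write_evidence_tsv(evidence: Iterable[PeptideEvidence], path: PathLike) -> None:
    rows = [
        {
            "peptide": ev.peptide,
            "transcript_id": ev.transcript_id,
            "acetylated": ev.acetylated,
            "source": ev.source,
        }
        for ev in evidence
    ]
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_comment_header(table="peptide-evidence"))
        pd.DataFrame(
            rows, columns=["peptide", "transcript_id", "acetylated", "source"]
        ).to_csv(handle, sep="\t", index=False)


def read_evidence_tsv(path: PathLike) -> list[PeptideEvidence]:
    table = pd.read_csv(path, sep="\t", comment="#")
    return [
        PeptideEvidence(
            peptide=str(row["peptide"]),
            transcript_id=str(row["transcript_id"]),
            acetylated=bool(row["acetylated"]),
            source=str(row.get("source", "")),
        )
        for _, row in table.iterrows()
    ]


def write_comparison(result: ComparisonResult, path: PathLike) -> None:
    """Comparison result as JSON (medians, U, one-sided p, flags)."""
    payload = {
        "group_names": list(result.group_names),
        "n": list(result.n),
        "medians": list(result.medians),
        "u_statistic": result.u_statistic,
        "p_value_one_sided": result.p_value_one_sided,
        "alternative": result.alternative,
        "outlier_removed": result.outlier_removed,
        "method": result.method,
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2)
        handle.write("\n")


def write_ground_truth_tsv(truth, path: PathLike) -> None:
    rows = []
    for rec in truth.records:
        for planted in rec.planted:
            rows.append(
                {
                    "transcript_id": rec.transcript_id,
                    "position_1based": planted.position + 1,
                    "codon": planted.codon,
                    "main_tic_start_1based": rec.main_tic_start + 1,
                    "context_concentration": rec.context_concentration,
                }
            )
        if not rec.planted:
            rows.append(
                {
                    "transcript_id": rec.transcript_id,
                    "position_1based": "",
                    "codon": "",
                    "main_tic_start_1based": rec.main_tic_start + 1,
                    "context_concentration": rec.context_concentration,
                }
            )
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_comment_header(table="ground-truth"))
        pd.DataFrame(
            rows,
            columns=[
                "transcript_id", "position_1based", "codon",
                "main_tic_start_1based", "context_concentration",
            ],
        ).to_csv(handle, sep="\t", index=False)


# ----------------------------------------------------------------- annotation


@dataclass(frozen=True)
class AnnotatedCodon:
    position: int  # 0-based start
    codon: str
    kss: float
    color: str


@dataclass(frozen=True)
class AnnotationReport:
    """A transcript with its candidate codons highlighted.

    ``segments`` alternate plain sequence strings and
    :class:`AnnotatedCodon` entries and concatenate back to the input
    sequence exactly; when two candidates overlap (their 3-mers share
    nucleotides) only the 5'-most is highlighted inline, but every scored
    candidate appears in ``codons``.
    """

    transcript_id: str
    sequence: str
    segments: tuple
    codons: tuple[AnnotatedCodon, ...]

    def render_text(self) -> str:
        parts = []
        for seg in self.segments:
            if isinstance(seg, AnnotatedCodon):
                parts.append(f"[{seg.codon}({seg.kss:.3f}|{seg.color})]")
            else:
                parts.append(seg)
        return "".join(parts)

    def render_html(self) -> str:
        css = {
            "blue": "#1f4e9c", "teal": "#0f8b8d", "green": "#2e8b22",
            "orange": "#e07b00", "red": "#c42a1c",
        }
        parts = [
            "<html><head><meta charset='utf-8'><style>"
            "body{font-family:monospace;word-wrap:break-word;}"
            "span.codon{font-weight:bold;}"
            "</style></head><body>",
            f"<h3>{self.transcript_id}</h3><p>",
        ]
        for seg in self.segments:
            if isinstance(seg, AnnotatedCodon):
                parts.append(
                    f"<span class='codon' style='color:{css[seg.color]}' "
                    f"title='pos {seg.position + 1}'>"
                    f"{seg.codon}({seg.kss:.3f})</span>"
                )
            else:
                parts.append(seg)
        parts.append("</p></body></html>")
        return "".join(parts)


def kss_color_bin(
    kss: float, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> str:
    """Color name for a KSS value; bins are right-closed and monotone in KSS."""
    return COLOR_BINS[bisect.bisect_left(list(bin_edges), kss)]


def annotate_transcript(
    transcript: TranscriptRecord,
    matrix: BitsMatrix,
    codon_filter: Iterable[str] = DEFAULT_CANDIDATE_CODONS,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    region: ScanRegion = ScanRegion.FULL,
) -> AnnotationReport:
    """Highlight every fully-flanked candidate codon with KSS and color."""
    edges = list(bin_edges)
    if len(edges) != 4 or sorted(edges) != edges:
        raise ValueError("bin_edges must be 4 ascending KSS thresholds")
    candidates = [
        c
        for c in enumerate_candidates(transcript, region, codon_filter)
        if c.has_full_flanks
    ]
    score_candidates(candidates, transcript, matrix)
    annotated = tuple(
        AnnotatedCodon(
            position=c.position,
            codon=c.codon,
            kss=c.kss,
            color=kss_color_bin(c.kss, edges),
        )
        for c in candidates
    )
    segments: list = []
    cursor = 0
    seq = transcript.sequence
    for ann in annotated:
        if ann.position < cursor:
            continue  # overlaps the previously highlighted codon
        if ann.position > cursor:
            segments.append(seq[cursor : ann.position])
        segments.append(ann)
        cursor = ann.position + 3
    if cursor < len(seq):
        segments.append(seq[cursor:])
    return AnnotationReport(
        transcript_id=transcript.id,
        sequence=seq,
        segments=tuple(segments),
        codons=annotated,
    )
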