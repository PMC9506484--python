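"""Peptide-evidence mapping, Met-cleavage rules, product classification."""

import numpy as np
import pytest

from kozascan import (
    PeptideEvidence,
    ProductClass,
    Status,
    TranscriptRecord,
    apply_filters,
    classify_product,
    infer_tic,
    map_peptide,
    translate_frames,
)
from kozascan.peptide_map import (
    REASON_ATG_DROPPED,
    REASON_BOTH_CONDITIONS,
    REASON_NO_UPSTREAM,
    REASON_UNMAPPED,
)

# Independent codon-table oracle: hand-written standard genetic code.
_CODON_TABLE = {}
for _i, _aa1 in enumerate(
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
):
    _b1 = "TCAG"[_i // 16]
    _b2 = "TCAG"[(_i // 4) % 4]
    _b3 = "TCAG"[_i % 4]
    _CODON_TABLE[_b1 + _b2 + _b3] = _aa1


def translate_oracle(seq: str, offset: int) -> str:
    out = []
    for i in range(offset, len(seq) - 2, 3):
        out.append(_CODON_TABLE[seq[i : i + 3]])
    return "".join(out)


class TestTranslateFrames:
    def test_known_frames(self):
        assert translate_frames("ATGGCC")[0] == "MA"
        assert translate_frames("TATGGCC")[1] == "MA"
        assert translate_frames("ATGTAAGCC")[0] == "M*A"

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_codon_table_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        frames = translate_frames(seq)
        for offset in range(3):
            assert frames[offset] == translate_oracle(seq, offset)

    def test_non_acgt_strict_raises_lenient_gives_x(self):
        with pytest.raises(ValueError, match="non-A/C/G/T"):
            translate_frames("ATGNCC")
        assert translate_frames("ATGNCCGCC", lenient=True)[0] == "MXA"


class TestMapPeptide:
    def test_engineered_single_match(self, peptide_transcript):
        ev = PeptideEvidence("MRNDC", "pepfix")
        assert map_peptide(ev, peptide_transcript) == [67]

    def test_absent_peptide_maps_nowhere(self, peptide_transcript):
        assert map_peptide(PeptideEvidence("WWWWW", "pepfix"), peptide_transcript) == []

    def test_two_loci_both_reported_ascending(self):
        unit = "ATGCGTAATGATTGT"  # encodes MRNDC
        seq = "CC" + unit + "CCCC" + unit + "CC"
        rec = TranscriptRecord(id="t", sequence=seq, main_tic_start=2)
        positions = map_peptide(PeptideEvidence("MRNDC", "t"), rec)
        assert positions == sorted(positions) and len(positions) == 2


class TestInferTic:
    def test_m_initial_kept_at_atg(self, peptide_transcript):
        tic = infer_tic(67, PeptideEvidence("MRNDC", "pepfix"), peptide_transcript)
        assert (tic.status, tic.codon, tic.met_cleaved) == (Status.KEPT, "ATG", False)

    def test_cleaved_met_kept_at_near_cognate(self, peptide_transcript):
        tic = infer_tic(
            31, PeptideEvidence("GHHKL", "pepfix", acetylated=True), peptide_transcript
        )
        assert (tic.status, tic.codon, tic.position, tic.met_cleaved) == (
            Status.KEPT, "CTG", 28, True
        )

    def test_cleaved_met_excluded_at_non_candidate(self, peptide_transcript):
        tic = infer_tic(
            49, PeptideEvidence("DEFIK", "pepfix", acetylated=True), peptide_transcript
        )
        assert tic.status is Status.EXCLUDED
        assert tic.exclusion_reason == REASON_BOTH_CONDITIONS

    def test_no_upstream_codon(self):
        rec = TranscriptRecord(id="t", sequence="GGTCACCATAAACTTCCC", main_tic_start=15)
        tic = infer_tic(0, PeptideEvidence("GHHKL", "t", acetylated=True), rec)
        assert tic.status is Status.EXCLUDED
        assert tic.exclusion_reason == REASON_NO_UPSTREAM

    def test_strict_mode_excludes_non_acetylated(self, peptide_transcript):
        ev = PeptideEvidence("GHHKL", "pepfix", acetylated=False)
        assert infer_tic(31, ev, peptide_transcript).status is Status.KEPT
        strict = infer_tic(31, ev, peptide_transcript, strict_acetylation=True)
        assert strict.status is Status.EXCLUDED


class TestClassifyProduct:
    def test_in_frame_upstream_is_extension(self, peptide_transcript):
        tic = infer_tic(
            31, PeptideEvidence("GHHKL", "pepfix", acetylated=True), peptide_transcript
        )
        assert classify_product(tic, peptide_transcript) is ProductClass.N_EXTENSION

    @staticmethod
    def _tic(transcript_id, position, codon):
        from kozascan import MappedTIC

        return MappedTIC(
            transcript_id=transcript_id,
            position=position,
            codon=codon,
            met_cleaved=False,
            status=Status.KEPT,
        )

    def test_frame_shifted_upstream_is_novel(self):
        seq = "C" * 12 + "GTG" + "C" * 10 + "ATG" + "C" * 15
        rec = TranscriptRecord(id="t", sequence=seq, main_tic_start=25)
        assert (25 - 12) % 3 != 0
        assert classify_product(self._tic("t", 12, "GTG"), rec) is (
            ProductClass.NOVEL_UPSTREAM
        )

    def test_in_frame_with_intervening_stop_is_novel(self):
        seq = "C" * 12 + "CTG" + "TAA" + "CCC" + "ATG" + "C" * 15
        rec = TranscriptRecord(id="t", sequence=seq, main_tic_start=21)
        assert classify_product(self._tic("t", 12, "CTG"), rec) is (
            ProductClass.NOVEL_UPSTREAM
        )

    def test_downstream_and_main(self, peptide_transcript):
        tic = infer_tic(67, PeptideEvidence("MRNDC", "pepfix"), peptide_transcript)
        assert classify_product(tic, peptide_transcript) is ProductClass.MAIN
        tic.position = 73
        assert classify_product(tic, peptide_transcript) is ProductClass.DOWNSTREAM


class TestApplyFilters:
    def test_hand_traced_partition(self, peptide_transcript, peptide_evidence_six):
        kept, excluded = apply_filters(
            peptide_evidence_six, {"pepfix": peptide_transcript}
        )
        assert [(t.position, t.codon) for t in kept] == [
            (10, "ATG"), (28, "CTG"), (67, "ATG")
        ]
        assert {t.product_class for t in kept} == {
            ProductClass.N_EXTENSION, ProductClass.MAIN
        }
        reasons = sorted(t.exclusion_reason for t in excluded)
        assert reasons == sorted([REASON_BOTH_CONDITIONS, REASON_UNMAPPED])

    def test_drop_atg_flag_isolates_noncanonical(
        self, peptide_transcript, peptide_evidence_six
    ):
        kept, excluded = apply_filters(
            peptide_evidence_six, {"pepfix": peptide_transcript}, drop_atg=True
        )
        assert [(t.position, t.codon) for t in kept] == [(28, "CTG")]
        assert sum(t.exclusion_reason == REASON_ATG_DROPPED for t in excluded) == 2

    def test_output_invariant_to_input_order(
        self, peptide_transcript, peptide_evidence_six
    ):
        forward = apply_filters(peptide_evidence_six, {"pepfix": peptide_transcript})
        backward = apply_filters(
            list(reversed(peptide_evidence_six)), {"pepfix": peptide_transcript}
        )
        assert [
            (t.position, t.codon, t.status) for t in forward[0]
        ] == [(t.position, t.codon, t.status) for t in backward[0]]
        assert [t.exclusion_reason for t in forward[1]] == [
            t.exclusion_reason for t in backward[1]
        ]

    def test_every_kept_codon_is_candidate(
        self, peptide_transcript, peptide_evidence_six
    ):
        from kozascan import near_cognate_set

        kept, _ = apply_filters(peptide_evidence_six, {"pepfix": peptide_transcript})
        candidates = near_cognate_set() | {"ATG"}
        assert all(t.codon in candidates for t in kept)
        assert all(t.product_class is not None for t in kept)
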