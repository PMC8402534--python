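import pytest
from Bio.Seq import Seq

from venus import (
    MissingPredictionError,
    ReferenceMismatchError,
    SomaticVariant,
    ValidationError,
    VariantClass,
    build_fsp,
    build_snv_25mer,
    enumerate_candidates,
    tailor_fsp,
)
from venus.peptides import (
    FrameShiftPeptide,
    ProteinContext,
    load_contexts,
    mutant_9mers,
    mutant_anchor_offsets,
)

from conftest import make_cds, make_context

PROTEIN_30 = "MKTAYIAKQRQISFVKSHFSRQLEERLGLI"  # 30 aa, V at position 15


def snv(protein_pos, aa_ref, aa_alt, vid="V1", tx="TX1"):
    return SomaticVariant(
        variant_id=vid,
        chrom="chr1",
        pos=1,
        ref_allele="N",
        alt_allele="N",
        variant_class=VariantClass.MISSENSE_SNV,
        gene_id="G1",
        transcript_id=tx,
        protein_pos=protein_pos,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        tumor_mf=0.5,
        normal_mf=0.0,
        tumor_alt_reads=10,
        normal_alt_reads=0,
    )


def fs(protein_pos, ref, alt, vid="V1", tx="TX1"):
    return SomaticVariant(
        variant_id=vid,
        chrom="chr1",
        pos=1,
        ref_allele=ref,
        alt_allele=alt,
        variant_class=VariantClass.FRAMESHIFT_INDEL,
        gene_id="G1",
        transcript_id=tx,
        protein_pos=protein_pos,
        aa_ref=None,
        aa_alt=None,
        tumor_mf=0.5,
        normal_mf=0.0,
        tumor_alt_reads=10,
        normal_alt_reads=0,
    )


class TestSnv25mer:
    def test_centered_25mer_covers_flanks(self):
        ctx = make_context(PROTEIN_30)
        assert PROTEIN_30[14] == "V"
        pep = build_snv_25mer(snv(15, "V", "T"), ctx)
        # wild-type positions 3..27 with the mutant at peptide position 13
        assert pep.sequence == PROTEIN_30[2:14] + "T" + PROTEIN_30[15:27]
        assert len(pep.sequence) == 25
        assert pep.mutated_positions == frozenset({13})

    def test_n_terminal_truncation(self):
        ctx = make_context(PROTEIN_30)
        pep = build_snv_25mer(snv(1, "M", "V"), ctx)
        assert pep.sequence == "V" + PROTEIN_30[1:13]
        assert len(pep.sequence) == 13
        assert pep.mutated_positions == frozenset({1})

    def test_partial_upstream_flank(self):
        protein = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIENMKTAYIAK"  # 40 aa
        ctx = make_context(protein)
        pep = build_snv_25mer(snv(5, protein[4], "W"), ctx)
        assert len(pep.sequence) == 17  # 4 upstream + 1 + 12 downstream
        assert pep.mutated_positions == frozenset({5})
        assert pep.sequence == protein[:4] + "W" + protein[5:17]

    def test_reference_mismatch_raises(self):
        ctx = make_context(PROTEIN_30)
        with pytest.raises(ReferenceMismatchError, match="V1"):
            build_snv_25mer(snv(15, "C", "T"), ctx)

    def test_short_protein_peptide_discarded(self):
        ctx = make_context("MKTAYIAKQR")  # mutation at the last residue, short tail
        pep = build_snv_25mer(snv(10, "R", "W"), ctx, flank=2, min_length=9)
        assert pep is None


class TestFsp:
    WT = "MKLVNPQRST"
    CDS = "ATGAAACTGGTGAATCCGCAGCGTAGCACCTAA"

    def ctx(self):
        return ProteinContext(transcript_id="TX1", protein_seq=self.WT, cds_seq=self.CDS)

    def test_hand_translated_deletion(self):
        # deleting one base of codon 5 shifts the frame; no stop is met, so
        # translation runs to the transcript end: novel = IRSVAP (hand-checked)
        fsp = build_fsp(fs(5, "AA", "A"), self.ctx())
        assert fsp.novel_seq == "IRSVAP"
        assert fsp.modified_seq == "MKLVIRSVAP"
        assert fsp.prefix_len == 4
        assert fsp.stop_found is False

    def test_immediate_stop_yields_none(self):
        # the shifted frame opens with TAA: zero novel residues, FSP dropped
        assert build_fsp(fs(5, "A", "TA"), self.ctx()) is None

    def test_short_modified_fsp_dropped(self):
        # one inserted base gives novel ISAA; 4 wt prefix + 4 novel = 8 < 9
        assert build_fsp(fs(5, "A", "AT"), self.ctx()) is None

    def test_translation_matches_biopython_oracle(self):
        """The novel sequence equals a direct re-translation of the edited CDS."""
        protein = "MKTAYIAKQRQISFVKSHFSRQLEERLGLI"
        ctx = make_context(protein)
        variant = fs(20, ctx.cds_seq[57:59], ctx.cds_seq[57])  # 1-nt deletion at codon 20
        fsp = build_fsp(variant, ctx)
        edited = ctx.cds_seq[:57] + ctx.cds_seq[57] + ctx.cds_seq[59:]
        oracle = str(Seq(edited[: len(edited) - len(edited) % 3]).translate()).split("*")[0]
        diff = next(i for i in range(len(oracle)) if i >= len(protein) or oracle[i] != protein[i])
        assert fsp.novel_seq == oracle[diff:]
        assert fsp.modified_seq.endswith(fsp.novel_seq)
        assert fsp.modified_seq[: fsp.prefix_len] == protein[diff - fsp.prefix_len : diff]

    def test_in_frame_indel_rejected(self):
        with pytest.raises(ValidationError):
            build_fsp(fs(5, "AATC", "A"), self.ctx())


def make_fsp(n_wt=12, n_novel=7):
    wt = "ACDEFGHIKLMN"[:n_wt]
    novel = "PQRSTVW"[:n_novel]
    return FrameShiftPeptide(
        fsp_id="V1|fsp", variant_id="V1", novel_seq=novel, modified_seq=wt + novel
    )


class TestTailoring:
    def test_mutant_anchor_enumeration(self):
        # 19-mer modified FSP (12 wt + 7 novel): 11 9-mers, 7 reach a novel residue
        fsp = make_fsp()
        assert len(fsp.modified_seq) == 19
        offsets = mutant_anchor_offsets(fsp)
        assert offsets == [4, 5, 6, 7, 8, 9, 10]  # 1-based 5..11

    def test_extension_truncates_at_fsp_boundaries(self):
        fsp = make_fsp()
        ic50 = {fsp.modified_seq[i : i + 9]: 2000.0 for i in mutant_anchor_offsets(fsp)}
        ic50[fsp.modified_seq[4:13]] = 100.0
        peptides = tailor_fsp(fsp, ic50, threshold_nm=1000.0)
        (pep,) = peptides
        assert pep.anchor_9mer == fsp.modified_seq[4:13]
        assert pep.sequence == fsp.modified_seq  # 8-residue extension hits both ends
        assert pep.mutated_positions == frozenset(range(13, 20))

    def test_fallback_keeps_single_best_anchor(self):
        fsp = make_fsp()
        offsets = mutant_anchor_offsets(fsp)
        ic50 = {
            fsp.modified_seq[i : i + 9]: 3000.0 + 100 * i for i in offsets
        }
        peptides = tailor_fsp(fsp, ic50, threshold_nm=1000.0)
        assert len(peptides) == 1
        assert peptides[0].anchor_9mer == fsp.modified_seq[4:13]  # lowest IC50 anchor

    def test_permissive_threshold_keeps_all_unique_extensions(self):
        fsp = make_fsp()
        offsets = mutant_anchor_offsets(fsp)
        ic50 = {fsp.modified_seq[i : i + 9]: 10.0 for i in offsets}
        peptides = tailor_fsp(fsp, ic50, threshold_nm=float("inf"))
        # anchors 4..8 all extend to the full 19-mer and deduplicate
        assert len(peptides) == len({fsp.modified_seq[max(0, i - 8) : i + 17] for i in offsets})
        assert len(peptides) <= len(offsets)
        for pep in peptides:
            assert 9 <= len(pep.sequence) <= 25
            assert pep.mutated_positions

    def test_missing_prediction_lists_9mers(self):
        fsp = make_fsp()
        with pytest.raises(MissingPredictionError, match="V1"):
            tailor_fsp(fsp, {}, threshold_nm=1000.0)


class TestEnumerateCandidates:
    def contexts_and_variants(self):
        p1 = "MKTAYIAKQRQISFVKSHFSRQLEERLGLI"
        p2 = "MHHLLWAESRVSNGGGGSAAYYCCDDEEFF"
        contexts = {
            "TX1": make_context(p1, "TX1"),
            "TX2": make_context(p2, "TX2"),
            "TX3": ProteinContext("TX3", TestFsp.WT, TestFsp.CDS),
        }
        variants = [
            snv(15, "V", "T", vid="V1", tx="TX1"),
            snv(7, "A", "G", vid="V2", tx="TX2"),
            fs(5, "AA", "A", vid="V3", tx="TX3"),
        ]
        return contexts, variants

    def epitope_map(self, contexts, variants):
        fsp = build_fsp(variants[2], contexts["TX3"])
        mod = fsp.modified_seq
        return {mod[i : i + 9]: 50.0 for i in mutant_anchor_offsets(fsp)}

    def test_counts_and_sources(self):
        contexts, variants = self.contexts_and_variants()
        peptides, dropped = enumerate_candidates(
            variants, contexts, self.epitope_map(contexts, variants)
        )
        assert dropped == []
        by_source = {}
        for pep in peptides:
            by_source.setdefault(pep.source, []).append(pep)
        assert len(by_source["snv_25mer"]) == 2
        assert len(by_source["fsp_25mer"]) >= 1
        assert all(p.fsp_parent_id == "V3|fsp" for p in by_source["fsp_25mer"])

    def test_reordered_input_gives_identical_output(self):
        contexts, variants = self.contexts_and_variants()
        epitopes = self.epitope_map(contexts, variants)
        forward, _ = enumerate_candidates(variants, contexts, epitopes)
        backward, _ = enumerate_candidates(list(reversed(variants)), contexts, epitopes)
        assert forward == backward

    def test_dropped_fsp_contributes_no_peptides(self):
        contexts, variants = self.contexts_and_variants()
        variants[2] = fs(5, "A", "TA", vid="V3", tx="TX3")  # immediate stop
        peptides, dropped = enumerate_candidates(variants, contexts, {})
        assert all(p.variant_id != "V3" for p in peptides)
        assert dropped == [{"variant_id": "V3", "reason": "fsp_not_retained"}]

    def test_every_peptide_carries_a_non_wt_residue(self):
        contexts, variants = self.contexts_and_variants()
        peptides, _ = enumerate_candidates(
            variants, contexts, self.epitope_map(contexts, variants)
        )
        for pep in peptides:
            assert pep.mutated_positions
            assert 9 <= len(pep.sequence) <= 25
            for _, window in mutant_9mers(pep):
                assert window in pep.sequence


def test_load_contexts_requires_paired_fastas(tmp_path):
    (tmp_path / "p.fasta").write_text(">TX1\nMKTAYIAKQR\n")
    (tmp_path / "c.fasta").write_text(f">TX1\n{make_cds('MKTAYIAKQR')}\n>TX2\nATGTAA\n")
    with pytest.raises(Exception, match="TX2"):
        load_contexts(tmp_path / "p.fasta", tmp_path / "c.fasta")
    (tmp_path / "c2.fasta").write_text(f">TX1\n{make_cds('MKTAYIAKQR')}\n")
    contexts = load_contexts(tmp_path / "p.fasta", tmp_path / "c2.fasta")
    assert contexts["TX1"].protein_seq == "MKTAYIAKQR"
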