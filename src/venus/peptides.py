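"""Candidate neo-peptide construction.

Two construct families are produced from filtered somatic variants:

* **SNV 25-mers** — the mutated amino acid flanked upstream and downstream by
  12 wild-type residues (truncated at the protein termini), so the mutant
  residue of an untruncated peptide sits at position 13 of 25.
* **Frameshift peptides (FSPs)** — the indel is applied to the coding
  sequence and translation proceeds in the new frame; the FSP runs from the
  first mutated amino acid to the residue before the first stop codon (or to
  the transcript end when no stop is met, which is flagged). A *modified FSP*
  prefixes up to 12 wild-type residues for epitope context. FSPs with at
  least one novel residue and a modified length of at least nine residues are
  retained.

Because a long FSP contains stretches unlikely to be presented by MHC
class-I, a *tailoring* step reduces the modified FSP to 9-mer-anchored
25-mers: every 9-mer containing a novel residue whose best predicted IC50 is
at or below a threshold (default 1000 nM) is extended by up to eight
residues on both sides; when no 9-mer qualifies, the single best-IC50 anchor
is kept so a retained FSP is never silently dropped.

Coordinates: protein and peptide positions are 1-based inclusive; CDS
offsets are 0-based half-open internally. Frameshift ``ref``/``alt`` alleles
are interpreted in CDS orientation anchored at the first base of the codon
at ``protein_pos``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    MissingPredictionError,
    ReferenceMismatchError,
    SchemaError,
    ValidationError,
)
from .variants import STANDARD_AA, SomaticVariant, VariantClass

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: TSV dialect for peptide output.
PEPTIDE_TSV_COLUMNS = (
    "peptide_id",
    "variant_id",
    "source",
    "sequence",
    "mutated_positions",
    "fsp_parent_id",
    "anchor_9mer",
)


@dataclass(frozen=True)
class ProteinContext:
    """Wild-type protein and coding sequence for one transcript.

    The CDS must translate (standard genetic code) to the protein followed by
    a single terminal stop codon; ambiguous nucleotides are rejected.
    """

    transcript_id: str
    protein_seq: str
    cds_seq: str

    def __post_init__(self) -> None:
        if len(self.cds_seq) % 3 != 0:
            raise ValidationError(
                f"context {self.transcript_id!r}: CDS length not divisible by 3"
            )
        if not set(self.cds_seq) <= NUCLEOTIDES:
            raise ValidationError(
                f"context {self.transcript_id!r}: CDS contains non-ACGT characters"
            )
        if not set(self.protein_seq) <= STANDARD_AA:
            raise ValidationError(
                f"context {self.transcript_id!r}: protein contains non-standard residues"
            )
        translated = str(Seq(self.cds_seq).translate())
        if translated != self.protein_seq + "*":
            raise ValidationError(
                f"context {self.transcript_id!r}: CDS does not translate to protein + stop"
            )


@dataclass(frozen=True)
class FrameShiftPeptide:
    """A retained frameshift peptide.

    ``novel_seq`` runs from the first mutated residue to the residue before
    the stop; ``modified_seq`` prefixes up to 12 wild-type residues.
    ``stop_found`` is False when translation ran to the transcript end.
    """

    fsp_id: str
    variant_id: str
    novel_seq: str
    modified_seq: str
    stop_found: bool = True

    def __post_init__(self) -> None:
        if len(self.novel_seq) < 1:
            raise ValidationError(f"FSP {self.fsp_id!r}: empty novel sequence")
        if not self.modified_seq.endswith(self.novel_seq):
            raise ValidationError(f"FSP {self.fsp_id!r}: modified_seq must end with novel_seq")
        if len(self.modified_seq) < 9:
            raise ValidationError(f"FSP {self.fsp_id!r}: modified_seq shorter than 9 residues")

    @property
    def prefix_len(self) -> int:
        """Number of wild-type residues ahead of the novel sequence."""
        return len(self.modified_seq) - len(self.novel_seq)


@dataclass(frozen=True)
class NeoPeptide:
    """One candidate peptide (SNV- or FSP-derived).

    ``mutated_positions`` are 1-based positions within ``sequence`` of
    residues that differ from (or are absent in) the wild-type protein.
    """

    peptide_id: str
    variant_id: str
    source: str  # "snv_25mer" | "fsp_25mer"
    sequence: str
    mutated_positions: frozenset
    fsp_parent_id: str | None = None
    anchor_9mer: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutated_positions", frozenset(self.mutated_positions))
        if not 9 <= len(self.sequence) <= 25:
            raise ValidationError(
                f"peptide {self.peptide_id!r}: length {len(self.sequence)} outside [9, 25]"
            )
        if not self.mutated_positions:
            raise ValidationError(f"peptide {self.peptide_id!r}: no mutated positions")
        if any(p < 1 or p > len(self.sequence) for p in self.mutated_positions):
            raise ValidationError(f"peptide {self.peptide_id!r}: mutated position out of range")


def build_snv_25mer(
    variant: SomaticVariant,
    ctx: ProteinContext,
    flank: int = 12,
    min_length: int = 9,
) -> NeoPeptide | None:
    """Centered 25-mer for a missense SNV; ``None`` (logged) when too short.

    The returned sequence is the mutant residue with up to ``flank``
    wild-type residues on each side, truncated at the protein termini.
    """
    if variant.variant_class is not VariantClass.MISSENSE_SNV:
        raise ValidationError(f"variant {variant.variant_id!r} is not a missense SNV")
    wt = ctx.protein_seq
    p = variant.protein_pos
    if p > len(wt):
        raise ReferenceMismatchError(
            f"variant {variant.variant_id!r}: protein_pos {p} beyond protein length {len(wt)}"
        )
    if wt[p - 1] != variant.aa_ref:
        raise ReferenceMismatchError(
            f"variant {variant.variant_id!r}: aa_ref {variant.aa_ref!r} does not match "
            f"protein residue {wt[p - 1]!r} at position {p} of {ctx.transcript_id}"
        )
    upstream = wt[max(0, p - 1 - flank) : p - 1]
    downstream = wt[p : p + flank]
    sequence = upstream + variant.aa_alt + downstream
    if len(sequence) < min_length:
        logger.info(
            "dropped SNV peptide for %s: length %d < %d",
            variant.variant_id,
            len(sequence),
            min_length,
        )
        return None
    return NeoPeptide(
        peptide_id=f"{variant.variant_id}|snv",
        variant_id=variant.variant_id,
        source="snv_25mer",
        sequence=sequence,
        mutated_positions=frozenset({len(upstream) + 1}),
    )


def build_fsp(
    variant: SomaticVariant,
    ctx: ProteinContext,
    prefix: int = 12,
    min_modified_length: int = 9,
) -> FrameShiftPeptide | None:
    """Apply a frameshift indel to the CDS and translate the new frame.

    Returns ``None`` (with a logged reason) when the new frame yields no
    novel residue or the modified FSP is shorter than nine residues.
    """
    if variant.variant_class is not VariantClass.FRAMESHIFT_INDEL:
        raise ValidationError(f"variant {variant.variant_id!r} is not a frameshift indel")
    shift = len(variant.alt_allele) - len(variant.ref_allele)
    if shift % 3 == 0:
        raise ValidationError(
            f"variant {variant.variant_id!r}: indel length difference {shift} is in-frame"
        )
    cds = ctx.cds_seq
    start = 3 * (variant.protein_pos - 1)
    end = start + len(variant.ref_allele)
    if end > len(cds):
        raise ReferenceMismatchError(
            f"variant {variant.variant_id!r}: indel extends beyond CDS of {ctx.transcript_id}"
        )
    if cds[start:end] != variant.ref_allele:
        raise ReferenceMismatchError(
            f"variant {variant.variant_id!r}: ref allele {variant.ref_allele!r} does not match "
            f"CDS[{start}:{end}]={cds[start:end]!r} of {ctx.transcript_id}"
        )
    if not set(variant.alt_allele) <= NUCLEOTIDES:
        raise ValidationError(f"variant {variant.variant_id!r}: alt allele has non-ACGT bases")

    mutated = cds[:start] + variant.alt_allele + cds[end:]
    mutated = mutated[: len(mutated) - len(mutated) % 3]
    translated = str(Seq(mutated).translate())
    stop_index = translated.find("*")
    stop_found = stop_index != -1
    full = translated[:stop_index] if stop_found else translated
    if not stop_found:
        logger.warning(
            "variant %s: no stop codon in the shifted frame of %s; translated to transcript end",
            variant.variant_id,
            ctx.transcript_id,
        )

    wt = ctx.protein_seq
    first_diff = next(
        (i for i in range(min(len(full), len(wt))) if full[i] != wt[i]),
        min(len(full), len(wt)),
    )
    novel = full[first_diff:]
    if not novel:
        logger.info("dropped FSP for %s: FSP length 0", variant.variant_id)
        return None
    modified = wt[max(0, first_diff - prefix) : first_diff] + novel
    if len(modified) < min_modified_length:
        logger.info(
            "dropped FSP for %s: modified length %d < %d",
            variant.variant_id,
            len(modified),
            min_modified_length,
        )
        return None
    return FrameShiftPeptide(
        fsp_id=f"{variant.variant_id}|fsp",
        variant_id=variant.variant_id,
        novel_seq=novel,
        modified_seq=modified,
        stop_found=stop_found,
    )


def mutant_anchor_offsets(fsp: FrameShiftPeptide, k: int = 9) -> list[int]:
    """0-based offsets of the k-mers of the modified FSP that reach a novel residue."""
    return [
        i for i in range(len(fsp.modified_seq) - k + 1) if i + k > fsp.prefix_len
    ]


def tailor_fsp(
    fsp: FrameShiftPeptide,
    epitope_ic50: Mapping[str, float],
    threshold_nm: float = 1000.0,
    extension: int = 8,
) -> list[NeoPeptide]:
    """Reduce a modified FSP to 9-mer-anchored peptides of at most 25 residues.

    ``epitope_ic50`` must provide the best IC50 (nM, over the patient's
    alleles) for every mutant-containing 9-mer of the modified FSP. Anchors
    with IC50 <= ``threshold_nm`` are kept; if none qualify the single
    lowest-IC50 anchor is kept. Each anchor is extended by up to
    ``extension`` residues on both sides (truncated at the FSP boundaries)
    and identical extended sequences are deduplicated.
    """
    mod = fsp.modified_seq
    offsets = mutant_anchor_offsets(fsp)
    missing = sorted({mod[i : i + 9] for i in offsets if mod[i : i + 9] not in epitope_ic50})
    if missing:
        raise MissingPredictionError(
            f"FSP {fsp.fsp_id!r}: no IC50 prediction for 9-mers {missing}"
        )
    kept = [i for i in offsets if epitope_ic50[mod[i : i + 9]] <= threshold_nm]
    if not kept:
        kept = [min(offsets, key=lambda i: (epitope_ic50[mod[i : i + 9]], i))]
        logger.info(
            "FSP %s: no anchor at or below %.0f nM; keeping best anchor only",
            fsp.fsp_id,
            threshold_nm,
        )

    peptides: list[NeoPeptide] = []
    seen: set[str] = set()
    for i in kept:
        ext_start = max(0, i - extension)
        ext_end = min(len(mod), i + 9 + extension)
        sequence = mod[ext_start:ext_end]
        if sequence in seen:
            continue
        seen.add(sequence)
        mutated_positions = frozenset(
            j for j in range(1, len(sequence) + 1) if ext_start + j - 1 >= fsp.prefix_len
        )
        peptides.append(
            NeoPeptide(
                peptide_id=f"{fsp.variant_id}|fsp@{i + 1}",
                variant_id=fsp.variant_id,
                source="fsp_25mer",
                sequence=sequence,
                mutated_positions=mutated_positions,
                fsp_parent_id=fsp.fsp_id,
                anchor_9mer=mod[i : i + 9],
            )
        )
    return peptides


def mutant_9mers(peptide: NeoPeptide, k: int = 9) -> list[tuple[int, str]]:
    """(0-based offset, sequence) of every k-mer window containing a mutated residue."""
    windows = []
    for i in range(len(peptide.sequence) - k + 1):
        if any(i + 1 <= p <= i + k for p in peptide.mutated_positions):
            windows.append((i, peptide.sequence[i : i + k]))
    return windows


def enumerate_candidates(
    variants: Sequence[SomaticVariant],
    contexts: Mapping[str, ProteinContext],
    epitope_ic50: Mapping[str, float],
    tailoring_threshold_nm: float = 1000.0,
) -> tuple[list[NeoPeptide], list[dict]]:
    """Construct the full candidate list for one patient.

    SNV 25-mers and tailored FSP 25-mers are concatenated; duplicates by
    (variant_id, sequence) are removed and the output is canonically sorted
    by (variant_id, peptide_id) so reordered inputs give identical output.

    Returns ``(peptides, dropped)`` where each drop record names the variant
    and a machine-readable reason.
    """
    peptides: list[NeoPeptide] = []
    dropped: list[dict] = []
    for variant in sorted(variants, key=lambda v: v.variant_id):
        if variant.transcript_id not in contexts:
            raise SchemaError(
                f"variant {variant.variant_id!r}: no protein context for transcript "
                f"{variant.transcript_id!r}"
            )
        ctx = contexts[variant.transcript_id]
        if variant.variant_class is VariantClass.MISSENSE_SNV:
            pep = build_snv_25mer(variant, ctx)
            if pep is None:
                dropped.append(
                    {"variant_id": variant.variant_id, "reason": "snv_peptide_too_short"}
                )
            else:
                peptides.append(pep)
        else:
            fsp = build_fsp(variant, ctx)
            if fsp is None:
                dropped.append({"variant_id": variant.variant_id, "reason": "fsp_not_retained"})
            else:
                peptides.extend(tailor_fsp(fsp, epitope_ic50, tailoring_threshold_nm))
    unique: dict[tuple[str, str], NeoPeptide] = {}
    for pep in peptides:
        unique.setdefault((pep.variant_id, pep.sequence), pep)
    result = sorted(unique.values(), key=lambda p: (p.variant_id, p.peptide_id))
    return result, dropped


# ---------------------------------------------------------------------------
# FASTA / TSV interfaces
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping."""
    return {record.id: str(record.seq).upper() for record in SeqIO.parse(str(path), "fasta")}


def load_contexts(protein_fasta, cds_fasta) -> dict[str, ProteinContext]:
    """Pair protein and CDS FASTA records by transcript id into contexts."""
    proteins = read_fasta(protein_fasta)
    cds = read_fasta(cds_fasta)
    missing = sorted(set(proteins) ^ set(cds))
    if missing:
        raise SchemaError(f"protein/CDS FASTA ids do not match; unpaired: {missing}")
    return {
        tx: ProteinContext(transcript_id=tx, protein_seq=proteins[tx], cds_seq=cds[tx])
        for tx in sorted(proteins)
    }


def peptides_to_frame(peptides: Iterable[NeoPeptide]) -> "pd.DataFrame":
    rows = [
        {
            "peptide_id": p.peptide_id,
            "variant_id": p.variant_id,
            "source": p.source,
            "sequence": p.sequence,
            "mutated_positions": ",".join(str(i) for i in sorted(p.mutated_positions)),
            "fsp_parent_id": p.fsp_parent_id or "",
            "anchor_9mer": p.anchor_9mer or "",
        }
        for p in peptides
    ]
    return pd.DataFrame(rows, columns=list(PEPTIDE_TSV_COLUMNS))


def write_peptides_tsv(peptides: Iterable[NeoPeptide], path) -> None:
    peptides_to_frame(peptides).to_csv(path, sep="\t", index=False)
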