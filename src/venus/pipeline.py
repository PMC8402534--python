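"""End-to-end orchestration: filter, build peptides, join evidence, score.

``rank_bundle`` runs the whole method on an in-memory patient bundle and is
the single code path behind the CLI ``rank`` subcommand, the strategy
comparisons and the synthetic-recovery evaluations. Every record that leaves
the pipeline is logged with a machine-readable reason, and the report keeps
the conservation identity

    variants_in = variants_filtered_out + variants_with_peptides
                  + variants_without_peptides

so no row is dropped silently.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .binding import build_peptide_predictions, epitope_best_ic50, summarize_binding
from .config import PipelineConfig
from .errors import ValidationError
from .expression import read_expression_tsv
from .peptides import enumerate_candidates, load_contexts
from .scoring import rank_alternative, score_patient
from .synthetic import PatientBundle
from .variants import apply_somatic_filters, read_variants_tsv

logger = logging.getLogger(__name__)

#: column order of the ranked output TSV.
RANKED_COLUMNS = (
    "final_position",
    "peptide_id",
    "variant_id",
    "sequence",
    "tumor_mf",
    "corr_tpm",
    "tpm",
    "rna_mut_reads",
    "rna_wt_reads",
    "best_ic50_nm",
    "best_allele",
    "r_freq",
    "r_expr",
    "r_ic50",
    "k",
    "wf",
    "rsum",
)


def candidate_table(bundle: PatientBundle, config: PipelineConfig | None = None):
    """Filter variants, construct peptides and join all per-peptide evidence.

    Returns ``(candidates, drop_log)`` where ``candidates`` is the joined
    table :func:`venus.scoring.score_patient` consumes (plus sequence and
    evidence columns for the output TSV).
    """
    config = config or PipelineConfig()
    decisions = apply_somatic_filters(bundle.variants, config.filters)
    drop_log = [
        {
            "stage": "filter",
            "variant_id": d.variant_id,
            "reason": "failed_somatic_filter",
            "detail": ",".join(c.value for c in d.failed_criteria),
        }
        for d in decisions
        if not d.passed
    ]
    passed = [v for v, d in zip(bundle.variants, decisions) if d.passed]

    epitope_map = epitope_best_ic50(bundle.predictions)
    peptides, build_drops = enumerate_candidates(
        passed, bundle.contexts, epitope_map, config.tailoring_threshold_nm
    )
    drop_log.extend({"stage": "build", **record} for record in build_drops)

    orphans = sorted(
        {p.variant_id for p in peptides if p.variant_id not in bundle.expression}
    )
    if orphans:
        raise ValidationError(f"no expression evidence for variants: {orphans}")

    summaries = summarize_binding(build_peptide_predictions(peptides, bundle.predictions))
    by_id = {v.variant_id: v for v in bundle.variants}
    rows = []
    for pep in peptides:
        variant = by_id[pep.variant_id]
        evidence = bundle.expression[pep.variant_id]
        summary = summaries[pep.peptide_id]
        rows.append(
            {
                "peptide_id": pep.peptide_id,
                "variant_id": pep.variant_id,
                "source": pep.source,
                "sequence": pep.sequence,
                "tumor_mf": variant.tumor_mf,
                "tpm": evidence.tpm,
                "rna_mut_reads": evidence.rna_mut_reads,
                "rna_wt_reads": evidence.rna_wt_reads,
                "corr_tpm": evidence.corr_tpm,
                "wf": evidence.wf,
                "best_ic50_nm": summary.best_ic50_nm,
                "best_allele": summary.best_allele,
            }
        )
    candidates = pd.DataFrame(rows)
    report = {
        "patient_id": bundle.patient_id,
        "variants_in": len(bundle.variants),
        "variants_filtered_out": sum(1 for d in decisions if not d.passed),
        "variants_with_peptides": int(candidates["variant_id"].nunique()) if len(rows) else 0,
        "variants_without_peptides": len(passed)
        - (int(candidates["variant_id"].nunique()) if len(rows) else 0),
        "n_candidates": len(rows),
        "drops": drop_log,
    }
    return candidates, report


def rank_bundle(bundle: PatientBundle, config: PipelineConfig | None = None):
    """Run the full ranking on one patient bundle.

    Returns ``(ranked, report)``: the ranked table in :data:`RANKED_COLUMNS`
    order and a report dict with counts and the drop log.
    """
    config = config or PipelineConfig()
    candidates, report = candidate_table(bundle, config)
    if candidates.empty:
        raise ValidationError(f"patient {bundle.patient_id}: no candidates after filtering")
    ranked = score_patient(candidates, config.penalty_threshold_nm)
    ranked = ranked[list(RANKED_COLUMNS)]
    report["n_ranked"] = len(ranked)
    return ranked, report


def rank_strategies(
    bundle: PatientBundle, config: PipelineConfig | None = None, strategies=("venus",)
):
    """Rank one bundle under several selection strategies from one joined table."""
    config = config or PipelineConfig()
    candidates, report = candidate_table(bundle, config)
    ranked = {
        strategy: rank_alternative(
            candidates,
            strategy,
            funnel_ic50_nm=config.funnel_ic50_nm,
            funnel_tpm_min=config.funnel_tpm_min,
            penalty_threshold_nm=config.penalty_threshold_nm,
        )
        for strategy in strategies
    }
    return ranked, report


def run_pipeline(
    config: PipelineConfig | None,
    variants_tsv,
    proteins_fasta,
    cds_fasta,
    expression_tsv,
    predictions_tsv,
    out_ranked,
    out_report=None,
) -> dict:
    """File-level entry point: read inputs, rank, write ranked TSV and report."""
    config = config or PipelineConfig()
    variants, ingest_drops = read_variants_tsv(variants_tsv)
    bundle = PatientBundle(
        patient_id=Path(str(variants_tsv)).parent.name or "patient",
        alleles=(),
        variants=variants,
        contexts=load_contexts(proteins_fasta, cds_fasta),
        expression=read_expression_tsv(expression_tsv, config.tpm_floor),
        predictions=pd.read_csv(predictions_tsv, sep="\t"),
        truth=(),
    )
    ranked, report = rank_bundle(bundle, config)
    report["variants_rejected_at_ingest"] = len(ingest_drops)
    report["drops"] = [
        {"stage": "ingest", **record} for record in ingest_drops
    ] + report["drops"]
    ranked.to_csv(out_ranked, sep="\t", index=False, float_format="%.6g")
    if out_report is not None:
        with open(out_report, "w") as handle:
            json.dump(report, handle, indent=2, sort_keys=True)
            handle.write("\n")
    logger.info(
        "ranked %d candidates from %d variants (%d dropped records logged)",
        report["n_ranked"],
        report["variants_in"],
        len(report["drops"]),
    )
    return report
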