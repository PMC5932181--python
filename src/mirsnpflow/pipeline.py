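"""End-to-end orchestration and report/summary construction.

Stage order: score integration -> association filter -> eQTL annotation
-> expression correlation (optional) -> validated-interaction
cross-reference (optional) -> report. The long-form table is the
canonical output; a denormalized table in the style of the published
association table is also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .association import attach_associations, shared_disease_filter
from .config import Config
from .crossref import crossref_validated
from .eqtl import annotate_eqtl
from .expression import (
    correlate_candidates,
    expression_concordance,
    stratified_correlation,
)
from .io import load_table2_fixture
from .models import (
    AssociationEvidence,
    CombinedCandidate,
    CorrelationResult,
    EqtlAnnotation,
    EFFECT_TO_CODE,
    ExpressionMatrix,
    GenotypeTable,
    GwasRecord,
    LdPair,
    EqtlRecord,
    ToolPrediction,
    ValidatedInteraction,
    Variant,
)
from .scoring import call_candidates, zscore_harmonize

logger = logging.getLogger(__name__)


@dataclass
class PredictionReport:
    """Everything known about one retained (miRSNP, miRNA, gene) triple."""

    candidate: CombinedCandidate
    eqtl: EqtlAnnotation | None = None
    correlation_all: CorrelationResult | None = None
    correlation_hom_ref: CorrelationResult | None = None
    correlation_hom_minor: CorrelationResult | None = None
    expression_concordant: str = "not_applicable"
    validated: list[ValidatedInteraction] = field(default_factory=list)


@dataclass
class ReportEntry:
    """One retained miRSNP with its per-disease and per-miRNA records."""

    variant: Variant
    is_reported_lead: bool
    associations: list[AssociationEvidence]
    predictions: list[PredictionReport]


@dataclass
class CandidateReport:
    entries: list[ReportEntry]

    def to_long_frame(self) -> pd.DataFrame:
        """Canonical long form: one row per (miRSNP, disease, miRNA)."""
        rows = []
        for e in self.entries:
            assocs = e.associations or [None]
            for p in e.predictions:
                for a in assocs:
                    rows.append({
                        "rsid": e.variant.rsid,
                        "chrom": e.variant.chrom,
                        "pos": e.variant.pos,
                        "ref_allele": e.variant.ref_allele,
                        "minor_allele": e.variant.minor_allele,
                        "maf": e.variant.maf,
                        "is_reported_lead": e.is_reported_lead,
                        "disease": a.disease if a else None,
                        "p_value": a.p_value if a else None,
                        "odds_ratio": a.odds_ratio if a else None,
                        "support": a.support if a else None,
                        "proxy_lead_rsid": a.proxy_lead_rsid if a else None,
                        "gene": p.candidate.gene,
                        "mirna": p.candidate.mirna,
                        "effect": EFFECT_TO_CODE[p.candidate.effect],
                        "nbc_score": p.candidate.nbc_score,
                        "has_eqtl": p.eqtl.has_eqtl if p.eqtl else None,
                        "eqtl_directions": "/".join(sorted(p.eqtl.directions)) if p.eqtl else None,
                        "eqtl_concordant": p.eqtl.concordant if p.eqtl else None,
                        "corr_r": p.correlation_all.r if p.correlation_all else None,
                        "corr_p": p.correlation_all.p_value if p.correlation_all else None,
                        "corr_significant": p.correlation_all.significant
                        if p.correlation_all else None,
                        "expression_concordant": p.expression_concordant,
                        "validated": bool(p.validated),
                    })
        return pd.DataFrame(rows)

    def to_table2_frame(self) -> pd.DataFrame:
        """Denormalized view with one row per printed cell group, mirroring
        the published table's layout (variant fields only on first row)."""
        rows = []
        for e in self.entries:
            n = max(len(e.associations), len(e.predictions), 1)
            for i in range(n):
                a = e.associations[i] if i < len(e.associations) else None
                p = e.predictions[i] if i < len(e.predictions) else None
                first = i == 0
                rows.append({
                    "rsid": e.variant.rsid if first else "",
                    "chrom": e.variant.chrom if first else "",
                    "pos": e.variant.pos if first else "",
                    "disease": a.disease if a else "",
                    "p_value": a.p_value if a else "",
                    "odds_ratio": a.odds_ratio if a else "",
                    "gene": p.candidate.gene if p and first else "",
                    "mirna": p.candidate.mirna if p else "",
                    "effect": EFFECT_TO_CODE[p.candidate.effect] if p else "",
                    "nbc_score": p.candidate.nbc_score if p else "",
                    "eqtl": ("Yes" if p.eqtl.has_eqtl else "No")
                    if p and p.eqtl and first else "",
                })
        return pd.DataFrame(rows)


@dataclass
class SummaryCounts:
    """Distinct-key counts over a candidate report.

    miRSNPs count by rsid, miRNAs by exact printed name (arm suffixes
    distinguish mature products), genes by symbol.
    """

    n_mirsnps: int
    n_mirnas: int
    n_genes: int
    n_with_eqtl: int
    n_genes_with_eqtl: int
    n_reported_lead: int
    per_disease: dict[str, int]
    n_corr_significant: int
    n_corr_concordant: int
    n_validated: int

    def __post_init__(self) -> None:
        if self.n_with_eqtl > self.n_mirsnps:
            raise ValueError("n_with_eqtl cannot exceed n_mirsnps")
        if self.n_genes_with_eqtl > self.n_genes:
            raise ValueError("n_genes_with_eqtl cannot exceed n_genes")
        for disease, count in self.per_disease.items():
            if count > self.n_mirsnps:
                raise ValueError(f"per-disease count for {disease} exceeds n_mirsnps")


def summarize(report: CandidateReport) -> SummaryCounts:
    """Distinct-key summary of a report (see SummaryCounts for the rules)."""
    rsids = {e.variant.rsid for e in report.entries}
    mirnas = {p.candidate.mirna for e in report.entries for p in e.predictions}
    genes = {p.candidate.gene for e in report.entries for p in e.predictions}
    with_eqtl = {e.variant.rsid for e in report.entries
                 if any(p.eqtl and p.eqtl.has_eqtl for p in e.predictions)}
    genes_with_eqtl = {p.candidate.gene for e in report.entries for p in e.predictions
                       if p.eqtl and p.eqtl.has_eqtl}
    per_disease: dict[str, int] = {}
    for e in report.entries:
        for d in {a.disease for a in e.associations}:
            per_disease[d] = per_disease.get(d, 0) + 1
    sig_pairs = {(p.candidate.mirna, p.candidate.gene)
                 for e in report.entries for p in e.predictions
                 if p.correlation_all and p.correlation_all.significant}
    conc_pairs = {(p.candidate.mirna, p.candidate.gene)
                  for e in report.entries for p in e.predictions
                  if p.expression_concordant == "yes"}
    val_pairs = {(p.candidate.mirna, p.candidate.gene)
                 for e in report.entries for p in e.predictions if p.validated}
    return SummaryCounts(
        n_mirsnps=len(rsids),
        n_mirnas=len(mirnas),
        n_genes=len(genes),
        n_with_eqtl=len(with_eqtl),
        n_genes_with_eqtl=len(genes_with_eqtl),
        n_reported_lead=sum(e.is_reported_lead for e in report.entries),
        per_disease=per_disease,
        n_corr_significant=len(sig_pairs),
        n_corr_concordant=len(conc_pairs),
        n_validated=len(val_pairs),
    )


def run_pipeline(
    config: Config | None,
    predictions: Sequence[ToolPrediction],
    gwas: Sequence[GwasRecord],
    ld: Sequence[LdPair],
    eqtl: Sequence[EqtlRecord] = (),
    mirna_expr: ExpressionMatrix | None = None,
    mrna_expr: ExpressionMatrix | None = None,
    genotypes: GenotypeTable | None = None,
    validated: Sequence[ValidatedInteraction] | None = None,
) -> tuple[CandidateReport, SummaryCounts]:
    """Run every stage in order on in-memory inputs.

    Expression matrices and the validated table are optional; their
    stages are skipped with a logged notice when absent.
    """
    config = config or Config()

    harmonized = zscore_harmonize(predictions, config.tool_flip)
    candidates = call_candidates(harmonized, config)
    logger.info("score integration: %d candidate triples over the NBC threshold",
                len(candidates))

    annotated = shared_disease_filter(
        attach_associations(candidates, gwas, ld, config), config)
    logger.info("association filter: %d triples with >= %d diseases",
                len(annotated), config.min_shared_diseases)

    kept = [cand for cand, _ in annotated]
    annotations = annotate_eqtl(kept, eqtl, config)
    ann_by_triple = {(a.rsid, c.mirna, c.gene): a
                     for c, a in zip(kept, annotations)}

    # expression stage (optional)
    corr_all: dict[tuple[str, str], CorrelationResult] = {}
    corr_strat: dict[tuple[str, str, str], tuple[CorrelationResult, CorrelationResult]] = {}
    have_expr = mirna_expr is not None and mrna_expr is not None
    if have_expr:
        pairs = sorted({(c.mirna, c.gene) for c in kept})
        for res in correlate_candidates(pairs, mirna_expr, mrna_expr, config):
            corr_all[(res.mirna, res.gene)] = res
        if genotypes is not None:
            for c in kept:
                key = (c.rsid, c.mirna, c.gene)
                if key in corr_strat or c.rsid not in genotypes.rsids:
                    continue
                if (c.mirna not in mirna_expr.values.columns
                        or c.gene not in mrna_expr.values.columns):
                    continue
                corr_strat[key] = stratified_correlation(
                    (c.mirna, c.gene), mirna_expr, mrna_expr, genotypes, c.rsid, config)
    else:
        logger.info("expression stage skipped: no expression matrices supplied")

    # validated-interaction stage (optional)
    val_by_triple: dict[tuple[str, str], list[ValidatedInteraction]] = {}
    if validated is not None:
        for cand, matches in crossref_validated(kept, validated):
            val_by_triple[(cand.mirna, cand.gene)] = matches
    else:
        logger.info("cross-reference stage skipped: no validated table supplied")

    reported_leads = {rec.rsid for rec in gwas if rec.is_reported_lead}

    entries: dict[str, ReportEntry] = {}
    order: list[str] = []
    for cand, evidence in annotated:
        rsid = cand.rsid
        if rsid not in entries:
            entries[rsid] = ReportEntry(
                variant=cand.variant,
                is_reported_lead=rsid in reported_leads,
                associations=list(evidence),
                predictions=[],
            )
            order.append(rsid)
        ann = ann_by_triple[(rsid, cand.mirna, cand.gene)]
        c_all = corr_all.get((cand.mirna, cand.gene))
        strat = corr_strat.get((rsid, cand.mirna, cand.gene))
        entries[rsid].predictions.append(PredictionReport(
            candidate=cand,
            eqtl=ann,
            correlation_all=c_all,
            correlation_hom_ref=strat[0] if strat else None,
            correlation_hom_minor=strat[1] if strat else None,
            expression_concordant=expression_concordance(cand, c_all)
            if c_all else "not_applicable",
            validated=val_by_triple.get((cand.mirna, cand.gene), []),
        ))

    report = CandidateReport(entries=[entries[r] for r in order])
    return report, summarize(report)


def fixture_report() -> CandidateReport:
    """The packaged published association table as a CandidateReport, so
    ``summarize`` applies to it with the same distinct-key rules."""
    fx = load_table2_fixture()
    ann_by_rsid = {a.rsid: a for a in fx.eqtl}
    entries: dict[str, ReportEntry] = {}
    order: list[str] = []
    for cand in fx.candidates:
        rsid = cand.rsid
        if rsid not in entries:
            entries[rsid] = ReportEntry(
                variant=fx.variants[rsid],
                is_reported_lead=rsid in fx.lead_rsids,
                associations=[a for a in fx.associations if a.rsid == rsid],
                predictions=[],
            )
            order.append(rsid)
        entries[rsid].predictions.append(PredictionReport(
            candidate=cand, eqtl=ann_by_rsid[rsid]))
    return CandidateReport(entries=[entries[r] for r in order])
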