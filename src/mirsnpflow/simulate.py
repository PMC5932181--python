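"""Synthetic input generator with a planted truth set.

Emulates the statistical structure the pipeline assumes in its real
inputs: per-tool prediction scores are standard normal on each tool's
native scale with true triples shifted upward on the z scale; null GWAS
P-values are Uniform(0, 1) while planted leads are genome-wide
significant; planted miRSNPs are either their own lead or sit in perfect
LD (r2 = 1, D' = 1) with one, and decoy LD pairs stay below the proxy
threshold; genotypes are Binomial(2, MAF) draws (Hardy-Weinberg);
expression is log2-scale Gaussian, with the target mRNA of a coupled
truth linearly driven by its miRNA among minor-allele homozygotes only.

Every truth therefore satisfies all pipeline pass conditions by
construction, so end-to-end recovery of the truth set is a meaningful
sensitivity measure. What the generator does NOT emulate: realistic LD
block structure, population stratification, read-count noise, or
correlated expression between genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    CREATE,
    DISRUPT,
    DISEASES,
    EQTL_SOURCES,
    EqtlRecord,
    ExpressionMatrix,
    GenotypeTable,
    GwasRecord,
    LdPair,
    ToolPrediction,
    ValidatedInteraction,
    Variant,
)
from .io import write_table, write_expression_matrix, write_genotype_table

#: Native (scale, offset) of each emulated tool's raw-score distribution;
#: z-scoring must recover the same standardized values regardless.
_TOOL_SCALES = {"polymirts": (1.0, 0.0), "mirnasnp2": (10.0, 50.0), "mirsnpscore": (0.2, -1.0)}

_TISSUES = ("whole_blood", "lcl", "small_intestine", "thyroid", "muscle_skeletal")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator; defaults define the study-scale conditions."""

    n_variants: int = 2000
    n_mirnas: int = 150
    n_genes: int = 100
    n_diseases: int = 12
    n_true_mirsnps: int = 20
    n_samples: int = 300
    tool_signal_shift: float = 2.5
    lead_log10p_range: tuple[float, float] = (9.0, 20.0)
    ld_block_size: int = 5
    expr_effect_size: float = -0.8
    noise_sd: float = 1.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    eqtl_prob: float = 0.8
    coupling_prob: float = 0.9
    own_lead_prob: float = 0.15
    missing_genotype_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_mirsnps > self.n_variants:
            raise ValueError("cannot plant more truths than variants")
        if self.n_true_mirsnps > min(self.n_mirnas, self.n_genes):
            raise ValueError("truth triples need distinct miRNAs and genes")
        if self.n_diseases < 2 or self.n_diseases > len(DISEASES):
            raise ValueError(f"n_diseases must be in [2, {len(DISEASES)}]")
        for name in ("n_variants", "n_mirnas", "n_genes", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError(f"bad maf_range {self.maf_range}")


@dataclass(frozen=True)
class TruthRecord:
    """One planted miRSNP with every attribute the pipeline should recover."""

    rsid: str
    mirna: str
    gene: str
    effect: str
    diseases: frozenset[str]
    lead_rsid: str  # == rsid when the truth is its own reported lead
    has_eqtl: bool
    eqtl_direction: str | None
    expression_coupled: bool


@dataclass
class SimulatedBundle:
    """All generated input tables plus the truth set."""

    params: SimulationParams
    predictions: list[ToolPrediction]
    gwas: list[GwasRecord]
    ld: list[LdPair]
    eqtl: list[EqtlRecord]
    mirna_expr: ExpressionMatrix
    mrna_expr: ExpressionMatrix
    genotypes: GenotypeTable
    validated: list[ValidatedInteraction]
    truths: list[TruthRecord]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(out / "predictions.tsv", self.predictions, "tool_prediction")
        write_table(out / "gwas.tsv", self.gwas, "gwas")
        write_table(out / "ld.tsv", self.ld, "ld")
        write_table(out / "eqtl.tsv", self.eqtl, "eqtl")
        write_table(out / "validated.tsv", self.validated, "validated")
        write_expression_matrix(out / "mirna_expr.tsv", self.mirna_expr)
        write_expression_matrix(out / "mrna_expr.tsv", self.mrna_expr)
        write_genotype_table(out / "genotypes.tsv", self.genotypes)
        rows = []
        for t in self.truths:
            rows.append({
                "rsid": t.rsid, "mirna": t.mirna, "gene": t.gene, "effect": t.effect,
                "diseases": ";".join(sorted(t.diseases)), "lead_rsid": t.lead_rsid,
                "has_eqtl": t.has_eqtl, "eqtl_direction": t.eqtl_direction or "NA",
                "expression_coupled": t.expression_coupled,
            })
        pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)


def dosage_ld(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors (the usual
    composite r2 estimate); internal consistency helper only."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


_ALLELES = ("A", "C", "G", "T")


def simulate(params: SimulationParams | None = None) -> SimulatedBundle:
    """Generate the full input bundle for the given parameters.

    Deterministic for a fixed seed: everything is drawn from a single
    integer-seeded generator in fixed order.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)

    mirna_pool = [f"hsa-miR-sim{j:03d}" for j in range(params.n_mirnas)]
    gene_pool = [f"GENE{j:03d}" for j in range(params.n_genes)]
    diseases = list(DISEASES[: params.n_diseases])

    # --- variants, each predicted against one (miRNA, gene) triple -------
    variants: list[Variant] = []
    for i in range(params.n_variants):
        ref, minor = rng.choice(4, size=2, replace=False)
        variants.append(Variant(
            rsid=f"rs{100001 + i}",
            chrom=str(int(rng.integers(1, 23))),
            pos=int(1_000_000 + i * 1_000 + rng.integers(0, 1_000)),
            ref_allele=_ALLELES[ref], minor_allele=_ALLELES[minor],
            maf=float(rng.uniform(*params.maf_range)),
        ))

    truth_idx = sorted(int(i) for i in rng.choice(params.n_variants,
                                                  params.n_true_mirsnps, replace=False))
    truth_set = set(truth_idx)
    # truths take distinct miRNAs/genes so planted expression couplings do
    # not overwrite each other
    truth_mirnas = [mirna_pool[int(j)] for j in
                    rng.choice(params.n_mirnas, params.n_true_mirsnps, replace=False)]
    truth_genes = [gene_pool[int(j)] for j in
                   rng.choice(params.n_genes, params.n_true_mirsnps, replace=False)]

    triple: dict[int, tuple[str, str]] = {}
    for k, i in enumerate(truth_idx):
        triple[i] = (truth_mirnas[k], truth_genes[k])
    for i in range(params.n_variants):
        if i not in triple:
            triple[i] = (mirna_pool[int(rng.integers(params.n_mirnas))],
                         gene_pool[int(rng.integers(params.n_genes))])

    truth_effects = {i: (CREATE if rng.random() < 0.5 else DISRUPT) for i in truth_idx}

    # --- tool predictions -------------------------------------------------
    predictions: list[ToolPrediction] = []
    for i, var in enumerate(variants):
        mirna, gene = triple[i]
        is_true = i in truth_set
        for tool, (scale, offset) in _TOOL_SCALES.items():
            z = rng.standard_normal() + (params.tool_signal_shift if is_true else 0.0)
            effect = truth_effects[i] if is_true else (CREATE if rng.random() < 0.5 else DISRUPT)
            predictions.append(ToolPrediction(
                tool=tool, variant=var, mirna=mirna, gene=gene,
                raw_score=float(z * scale + offset), effect=effect,
            ))

    # --- GWAS leads, LD proxies and null summary statistics ---------------
    gwas: list[GwasRecord] = []
    ld: list[LdPair] = []
    truths: list[TruthRecord] = []
    lo_log, hi_log = params.lead_log10p_range
    for k, i in enumerate(truth_idx):
        var = variants[i]
        n_dis = int(rng.integers(2, 5))
        assigned = [diseases[int(j)] for j in rng.choice(len(diseases), n_dis, replace=False)]
        own_lead = rng.random() < params.own_lead_prob
        lead_rsid = var.rsid if own_lead else f"rs{900001 + k}"
        if not own_lead:
            ld.append(LdPair(rsid_a=lead_rsid, rsid_b=var.rsid, r2=1.0, dprime=1.0))
        for disease in assigned:
            p = float(10.0 ** (-rng.uniform(lo_log, hi_log)))
            gwas.append(GwasRecord(
                disease=disease, rsid=lead_rsid, p_value=p,
                odds_ratio=float(rng.uniform(1.05, 1.6)), is_reported_lead=True,
            ))
        truths.append(TruthRecord(
            rsid=var.rsid, mirna=triple[i][0], gene=triple[i][1],
            effect=truth_effects[i], diseases=frozenset(assigned),
            lead_rsid=lead_rsid,
            has_eqtl=bool(rng.random() < params.eqtl_prob),
            eqtl_direction=None,  # filled below
            expression_coupled=bool(rng.random() < params.coupling_prob),
        ))

    # null summary statistics: P ~ Uniform(0, 1)
    for disease in diseases:
        null_idx = rng.choice(params.n_variants, size=min(200, params.n_variants), replace=False)
        for j in null_idx:
            if int(j) in truth_set:
                continue
            gwas.append(GwasRecord(
                disease=disease, rsid=variants[int(j)].rsid,
                p_value=float(rng.uniform()), odds_ratio=float(rng.uniform(0.8, 1.25)),
                is_reported_lead=False,
            ))

    # decoy LD pairs, grouped in small blocks, all below the proxy threshold
    n_blocks = max(1, params.n_variants // (10 * params.ld_block_size))
    for _ in range(n_blocks):
        block = rng.choice(params.n_variants, size=params.ld_block_size, replace=False)
        for a, b in zip(block[:-1], block[1:]):
            ld.append(LdPair(
                rsid_a=variants[int(a)].rsid, rsid_b=variants[int(b)].rsid,
                r2=float(rng.uniform(0.0, 0.8 - 1e-9)), dprime=float(rng.uniform(0.0, 1.0)),
            ))

    # --- eQTL records ------------------------------------------------------
    eqtl: list[EqtlRecord] = []
    for k, t in enumerate(truths):
        if not t.has_eqtl:
            continue
        direction = "up" if t.effect == DISRUPT else "down"
        truths[k] = replace(t, eqtl_direction=direction)
        for _ in range(int(rng.integers(1, 3))):
            eqtl.append(EqtlRecord(
                rsid=t.rsid, gene=t.gene,
                tissue=_TISSUES[int(rng.integers(len(_TISSUES)))],
                direction=direction, fdr=0.01,
                source=EQTL_SOURCES[int(rng.integers(len(EQTL_SOURCES)))],
            ))
    # decoys on null variants; some exceed the load-time FDR cut on purpose
    for j in rng.choice(params.n_variants, size=min(100, params.n_variants), replace=False):
        if int(j) in truth_set:
            continue
        var = variants[int(j)]
        eqtl.append(EqtlRecord(
            rsid=var.rsid, gene=triple[int(j)][1],
            tissue=_TISSUES[int(rng.integers(len(_TISSUES)))],
            direction="up" if rng.random() < 0.5 else "down",
            fdr=float(rng.uniform(0.0, 0.2)),
            source=EQTL_SOURCES[int(rng.integers(len(EQTL_SOURCES)))],
        ))

    # --- genotypes and expression -----------------------------------------
    samples = [f"S{i:04d}" for i in range(params.n_samples)]
    dosage_arr = rng.binomial(2, [v.maf for v in variants],
                              size=(params.n_samples, params.n_variants)).astype(float)
    missing = rng.random(dosage_arr.shape) < params.missing_genotype_rate
    dosage_df = pd.DataFrame(dosage_arr, index=samples,
                             columns=[v.rsid for v in variants])
    dosage_df = dosage_df.mask(missing).astype("Int64")
    genotypes = GenotypeTable(dosage_df)

    mirna_vals = rng.normal(5.0, 1.0, size=(params.n_samples, params.n_mirnas))
    mirna_df = pd.DataFrame(mirna_vals, index=samples, columns=mirna_pool)
    mrna_vals = rng.normal(8.0, params.noise_sd, size=(params.n_samples, params.n_genes))
    mrna_df = pd.DataFrame(mrna_vals, index=samples, columns=gene_pool)

    rsid_to_col = {v.rsid: j for j, v in enumerate(variants)}
    for t in truths:
        if not t.expression_coupled:
            continue
        dos = dosage_arr[:, rsid_to_col[t.rsid]].copy()
        dos[missing[:, rsid_to_col[t.rsid]]] = np.nan
        hom_minor = dos == 2
        # create: planted negative slope (site represses target);
        # disrupt: mirrored positive slope
        slope = params.expr_effect_size if t.effect == CREATE else -params.expr_effect_size
        x = mirna_df[t.mirna].to_numpy()
        mrna_df.loc[hom_minor, t.gene] = (
            8.0 + slope * (x[hom_minor] - 5.0)
            + rng.normal(0.0, params.noise_sd, size=int(hom_minor.sum()))
        )

    mirna_expr = ExpressionMatrix(mirna_df, "mirna")
    mrna_expr = ExpressionMatrix(mrna_df, "mrna")

    # --- validated interactions -------------------------------------------
    validated: list[ValidatedInteraction] = []
    n_val = min(5, len(truths))
    for t in truths[:n_val]:
        validated.append(ValidatedInteraction(
            mirna=t.mirna, gene=t.gene, method="CLIP-seq",
            source="mirtarbase" if rng.random() < 0.5 else "tarbase",
        ))
    for _ in range(10):  # decoys not matching any candidate triple
        validated.append(ValidatedInteraction(
            mirna=f"hsa-miR-decoy{int(rng.integers(1000))}",
            gene=gene_pool[int(rng.integers(params.n_genes))],
            method="Luciferase reporter assay",
            source="mirtarbase" if rng.random() < 0.5 else "tarbase",
        ))

    return SimulatedBundle(
        params=params, predictions=predictions, gwas=gwas, ld=ld, eqtl=eqtl,
        mirna_expr=mirna_expr, mrna_expr=mrna_expr, genotypes=genotypes,
        validated=validated, truths=truths,
    )
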