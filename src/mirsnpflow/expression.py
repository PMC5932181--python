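"""miRNA-mRNA expression correlation, overall and within homozygote strata.

Expression matrices are log2-scale, samples x features. Samples are
matched by identifier intersection across the miRNA matrix, the mRNA
matrix and (when supplied) the genotype table. Correlation is plain
Pearson with a two-sided t test on n - 2 degrees of freedom; no multiple
testing correction is applied by default (an optional Benjamini-Hochberg
switch exists in the config).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import Config
from .models import (
    AMBIGUOUS,
    CREATE,
    CombinedCandidate,
    CorrelationResult,
    ExpressionMatrix,
    GenotypeTable,
)

logger = logging.getLogger(__name__)


def match_samples(mirna_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix,
                  genotypes: GenotypeTable | None = None) -> list[str]:
    """Sorted intersection of sample ids across the supplied inputs."""
    common = set(mirna_expr.sample_ids) & set(mrna_expr.sample_ids)
    if genotypes is not None:
        common &= set(genotypes.sample_ids)
    if not common:
        raise ValueError("no samples shared across the supplied matrices")
    return sorted(common)


def _undefined(mirna: str, gene: str, stratum: str, n: int, reason: str) -> CorrelationResult:
    return CorrelationResult(mirna=mirna, gene=gene, stratum=stratum, n=n,
                             r=float("nan"), p_value=float("nan"),
                             significant=False, ok=False, reason=reason)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Sample Pearson r with its two-sided t-test P (n - 2 df).

    Raises for mismatched lengths or n < 3; zero variance in either
    vector raises ValueError too — batch callers catch it and emit a
    flagged undefined result instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    # two-sided P is in (0, 1]; clip the perfectly collinear case
    return r, max(p, 5e-324), n


def _correlate(mirna: str, gene: str, x: np.ndarray, y: np.ndarray,
               stratum: str, config: Config) -> CorrelationResult:
    try:
        r, p, n = pearson(x, y)
    except ValueError as exc:
        return _undefined(mirna, gene, stratum, int(x.size), str(exc))
    return CorrelationResult(mirna=mirna, gene=gene, stratum=stratum, n=n, r=r,
                             p_value=p, significant=p < config.corr_p_threshold)


def correlate_candidates(
    pairs: Sequence[tuple[str, str]],
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    config: Config | None = None,
) -> list[CorrelationResult]:
    """Pearson correlation for each (miRNA, gene) pair on matched samples.

    Pairs whose miRNA or gene is absent from the matrices are logged and
    skipped. With ``config.bh_fdr`` the significance flags are replaced
    by Benjamini-Hochberg rejection at the same alpha.
    """
    config = config or Config()
    samples = match_samples(mirna_expr, mrna_expr)
    out: list[CorrelationResult] = []
    for mirna, gene in pairs:
        if mirna not in mirna_expr.values.columns:
            logger.info("skip (%s, %s): miRNA absent from expression matrix", mirna, gene)
            continue
        if gene not in mrna_expr.values.columns:
            logger.info("skip (%s, %s): gene absent from expression matrix", mirna, gene)
            continue
        x = mirna_expr.vector(mirna, samples)
        y = mrna_expr.vector(gene, samples)
        out.append(_correlate(mirna, gene, x, y, "all", config))
    if config.bh_fdr:
        out = _apply_bh(out, config.corr_p_threshold)
    return out


def _apply_bh(results: list[CorrelationResult], alpha: float) -> list[CorrelationResult]:
    idx = [i for i, r in enumerate(results) if r.ok]
    if not idx:
        return results
    reject, _, _, _ = multipletests([results[i].p_value for i in idx],
                                    alpha=alpha, method="fdr_bh")[:4]
    out = list(results)
    for flag, i in zip(reject, idx):
        r = results[i]
        out[i] = CorrelationResult(mirna=r.mirna, gene=r.gene, stratum=r.stratum,
                                   n=r.n, r=r.r, p_value=r.p_value,
                                   significant=bool(flag), ok=r.ok, reason=r.reason)
    return out


def stratified_correlation(
    pair: tuple[str, str],
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    genotypes: GenotypeTable,
    rsid: str,
    config: Config | None = None,
) -> tuple[CorrelationResult, CorrelationResult]:
    """Correlation within reference-homozygote and minor-homozygote strata.

    Heterozygous and missing-genotype samples are excluded. A stratum
    smaller than ``config.min_stratum_size`` yields a flagged undefined
    result rather than an exception.
    """
    config = config or Config()
    mirna, gene = pair
    samples = match_samples(mirna_expr, mrna_expr, genotypes)
    dosage = genotypes.dosage(rsid, samples)

    results = []
    for stratum, wanted in (("hom_ref", 0), ("hom_minor", 2)):
        sub = [s for s, d in zip(samples, dosage) if pd.notna(d) and d == wanted]
        if len(sub) < config.min_stratum_size:
            results.append(_undefined(mirna, gene, stratum, len(sub),
                                      f"stratum size {len(sub)} < {config.min_stratum_size}"))
            continue
        x = mirna_expr.vector(mirna, sub)
        y = mrna_expr.vector(gene, sub)
        results.append(_correlate(mirna, gene, x, y, stratum, config))
    return results[0], results[1]


def expression_concordance(candidate: CombinedCandidate, result: CorrelationResult) -> str:
    """Does the correlation sign match the predicted binding effect?

    A created site represses its target, so ``create`` predicts negative
    correlation between miRNA and mRNA levels; ``disrupt`` predicts
    positive. Non-significant (or undefined) results and ambiguous
    predicted effects are ``not_applicable``.
    """
    if not result.significant or candidate.effect == AMBIGUOUS:
        return "not_applicable"
    expected_negative = candidate.effect == CREATE
    return "yes" if (result.r < 0) == expected_negative else "no"
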