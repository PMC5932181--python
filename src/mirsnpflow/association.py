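"""GWAS support per disease, with LD-proxy expansion and the shared-disease rule.

A candidate miRSNP is supported for a disease when it is itself
genome-wide significant there (P < 5e-8 by default), or when it is a
strong LD proxy (r2 >= 0.8 and D' = 1 by default) of a significant lead
SNP that the study did report. Candidates supported by fewer than two
distinct diseases are dropped.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Sequence

from .config import Config
from .models import AssociationEvidence, CombinedCandidate, GwasRecord, LdPair

logger = logging.getLogger(__name__)


def significant_leads(gwas: Sequence[GwasRecord],
                      config: Config | None = None) -> dict[str, set[str]]:
    """Per disease, the rsids with P strictly below the genome-wide threshold.

    Multiple studies of one disease are merged by taking each rsid's
    minimum P; records with missing P contribute nothing.
    """
    config = config or Config()
    best: dict[tuple[str, str], float] = {}
    for rec in gwas:
        if rec.p_value is None:
            continue
        key = (rec.disease, rec.rsid)
        if key not in best or rec.p_value < best[key]:
            best[key] = rec.p_value
    leads: dict[str, set[str]] = defaultdict(set)
    for (disease, rsid), p in best.items():
        if p < config.gwas_p_threshold:
            leads[disease].add(rsid)
    return dict(leads)


def _symmetrize(ld: Sequence[LdPair]) -> dict[str, list[LdPair]]:
    """Index LD pairs by either endpoint (the table is unordered)."""
    index: dict[str, list[LdPair]] = defaultdict(list)
    for pair in ld:
        index[pair.rsid_a].append(pair)
        index[pair.rsid_b].append(pair)
    return index


def _qualifies(pair: LdPair, config: Config) -> bool:
    if pair.r2 < config.ld_r2_min:
        return False
    if config.require_dprime and abs(pair.dprime - config.ld_dprime_required) > config.ld_dprime_tol:
        return False
    return True


def ld_proxies(rsid: str, ld: Sequence[LdPair], config: Config | None = None) -> set[str]:
    """All partners in qualifying LD with ``rsid``, plus ``rsid`` itself.

    Qualifying means r2 >= ld_r2_min (inclusive) and, unless disabled,
    D' equal to ld_dprime_required within tolerance. A SNP is trivially
    its own proxy (r2 = 1 with itself).
    """
    config = config or Config()
    proxies = {rsid}
    for pair in ld:
        if rsid not in (pair.rsid_a, pair.rsid_b):
            continue
        if _qualifies(pair, config):
            proxies.add(pair.rsid_b if pair.rsid_a == rsid else pair.rsid_a)
    return proxies


def attach_associations(
    candidates: Sequence[CombinedCandidate],
    gwas: Sequence[GwasRecord],
    ld: Sequence[LdPair],
    config: Config | None = None,
) -> list[tuple[CombinedCandidate, list[AssociationEvidence]]]:
    """Attach per-disease GWAS evidence to each candidate.

    Direct evidence (the candidate rsid is itself a significant lead for
    the disease) is preferred over proxy evidence. Proxy evidence picks
    the best qualifying lead: highest r2, ties broken by lead rsid
    lexicographically; its P/OR are left missing, mirroring summary
    tables that print NA for SNPs the study did not evaluate.
    """
    config = config or Config()
    leads = significant_leads(gwas, config)
    ld_index = _symmetrize(ld)

    # min-P record per (disease, rsid) for direct evidence P/OR reporting
    best_rec: dict[tuple[str, str], GwasRecord] = {}
    for rec in gwas:
        if rec.p_value is None:
            continue
        key = (rec.disease, rec.rsid)
        if key not in best_rec or rec.p_value < best_rec[key].p_value:
            best_rec[key] = rec

    out: list[tuple[CombinedCandidate, list[AssociationEvidence]]] = []
    for cand in candidates:
        evidence: list[AssociationEvidence] = []
        for disease in sorted(leads):
            disease_leads = leads[disease]
            if cand.rsid in disease_leads:
                rec = best_rec[(disease, cand.rsid)]
                evidence.append(AssociationEvidence(
                    rsid=cand.rsid, disease=disease,
                    p_value=rec.p_value, odds_ratio=rec.odds_ratio,
                    support="direct",
                ))
                logger.debug("admit %s/%s: direct P=%g < %g",
                             cand.rsid, disease, rec.p_value, config.gwas_p_threshold)
                continue
            best: LdPair | None = None
            best_lead: str | None = None
            for pair in ld_index.get(cand.rsid, ()):
                other = pair.rsid_b if pair.rsid_a == cand.rsid else pair.rsid_a
                if other not in disease_leads or not _qualifies(pair, config):
                    continue
                if (best is None or pair.r2 > best.r2
                        or (pair.r2 == best.r2 and other < best_lead)):
                    best, best_lead = pair, other
            if best is not None:
                evidence.append(AssociationEvidence(
                    rsid=cand.rsid, disease=disease,
                    p_value=None, odds_ratio=None,
                    support="ld_proxy", proxy_lead_rsid=best_lead,
                    proxy_r2=best.r2, proxy_dprime=best.dprime,
                ))
                logger.debug("admit %s/%s: proxy of %s (r2=%g, D'=%g)",
                             cand.rsid, disease, best_lead, best.r2, best.dprime)
        out.append((cand, evidence))
    return out


def shared_disease_filter(
    annotated: Sequence[tuple[CombinedCandidate, list[AssociationEvidence]]],
    config: Config | None = None,
) -> list[tuple[CombinedCandidate, list[AssociationEvidence]]]:
    """Keep candidates supported by at least ``min_shared_diseases`` distinct
    disease labels (IBD, CD and UC count separately)."""
    config = config or Config()
    kept = []
    for cand, evidence in annotated:
        n = len({e.disease for e in evidence})
        if n >= config.min_shared_diseases:
            kept.append((cand, evidence))
        else:
            logger.debug("reject %s: %d disease(s) < %d",
                         cand.rsid, n, config.min_shared_diseases)
    return kept
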