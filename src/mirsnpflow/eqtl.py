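"""eQTL annotation of candidate (miRSNP, gene) pairs.

Records from all sources are pooled; a pair has eQTL evidence when at
least one FDR-passing record matches it exactly. Direction labels are
taken as the minor-allele effect on the gene's expression, a contract the
loader of each source must deliver (public sources mix z-score, slope and
allele-orientation conventions).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from .config import Config
from .models import (
    AMBIGUOUS,
    CREATE,
    DISRUPT,
    CombinedCandidate,
    EqtlAnnotation,
    EqtlRecord,
)


def direction_concordance(candidate: CombinedCandidate, annotation: EqtlAnnotation) -> str:
    """Does the eQTL direction agree with the predicted binding effect?

    Disrupting a repressive miRNA site should raise target expression
    (direction up); creating one should lower it (down). Mixed directions
    across tissues/sources are ``ambiguous``; no eQTL or an ambiguous
    predicted effect is ``not_applicable``.
    """
    if not annotation.has_eqtl or candidate.effect == AMBIGUOUS:
        return "not_applicable"
    if len(annotation.directions) != 1:
        return "ambiguous"
    (direction,) = annotation.directions
    expected = "up" if candidate.effect == DISRUPT else "down"
    return "yes" if direction == expected else "no"


def annotate_eqtl(
    candidates: Sequence[CombinedCandidate],
    eqtl: Sequence[EqtlRecord],
    config: Config | None = None,
) -> list[EqtlAnnotation]:
    """One pooled annotation per candidate, matched on exact (rsid, gene).

    ``eqtl`` is expected to be FDR-filtered already (the loader drops
    records above ``config.eqtl_fdr_max``); any stragglers are ignored
    here as well so the invariant holds regardless of entry path.
    """
    config = config or Config()
    index: dict[tuple[str, str], list[EqtlRecord]] = defaultdict(list)
    for rec in eqtl:
        if rec.fdr <= config.eqtl_fdr_max:
            index[(rec.rsid, rec.gene)].append(rec)

    out: list[EqtlAnnotation] = []
    for cand in candidates:
        records = tuple(index.get((cand.rsid, cand.gene), ()))
        directions = frozenset(r.direction for r in records)
        ann = EqtlAnnotation(
            rsid=cand.rsid, gene=cand.gene,
            has_eqtl=bool(records), directions=directions, records=records,
        )
        out.append(EqtlAnnotation(
            rsid=ann.rsid, gene=ann.gene, has_eqtl=ann.has_eqtl,
            directions=ann.directions, records=ann.records,
            concordant=direction_concordance(cand, ann),
        ))
    return out
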