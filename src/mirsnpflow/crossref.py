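"""Cross-reference candidates against experimentally validated interactions."""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

from .models import CombinedCandidate, ValidatedInteraction


def canonical_mirna(name: str) -> str:
    """Canonical form for miRNA-name comparison: case-folded, species
    prefix stripped. Arm suffixes (-3p/-5p) are deliberately kept:
    miR-136 and miR-136-5p are distinct mature products."""
    n = name.strip().casefold()
    if n.startswith("hsa-"):
        n = n[4:]
    return n


def crossref_validated(
    candidates: Sequence[CombinedCandidate],
    validated: Sequence[ValidatedInteraction],
) -> list[tuple[CombinedCandidate, list[ValidatedInteraction]]]:
    """Match candidates to validated interactions on (miRNA, gene).

    miRNA names are compared canonically; gene symbols are compared as
    exact strings (no alias dictionary). Candidates without a match carry
    an empty list.
    """
    index: dict[tuple[str, str], list[ValidatedInteraction]] = defaultdict(list)
    for v in validated:
        index[(canonical_mirna(v.mirna), v.gene)].append(v)
    return [
        (cand, list(index.get((canonical_mirna(cand.mirna), cand.gene), ())))
        for cand in candidates
    ]
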