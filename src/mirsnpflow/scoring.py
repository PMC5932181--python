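"""Score harmonization and naive Bayes evidence combination.

Each prediction tool scores on its own scale, so raw scores are first
z-scored within tool (sample standard deviation), mapped to the unit
interval through the standard normal CDF, and then combined across tools
under an independence assumption:

    S = 1 - prod_i (1 - S_i)

The CDF mapping is a modeling choice of this package: it is monotone,
parameter-free, and sends the harmonized (mean 0, sd 1) scale to (0, 1)
as the combination rule requires. A triple scored by fewer than three
tools is combined over the tools present; an absent tool contributes a
factor of 1 (no evidence either way).
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .config import Config
from .models import (
    AMBIGUOUS,
    CombinedCandidate,
    HarmonizedScore,
    ToolPrediction,
)


def zscore_harmonize(predictions: Sequence[ToolPrediction],
                     tool_flip: Mapping[str, bool] | None = None) -> list[HarmonizedScore]:
    """Standardize raw scores within each tool and map them to (0, 1).

    Uses the sample standard deviation (n - 1 denominator) over the tool's
    full score set in the current run. A tool with fewer than two
    predictions, or with zero spread, cannot be standardized and raises.
    ``tool_flip[tool] = True`` negates that tool's raw scores first (for
    tools whose native scale decreases with evidence strength).
    """
    tool_flip = tool_flip or {}
    by_tool: dict[str, list[float]] = defaultdict(list)
    for p in predictions:
        raw = -p.raw_score if tool_flip.get(p.tool) else p.raw_score
        by_tool[p.tool].append(raw)

    stats: dict[str, tuple[float, float]] = {}
    for tool, scores in by_tool.items():
        if len(scores) < 2:
            raise ValueError(f"tool {tool!r} has {len(scores)} prediction(s); need >= 2 to z-score")
        arr = np.asarray(scores, dtype=float)
        sd = float(arr.std(ddof=1))
        if sd == 0.0:
            raise ValueError(f"tool {tool!r} has zero score spread; cannot z-score")
        stats[tool] = (float(arr.mean()), sd)

    out: list[HarmonizedScore] = []
    for p in predictions:
        mean, sd = stats[p.tool]
        raw = -p.raw_score if tool_flip.get(p.tool) else p.raw_score
        z = (raw - mean) / sd
        out.append(HarmonizedScore(
            tool=p.tool, variant=p.variant, mirna=p.mirna, gene=p.gene,
            z_score=z, unit_score=to_unit_interval(z), effect=p.effect,
        ))
    return out


def to_unit_interval(z: float) -> float:
    """Map a standardized score to (0, 1) via the standard normal CDF."""
    if not math.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    return float(norm.cdf(z))


def combine_nbc(unit_scores: Mapping[str, float] | Iterable[float]) -> float:
    """Naive Bayes combined score S = 1 - prod(1 - S_i) over tools present."""
    values = list(unit_scores.values()) if isinstance(unit_scores, Mapping) else list(unit_scores)
    if not values:
        raise ValueError("combine_nbc needs at least one unit score")
    complement = 1.0
    for s in values:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"unit score outside [0, 1]: {s}")
        complement *= 1.0 - s
    return 1.0 - complement


def consensus_effect(effects: Mapping[str, str] | Iterable[str]) -> str:
    """Unanimous effect across tools, else ``ambiguous``."""
    values = set(effects.values()) if isinstance(effects, Mapping) else set(effects)
    if not values:
        raise ValueError("consensus_effect needs at least one effect call")
    return values.pop() if len(values) == 1 else AMBIGUOUS


def call_candidates(harmonized: Sequence[HarmonizedScore],
                    config: Config | None = None) -> list[CombinedCandidate]:
    """Group harmonized scores by (variant, miRNA, gene) and keep triples
    whose combined score strictly exceeds the threshold.

    Within one triple only a tool's strongest unit score is kept should a
    tool somehow report the same triple twice. Output order follows first
    appearance of each retained triple.
    """
    config = config or Config()
    grouped: dict[tuple[str, str, str], dict[str, HarmonizedScore]] = {}
    order: list[tuple[str, str, str]] = []
    for h in harmonized:
        key = (h.variant.rsid, h.mirna, h.gene)
        if key not in grouped:
            grouped[key] = {}
            order.append(key)
        prev = grouped[key].get(h.tool)
        if prev is None or h.unit_score > prev.unit_score:
            grouped[key][h.tool] = h

    out: list[CombinedCandidate] = []
    for key in order:
        scores = grouped[key]
        unit = {tool: h.unit_score for tool, h in scores.items()}
        s = combine_nbc(unit)
        if s > config.nbc_threshold:
            any_h = next(iter(scores.values()))
            out.append(CombinedCandidate(
                variant=any_h.variant,
                mirna=any_h.mirna,
                gene=any_h.gene,
                unit_scores=unit,
                nbc_score=s,
                effect=consensus_effect({tool: h.effect for tool, h in scores.items()}),
            ))
    return out
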