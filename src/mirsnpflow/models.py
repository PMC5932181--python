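"""Domain records shared by every pipeline stage.

All records are plain dataclasses that validate their own invariants at
construction, so a table that parsed successfully is structurally sound
everywhere downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TOOLS = ("polymirts", "mirnasnp2", "mirsnpscore")

#: Controlled disease vocabulary (labels as printed; IBD, CD and UC are
#: distinct labels and are counted separately).
DISEASES = (
    "Ankylosing spondylitis",
    "Autoimmune thyroid disease",
    "Celiac disease",
    "Crohn's disease",
    "Inflammatory bowel disease",
    "Juvenile idiopathic arthritis",
    "Multiple sclerosis",
    "Primary biliary cirrhosis",
    "Psoriasis",
    "Rheumatoid arthritis",
    "Systemic lupus erythematosus",
    "Type 1 diabetes mellitus",
    "Ulcerative colitis",
)

EQTL_SOURCES = ("blood_eqtl", "geuvadis", "gtex")
VALIDATION_SOURCES = ("mirtarbase", "tarbase")

CREATE = "create"
DISRUPT = "disrupt"
AMBIGUOUS = "ambiguous"

#: Single-letter effect codes used in printed tables.
EFFECT_CODES = {"C": CREATE, "D": DISRUPT}
EFFECT_TO_CODE = {CREATE: "C", DISRUPT: "D", AMBIGUOUS: "?"}


def _finite(x: float, name: str) -> None:
    if not math.isfinite(x):
        raise ValueError(f"{name} must be finite, got {x}")


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP (or short indel, stored verbatim) on hg38, 1-based."""

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    minor_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.minor_allele:
            raise ValueError(f"{self.rsid}: ref and minor allele are identical")
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"{self.rsid}: maf must be in [0, 1], got {self.maf}")
        if self.maf > 0.5:
            # Printed tables report MAF up to 0.53 for some "minor" alleles;
            # which population defines minor is a data-source convention.
            warnings.warn(f"{self.rsid}: MAF {self.maf} > 0.5 stored as given", stacklevel=2)


@dataclass(frozen=True)
class ToolPrediction:
    """One tool's raw call that an allele creates/disrupts a miRNA site."""

    tool: str
    variant: Variant
    mirna: str
    gene: str
    raw_score: float
    effect: str

    def __post_init__(self) -> None:
        if self.tool not in TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}; expected one of {TOOLS}")
        _finite(self.raw_score, "raw_score")
        if self.effect not in (CREATE, DISRUPT):
            raise ValueError(f"effect must be create/disrupt, got {self.effect!r}")


@dataclass(frozen=True)
class HarmonizedScore:
    """A tool prediction after within-tool z-scoring and CDF mapping to (0, 1)."""

    tool: str
    variant: Variant
    mirna: str
    gene: str
    z_score: float
    unit_score: float
    effect: str

    def __post_init__(self) -> None:
        _finite(self.z_score, "z_score")
        if not 0.0 <= self.unit_score <= 1.0:
            raise ValueError(f"unit_score must be in [0, 1], got {self.unit_score}")


@dataclass(frozen=True)
class CombinedCandidate:
    """A (miRSNP, miRNA, gene) triple with its naive Bayes combined score."""

    variant: Variant
    mirna: str
    gene: str
    unit_scores: dict[str, float]
    nbc_score: float
    effect: str

    def __post_init__(self) -> None:
        for tool, s in self.unit_scores.items():
            if tool not in TOOLS:
                raise ValueError(f"unknown tool {tool!r} in unit_scores")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"unit score for {tool} outside [0, 1]: {s}")
        if not 0.0 <= self.nbc_score <= 1.0:
            raise ValueError(f"nbc_score must be in [0, 1], got {self.nbc_score}")
        if self.unit_scores and self.nbc_score < max(self.unit_scores.values()) - 1e-9:
            raise ValueError("nbc_score below the maximum per-tool score")
        if self.effect not in (CREATE, DISRUPT, AMBIGUOUS):
            raise ValueError(f"bad effect {self.effect!r}")

    @property
    def rsid(self) -> str:
        return self.variant.rsid


@dataclass(frozen=True)
class GwasRecord:
    """One disease association row from a summary-statistics download."""

    disease: str
    rsid: str
    p_value: float | None
    odds_ratio: float | None
    is_reported_lead: bool = False

    def __post_init__(self) -> None:
        if self.disease not in DISEASES:
            raise ValueError(f"unknown disease label {self.disease!r}")
        if self.p_value is not None and not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"{self.rsid}: p_value must be in (0, 1], got {self.p_value}")
        if self.odds_ratio is not None and self.odds_ratio <= 0:
            raise ValueError(f"{self.rsid}: odds_ratio must be positive")


@dataclass(frozen=True)
class LdPair:
    """Pairwise linkage disequilibrium between two SNPs (unordered)."""

    rsid_a: str
    rsid_b: str
    r2: float
    dprime: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must be in [0, 1], got {self.r2}")
        if not 0.0 <= self.dprime <= 1.0:
            raise ValueError(f"dprime must be in [0, 1], got {self.dprime}")


@dataclass(frozen=True)
class EqtlRecord:
    """A published cis-eQTL call; direction is the minor-allele effect."""

    rsid: str
    gene: str
    tissue: str
    direction: str
    fdr: float
    source: str

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr must be in [0, 1], got {self.fdr}")
        if self.source not in EQTL_SOURCES:
            raise ValueError(f"unknown eQTL source {self.source!r}")


@dataclass(frozen=True)
class AssociationEvidence:
    """Per-disease GWAS support for a candidate: direct or via an LD proxy."""

    rsid: str
    disease: str
    p_value: float | None = None
    odds_ratio: float | None = None
    support: str = "direct"
    proxy_lead_rsid: str | None = None
    proxy_r2: float | None = None
    proxy_dprime: float | None = None

    def __post_init__(self) -> None:
        # proxy_lead_rsid may be absent even for ld_proxy support: published
        # tables list proxy-supported rows without naming the lead.
        if self.support not in ("direct", "ld_proxy"):
            raise ValueError(f"support must be direct/ld_proxy, got {self.support!r}")
        if self.p_value is not None and not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        for nm in ("proxy_r2", "proxy_dprime"):
            v = getattr(self, nm)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class EqtlAnnotation:
    """Pooled eQTL evidence for one (miRSNP, gene) pair."""

    rsid: str
    gene: str
    has_eqtl: bool
    directions: frozenset[str]
    records: tuple[EqtlRecord, ...] = ()
    concordant: str = "not_applicable"

    def __post_init__(self) -> None:
        if self.has_eqtl != bool(self.records) and self.records is not None:
            # Fixture-derived annotations carry no per-record detail.
            if self.records:
                raise ValueError("records present but has_eqtl is False")
        if not self.directions <= {"up", "down"}:
            raise ValueError(f"directions must be within {{up, down}}, got {self.directions}")
        if self.concordant not in ("yes", "no", "ambiguous", "not_applicable"):
            raise ValueError(f"bad concordance value {self.concordant!r}")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between a miRNA and a target mRNA.

    ``ok`` is False for flagged-undefined results (zero variance or a
    stratum below the minimum size); then r and p are NaN and the result
    never counts as significant.
    """

    mirna: str
    gene: str
    stratum: str
    n: int
    r: float
    p_value: float
    significant: bool
    ok: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if self.stratum not in ("all", "hom_ref", "hom_minor"):
            raise ValueError(f"bad stratum {self.stratum!r}")
        if self.ok:
            if self.n < 3:
                raise ValueError("a computed correlation needs n >= 3")
            if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
                raise ValueError(f"|r| must be <= 1, got {self.r}")
            if not 0.0 < self.p_value <= 1.0:
                raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        elif self.significant:
            raise ValueError("an undefined result cannot be significant")


@dataclass(frozen=True)
class ValidatedInteraction:
    """An experimentally validated miRNA-target interaction."""

    mirna: str
    gene: str
    method: str
    source: str

    def __post_init__(self) -> None:
        if self.source not in VALIDATION_SOURCES:
            raise ValueError(f"unknown validation source {self.source!r}")


class ExpressionMatrix:
    """A sample x feature matrix of log2 expression values.

    Thin wrapper around a pandas DataFrame (index = sample ids, columns =
    feature ids) that enforces unique identifiers and finite values.
    """

    def __init__(self, values: pd.DataFrame, feature_kind: str, already_log2: bool = True):
        if feature_kind not in ("mirna", "mrna"):
            raise ValueError(f"feature_kind must be mirna/mrna, got {feature_kind!r}")
        if values.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if values.columns.duplicated().any():
            raise ValueError("duplicate feature ids")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must all be finite")
        if not already_log2:
            if (arr < 0).any():
                raise ValueError("raw counts must be non-negative for log2(x + 1)")
            values = np.log2(values + 1.0)
        self.values = values
        self.feature_kind = feature_kind

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def vector(self, feature: str, samples: list[str]) -> np.ndarray:
        return self.values.loc[samples, feature].to_numpy(dtype=float)


class GenotypeTable:
    """Minor-allele dosages (0/1/2, NA for missing) per sample and rsid."""

    def __init__(self, dosages: pd.DataFrame):
        if dosages.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if dosages.columns.duplicated().any():
            raise ValueError("duplicate rsids")
        dosages = dosages.astype("Int64")
        bad = ~(dosages.isin([0, 1, 2]) | dosages.isna())
        if bad.to_numpy().any():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        self.dosages = dosages

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def rsids(self) -> list[str]:
        return list(self.dosages.columns)

    def dosage(self, rsid: str, samples: list[str]) -> pd.Series:
        if rsid not in self.dosages.columns:
            raise KeyError(f"rsid {rsid!r} absent from genotype table")
        return self.dosages.loc[samples, rsid]
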