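"""Run configuration: every numeric decision rule of the pipeline in one place."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class Config:
    """Thresholds governing every filtering stage.

    Parameters
    ----------
    nbc_threshold
        Candidates are kept when the naive Bayes combined score S is
        strictly greater than this value.
    gwas_p_threshold
        Genome-wide significance limit; a lead SNP must have P strictly
        below it.
    ld_r2_min
        Minimum r-squared (inclusive) for a SNP to count as an LD proxy of
        a significant lead.
    ld_dprime_required
        D' a proxy pair must attain, compared within ``ld_dprime_tol``.
        Set ``require_dprime`` to False to use r-squared alone.
    min_shared_diseases
        A candidate must be associated (directly or by proxy) with at
        least this many distinct disease labels.
    eqtl_fdr_max
        eQTL records above this FDR are dropped at load time.
    corr_p_threshold
        Two-sided significance limit for Pearson correlation tests.
    min_stratum_size
        Smallest homozygote stratum on which a correlation is computed;
        below it the result is flagged undefined (3 is the minimum for a
        defined t test).
    tool_flip
        Per-tool flag; True means the tool's native raw score decreases
        with evidence strength and is negated before harmonization.
    bh_fdr
        Optional Benjamini-Hochberg correction across correlation tests
        (off by default: the significance rule is a plain per-test P cut).
    """

    nbc_threshold: float = 0.7
    gwas_p_threshold: float = 5e-8
    ld_r2_min: float = 0.8
    ld_dprime_required: float = 1.0
    ld_dprime_tol: float = 1e-6
    require_dprime: bool = True
    min_shared_diseases: int = 2
    eqtl_fdr_max: float = 0.05
    corr_p_threshold: float = 0.05
    min_stratum_size: int = 3
    rng_seed: int = 0
    tool_flip: dict[str, bool] = field(default_factory=dict)
    bh_fdr: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.nbc_threshold <= 1.0:
            raise ValueError(f"nbc_threshold must be in [0, 1], got {self.nbc_threshold}")
        if not 0.0 < self.gwas_p_threshold <= 1.0:
            raise ValueError(f"gwas_p_threshold must be in (0, 1], got {self.gwas_p_threshold}")
        if not 0.0 <= self.ld_r2_min <= 1.0:
            raise ValueError(f"ld_r2_min must be in [0, 1], got {self.ld_r2_min}")
        if not 0.0 <= self.ld_dprime_required <= 1.0:
            raise ValueError(f"ld_dprime_required must be in [0, 1], got {self.ld_dprime_required}")
        if self.min_shared_diseases < 1:
            raise ValueError("min_shared_diseases must be >= 1")
        if not 0.0 <= self.eqtl_fdr_max <= 1.0:
            raise ValueError(f"eqtl_fdr_max must be in [0, 1], got {self.eqtl_fdr_max}")
        if not 0.0 < self.corr_p_threshold <= 1.0:
            raise ValueError(f"corr_p_threshold must be in (0, 1], got {self.corr_p_threshold}")
        if self.min_stratum_size < 3:
            raise ValueError("min_stratum_size must be >= 3 (t test needs n - 2 >= 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
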