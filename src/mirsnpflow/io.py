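"""TSV readers/writers for every pipeline table, plus the packaged reference table.

All tables are tab-delimited UTF-8 with a header row and the literal ``NA``
for missing values. Parsing is row-by-row so malformed input is reported
with its row number and column.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Callable, Iterable, Sequence

import pandas as pd

from .models import (
    AssociationEvidence,
    CombinedCandidate,
    CorrelationResult,
    EqtlAnnotation,
    EqtlRecord,
    ExpressionMatrix,
    GenotypeTable,
    GwasRecord,
    LdPair,
    ToolPrediction,
    ValidatedInteraction,
    Variant,
    EFFECT_CODES,
    EFFECT_TO_CODE,
)

logger = logging.getLogger(__name__)

NA = "NA"

# sha256 of the packaged reference tables; guards against silent edits.
_TABLE2_SHA256 = "039a7ad3e71946c97a7026f8974ec1da69c953f178b458a6f4223c34cc62ff32"
_TABLE2_MIRNAS_SHA256 = "0c0eb8dd2fb8f6ceae5a34d6418c5d96ef699869557cee54bc1c26ef0a3ac25f"


class TableFormatError(ValueError):
    """A table failed to parse; the message names the row and column."""


def _opt_float(text: str) -> float | None:
    return None if text == NA else float(text)


def _req_float(text: str) -> float:
    if text == NA:
        raise ValueError("missing value where a number is required")
    return float(text)


def _opt_str(text: str) -> str | None:
    return None if text == NA else text


def _bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _fmt(value: Any) -> str:
    if value is None:
        return NA
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _effect(text: str) -> str:
    t = text.strip()
    if t in EFFECT_CODES:
        return EFFECT_CODES[t]
    if t == "?":
        return "ambiguous"
    if t in ("create", "disrupt", "ambiguous"):
        return t
    raise ValueError(f"bad effect {text!r} (expected C/D/? or create/disrupt/ambiguous)")


def _variant_from(row: dict[str, str]) -> Variant:
    return Variant(
        rsid=row["rsid"],
        chrom=row["chrom"],
        pos=int(row["pos"]),
        ref_allele=row["ref"],
        minor_allele=row["minor"],
        maf=_req_float(row["maf"]),
    )


@dataclass(frozen=True)
class _Schema:
    columns: tuple[str, ...]
    parse: Callable[[dict[str, str]], Any]
    unparse: Callable[[Any], list[Any]]


SCHEMAS: dict[str, _Schema] = {
    "tool_prediction": _Schema(
        ("tool", "rsid", "chrom", "pos", "ref", "minor", "maf", "gene", "mirna", "raw_score", "effect"),
        lambda r: ToolPrediction(
            tool=r["tool"],
            variant=_variant_from(r),
            mirna=r["mirna"],
            gene=r["gene"],
            raw_score=_req_float(r["raw_score"]),
            effect=_effect(r["effect"]),
        ),
        lambda p: [
            p.tool, p.variant.rsid, p.variant.chrom, p.variant.pos,
            p.variant.ref_allele, p.variant.minor_allele, p.variant.maf,
            p.gene, p.mirna, p.raw_score, p.effect,
        ],
    ),
    "gwas": _Schema(
        ("disease", "rsid", "p_value", "odds_ratio", "is_reported_lead"),
        lambda r: GwasRecord(
            disease=r["disease"],
            rsid=r["rsid"],
            p_value=_opt_float(r["p_value"]),
            odds_ratio=_opt_float(r["odds_ratio"]),
            is_reported_lead=_bool(r["is_reported_lead"]),
        ),
        lambda g: [g.disease, g.rsid, g.p_value, g.odds_ratio, g.is_reported_lead],
    ),
    "ld": _Schema(
        ("rsid_a", "rsid_b", "r2", "dprime"),
        lambda r: LdPair(r["rsid_a"], r["rsid_b"], _req_float(r["r2"]), _req_float(r["dprime"])),
        lambda p: [p.rsid_a, p.rsid_b, p.r2, p.dprime],
    ),
    "eqtl": _Schema(
        ("rsid", "gene", "tissue", "direction", "fdr", "source"),
        lambda r: EqtlRecord(r["rsid"], r["gene"], r["tissue"], r["direction"],
                             _req_float(r["fdr"]), r["source"]),
        lambda e: [e.rsid, e.gene, e.tissue, e.direction, e.fdr, e.source],
    ),
    "validated": _Schema(
        ("mirna", "gene", "method", "source"),
        lambda r: ValidatedInteraction(r["mirna"], r["gene"], r["method"], r["source"]),
        lambda v: [v.mirna, v.gene, v.method, v.source],
    ),
    "association": _Schema(
        ("rsid", "disease", "p_value", "odds_ratio", "support",
         "proxy_lead_rsid", "proxy_r2", "proxy_dprime"),
        lambda r: AssociationEvidence(
            rsid=r["rsid"],
            disease=r["disease"],
            p_value=_opt_float(r["p_value"]),
            odds_ratio=_opt_float(r["odds_ratio"]),
            support=r["support"],
            proxy_lead_rsid=_opt_str(r["proxy_lead_rsid"]),
            proxy_r2=_opt_float(r["proxy_r2"]),
            proxy_dprime=_opt_float(r["proxy_dprime"]),
        ),
        lambda a: [a.rsid, a.disease, a.p_value, a.odds_ratio, a.support,
                   a.proxy_lead_rsid, a.proxy_r2, a.proxy_dprime],
    ),
    "correlation": _Schema(
        ("mirna", "gene", "stratum", "n", "r", "p_value", "significant", "ok", "reason"),
        lambda r: CorrelationResult(
            mirna=r["mirna"], gene=r["gene"], stratum=r["stratum"], n=int(r["n"]),
            r=float("nan") if r["r"] == NA else float(r["r"]),
            p_value=float("nan") if r["p_value"] == NA else float(r["p_value"]),
            significant=_bool(r["significant"]), ok=_bool(r["ok"]), reason=r["reason"],
        ),
        lambda c: [c.mirna, c.gene, c.stratum, c.n,
                   None if c.r != c.r else c.r,
                   None if c.p_value != c.p_value else c.p_value,
                   c.significant, c.ok, c.reason],
    ),
    "candidate": _Schema(
        ("rsid", "chrom", "pos", "ref", "minor", "maf", "gene", "mirna", "effect",
         "nbc_score", "s_polymirts", "s_mirnasnp2", "s_mirsnpscore"),
        lambda r: CombinedCandidate(
            variant=_variant_from(r),
            mirna=r["mirna"],
            gene=r["gene"],
            unit_scores={t: float(r[f"s_{t}"]) for t in ("polymirts", "mirnasnp2", "mirsnpscore")
                         if r[f"s_{t}"] != NA},
            nbc_score=_req_float(r["nbc_score"]),
            effect=_effect(r["effect"]),
        ),
        lambda c: [c.variant.rsid, c.variant.chrom, c.variant.pos, c.variant.ref_allele,
                   c.variant.minor_allele, c.variant.maf, c.gene, c.mirna,
                   EFFECT_TO_CODE[c.effect], c.nbc_score,
                   c.unit_scores.get("polymirts"), c.unit_scores.get("mirnasnp2"),
                   c.unit_scores.get("mirsnpscore")],
    ),
}


def read_table(path: str | Path, schema: str, eqtl_fdr_max: float = 0.05) -> list[Any]:
    """Read a TSV into validated records.

    For the ``eqtl`` schema, records with FDR above ``eqtl_fdr_max`` are
    dropped (the count is logged) so downstream stages only ever see
    FDR-passing evidence.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    sch = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[Any] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}: empty file, expected header {sch.columns}")
        if tuple(header) != sch.columns:
            raise TableFormatError(
                f"{path}: header mismatch for schema {schema!r}: "
                f"got {tuple(header)}, expected {sch.columns}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(sch.columns):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(sch.columns)} fields, got {len(row)}"
                )
            mapping = dict(zip(sch.columns, row))
            try:
                records.append(sch.parse(mapping))
            except (ValueError, KeyError) as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
    if schema == "eqtl":
        kept = [r for r in records if r.fdr <= eqtl_fdr_max]
        dropped = len(records) - len(kept)
        if dropped:
            logger.info("eqtl load: dropped %d of %d records with FDR > %g",
                        dropped, len(records), eqtl_fdr_max)
        records = kept
    return records


def write_table(path: str | Path, records: Iterable[Any], schema: str) -> None:
    """Write records to TSV; ``read_table`` on the result round-trips."""
    sch = SCHEMAS[schema]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(sch.columns)
        for rec in records:
            writer.writerow([_fmt(v) for v in sch.unparse(rec)])


# ---------------------------------------------------------------------------
# Packaged reference table (published miRSNP-AID association table)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table2Fixture:
    """The published association table, one record per printed fact."""

    candidates: tuple[CombinedCandidate, ...]
    associations: tuple[AssociationEvidence, ...]
    eqtl: tuple[EqtlAnnotation, ...]
    variants: dict[str, Variant]
    genes: dict[str, str]
    lead_rsids: frozenset[str]
    lead_pairs: frozenset[tuple[str, str]]


def _fixture_text(name: str, expected_sha: str) -> str:
    ref = resources.files("mirsnpflow.data").joinpath(name)
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"packaged fixture {name} is missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected_sha:
        raise ValueError(f"fixture {name} checksum mismatch: {digest}")
    return raw.decode("utf-8")


def load_table2_fixture() -> Table2Fixture:
    """Load the packaged miRSNP-disease association table.

    Returns one association record per printed (miRSNP, disease) row, one
    combined-candidate record per printed (miRSNP, miRNA) prediction with
    its published combined score, and one pooled eQTL annotation per
    miRSNP. ``NA`` cells are preserved as missing.
    """
    assoc_text = _fixture_text("table2.tsv", _TABLE2_SHA256)
    mirna_text = _fixture_text("table2_mirnas.tsv", _TABLE2_MIRNAS_SHA256)

    import io as _io
    import warnings

    assoc_rows = list(csv.DictReader(_io.StringIO(assoc_text), delimiter="\t"))
    mirna_rows = list(csv.DictReader(_io.StringIO(mirna_text), delimiter="\t"))

    variants: dict[str, Variant] = {}
    genes: dict[str, str] = {}
    associations: list[AssociationEvidence] = []
    eqtl_by_rsid: dict[str, tuple[bool, frozenset[str]]] = {}
    lead_pairs: set[tuple[str, str]] = set()

    with warnings.catch_warnings():
        # Printed MAFs of 0.51/0.53 are stored as given.
        warnings.simplefilter("ignore", UserWarning)
        for row in assoc_rows:
            rsid = row["rsid"]
            if rsid not in variants:
                variants[rsid] = Variant(
                    rsid=rsid, chrom=row["chrom"], pos=int(row["pos"]),
                    ref_allele=row["ref_allele"], minor_allele=row["minor_allele"],
                    maf=float(row["maf"]),
                )
                genes[rsid] = row["gene"]
                dirs = frozenset() if row["eqtl_direction"] == NA else frozenset(
                    row["eqtl_direction"].split("/"))
                eqtl_by_rsid[rsid] = (row["eqtl"] == "Yes", dirs)
            lead = _bool(row["is_reported_lead"])
            if lead:
                lead_pairs.add((rsid, row["disease"]))
            associations.append(AssociationEvidence(
                rsid=rsid,
                disease=row["disease"],
                p_value=_opt_float(row["p_value"]),
                odds_ratio=_opt_float(row["odds_ratio"]),
                support="direct" if lead else "ld_proxy",
            ))

        candidates = tuple(
            CombinedCandidate(
                variant=variants[row["rsid"]],
                mirna=row["mirna"],
                gene=row["gene"],
                unit_scores={},
                nbc_score=float(row["nbc_score"]),
                effect=_effect(row["effect"]),
            )
            for row in mirna_rows
        )

    annotations = tuple(
        EqtlAnnotation(rsid=rsid, gene=genes[rsid], has_eqtl=flag, directions=dirs)
        for rsid, (flag, dirs) in eqtl_by_rsid.items()
    )
    return Table2Fixture(
        candidates=candidates,
        associations=tuple(associations),
        eqtl=annotations,
        variants=variants,
        genes=genes,
        lead_rsids=frozenset(r for r, _ in lead_pairs),
        lead_pairs=frozenset(lead_pairs),
    )


# ---------------------------------------------------------------------------
# Matrix-shaped inputs
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, feature_kind: str,
                           already_log2: bool = True) -> ExpressionMatrix:
    """Read a samples x features TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    if df.isna().to_numpy().any():
        raise TableFormatError(f"{path}: expression matrices may not contain missing values")
    return ExpressionMatrix(df, feature_kind=feature_kind, already_log2=already_log2)


def write_expression_matrix(path: str | Path, matrix: ExpressionMatrix) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="sample_id")


def read_genotype_table(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    return GenotypeTable(df)


def write_genotype_table(path: str | Path, table: GenotypeTable) -> None:
    table.dosages.to_csv(path, sep="\t", index_label="sample_id", na_rep=NA)
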