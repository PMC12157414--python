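"""Reading, validating, aggregating and writing allelic count tables.

Allelic count collections are plain :class:`pandas.DataFrame` objects with a
fixed schema rather than bespoke containers, so they compose with the usual
pandas workflow.

Gene-level schema (one row per (sample, gene)):
    ``sample_id, gene_id, ref_count, alt_count, total_count``

Variant-level schema (phASER-style, one row per heterozygous site):
    ``sample_id, contig, position, variant_id, ref_allele, alt_allele,
    ref_count, alt_count, total_count[, gene_id]``

``total_count`` is always recomputed as ``ref_count + alt_count``; a total
column found in a file is checked against that identity, never trusted.
Variant positions are 1-based (VCF/phASER convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

GENE_COLUMNS = ["sample_id", "gene_id", "ref_count", "alt_count", "total_count"]
VARIANT_COLUMNS = [
    "sample_id",
    "contig",
    "position",
    "variant_id",
    "ref_allele",
    "alt_allele",
    "ref_count",
    "alt_count",
    "total_count",
]

_PHASER_REQUIRED = [
    "contig",
    "position",
    "variantID",
    "refAllele",
    "altAllele",
    "refCount",
    "altCount",
    "totalCount",
]

DIALECTS = ("long", "matrix_pair", "phaser")


@dataclass(frozen=True)
class AggregationReport:
    """Bookkeeping for a variant-to-gene aggregation pass."""

    n_variants_in: int
    n_dropped_unmapped: int
    n_records_out: int


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")


def _coerce_counts(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    """Cast count columns to int64, accepting integral floats like '7.0'.

    Row numbers in error messages are 1-based file rows (header is row 1).
    """
    for col in columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2
            raise ValidationError(f"{path}: non-numeric {col} at row {row}")
        if values.isna().any():
            row = int(values.isna().idxmax()) + 2
            raise ValidationError(f"{path}: missing {col} at row {row}")
        nonintegral = values % 1 != 0
        if nonintegral.any():
            row = int(nonintegral.idxmax()) + 2
            raise ValidationError(f"{path}: non-integral {col} at row {row}")
        negative = values < 0
        if negative.any():
            row = int(negative.idxmax()) + 2
            raise ValidationError(f"{path}: negative {col} at row {row}")
        df[col] = values.astype(np.int64)
    return df


def read_long(path) -> pd.DataFrame:
    """Read a long-format gene-level table: sample_id, gene_id, ref_count, alt_count."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    _require_columns(df, ["sample_id", "gene_id", "ref_count", "alt_count"], path)
    df = _coerce_counts(df.reset_index(drop=True), ["ref_count", "alt_count"], path)
    df["total_count"] = df["ref_count"] + df["alt_count"]
    return df[GENE_COLUMNS]


def read_matrix_pair(ref_path, alt_path) -> pd.DataFrame:
    """Read the genes-by-samples matrix layout (one ref matrix, one alt matrix).

    Missing cells (empty/NA) are absent records, not zeros.  A cell present in
    one matrix but missing in the other is a validation error.
    """
    ref = pd.read_csv(ref_path, sep="\t", index_col=0)
    alt = pd.read_csv(alt_path, sep="\t", index_col=0)
    if not ref.index.equals(alt.index) or not ref.columns.equals(alt.columns):
        # Align on the union so a genuine layout mismatch surfaces as NA below.
        ref, alt = ref.align(alt)
    genes = ref.index.astype(str)
    samples = ref.columns.astype(str)
    df = pd.DataFrame(
        {
            "gene_id": np.repeat(genes, len(samples)),
            "sample_id": np.tile(samples, len(genes)),
            "ref_count": ref.to_numpy().ravel(),
            "alt_count": alt.to_numpy().ravel(),
        }
    )
    half_missing = df["ref_count"].isna() != df["alt_count"].isna()
    if half_missing.any():
        bad = df.loc[half_missing].iloc[0]
        raise ValidationError(
            f"{ref_path}/{alt_path}: cell ({bad.gene_id}, {bad.sample_id}) "
            "present in one matrix but missing in the other"
        )
    df = df.dropna(subset=["ref_count"]).reset_index(drop=True)
    df = _coerce_counts(df, ["ref_count", "alt_count"], ref_path)
    df["sample_id"] = df["sample_id"].astype(str)
    df["gene_id"] = df["gene_id"].astype(str)
    df["total_count"] = df["ref_count"] + df["alt_count"]
    return df[GENE_COLUMNS]


def read_phaser(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a phASER ``allelic_counts.txt``-style variant table.

    phASER writes one file per sample without a sample column; ``sample_id``
    defaults to an in-file ``sample_id`` column if present, else the file stem.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _PHASER_REQUIRED, path)
    df = df.reset_index(drop=True)
    df = _coerce_counts(df, ["refCount", "altCount", "totalCount", "position"], path)
    mismatch = df["totalCount"] != df["refCount"] + df["altCount"]
    if mismatch.any():
        row = int(mismatch.idxmax()) + 2
        raise ValidationError(
            f"{path}: totalCount differs from refCount + altCount at row {row}"
        )
    if (df["position"] < 1).any():
        row = int((df["position"] < 1).idxmax()) + 2
        raise ValidationError(f"{path}: non-positive 1-based position at row {row}")
    if "sample_id" in df.columns:
        sid = df["sample_id"].astype(str)
    else:
        sid = str(sample_id) if sample_id is not None else Path(path).stem
    out = pd.DataFrame(
        {
            "sample_id": sid,
            "contig": df["contig"].astype(str),
            "position": df["position"],
            "variant_id": df["variantID"].astype(str),
            "ref_allele": df["refAllele"].astype(str),
            "alt_allele": df["altAllele"].astype(str),
            "ref_count": df["refCount"],
            "alt_count": df["altCount"],
        }
    )
    out["total_count"] = out["ref_count"] + out["alt_count"]
    return out[VARIANT_COLUMNS]


def read_counts(
    path, dialect: str = "long", *, alt_path=None, sample_id: str | None = None
) -> pd.DataFrame:
    """Dispatch to the reader for ``dialect`` ('long', 'matrix_pair', 'phaser')."""
    if dialect == "long":
        return read_long(path)
    if dialect == "matrix_pair":
        if alt_path is None:
            raise FormatError("matrix_pair dialect needs both a ref and an alt matrix path")
        return read_matrix_pair(path, alt_path)
    if dialect == "phaser":
        return read_phaser(path, sample_id=sample_id)
    raise FormatError(f"unknown dialect '{dialect}' (expected one of {DIALECTS})")


def write_counts(df: pd.DataFrame, path, dialect: str = "long", *, alt_path=None) -> None:
    """Write a count table in the given dialect (inverse of :func:`read_counts`)."""
    if dialect == "long":
        df[["sample_id", "gene_id", "ref_count", "alt_count"]].to_csv(
            path, sep="\t", index=False
        )
    elif dialect == "matrix_pair":
        if alt_path is None:
            raise FormatError("matrix_pair dialect needs both a ref and an alt matrix path")
        ref = df.pivot(index="gene_id", columns="sample_id", values="ref_count")
        alt = df.pivot(index="gene_id", columns="sample_id", values="alt_count")
        ref.to_csv(path, sep="\t")
        alt.to_csv(alt_path, sep="\t")
    elif dialect == "phaser":
        out = pd.DataFrame(
            {
                "contig": df["contig"],
                "position": df["position"],
                "variantID": df["variant_id"],
                "refAllele": df["ref_allele"],
                "altAllele": df["alt_allele"],
                "refCount": df["ref_count"],
                "altCount": df["alt_count"],
                "totalCount": df["ref_count"] + df["alt_count"],
                "sample_id": df["sample_id"],
            }
        )
        out.to_csv(path, sep="\t", index=False)
    else:
        raise FormatError(f"unknown dialect '{dialect}' (expected one of {DIALECTS})")


def load_gene_map(path) -> pd.DataFrame:
    """Load a variant-to-gene map.

    Two layouts are accepted:

    * two-column TSV ``variant_id <tab> gene_id`` (with or without a header);
    * BED-like four-column interval file ``contig start end gene_id`` with
      0-based half-open intervals, used positionally via :func:`assign_genes`.

    Returns a DataFrame with either columns (variant_id, gene_id) or
    (contig, start, end, gene_id).
    """
    probe = pd.read_csv(path, sep="\t", header=None, nrows=5, dtype=str)
    n_cols = probe.shape[1]
    if n_cols == 2:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.iloc[0].tolist() == ["variant_id", "gene_id"]:
            df = df.iloc[1:].reset_index(drop=True)
        df.columns = ["variant_id", "gene_id"]
        return df
    if n_cols == 4:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["contig", "start", "end", "gene_id"],
            dtype={"contig": str, "gene_id": str},
        )
        df = _coerce_counts(df, ["start", "end"], path)
        if (df["end"] < df["start"]).any():
            raise ValidationError(f"{path}: interval with end < start")
        return df
    raise FormatError(f"{path}: gene map must have 2 (id map) or 4 (BED) columns, found {n_cols}")


def assign_genes(variants: pd.DataFrame, gene_map: pd.DataFrame) -> pd.Series:
    """Return a variant_id -> gene_id mapping series for ``variants``.

    For an id map the file is used directly; for a BED-style map each variant
    is assigned to the interval containing position-1 (0-based half-open).
    A variant hitting more than one gene is a validation error.
    """
    if set(gene_map.columns) == {"variant_id", "gene_id"}:
        dup = gene_map.drop_duplicates()["variant_id"].duplicated()
        if dup.any():
            vid = gene_map.drop_duplicates().loc[dup.idxmax(), "variant_id"]
            raise ValidationError(f"variant '{vid}' maps to multiple genes")
        return gene_map.drop_duplicates().set_index("variant_id")["gene_id"]

    assignments: dict[str, str] = {}
    by_contig = {c: g for c, g in gene_map.groupby("contig")}
    uniq = variants.drop_duplicates(subset=["variant_id"])
    for _, v in uniq.iterrows():
        intervals = by_contig.get(v.contig)
        if intervals is None:
            continue
        pos0 = v.position - 1
        hits = intervals.loc[
            (intervals["start"] <= pos0) & (pos0 < intervals["end"]), "gene_id"
        ].unique()
        if len(hits) > 1:
            raise ValidationError(
                f"variant '{v.variant_id}' maps to multiple genes: {sorted(hits)}"
            )
        if len(hits) == 1:
            assignments[v.variant_id] = hits[0]
    return pd.Series(assignments, name="gene_id", dtype=str)


def aggregate_to_gene_level(
    variants: pd.DataFrame,
    variant_to_gene: Mapping[str, str] | pd.Series | pd.DataFrame,
) -> tuple[pd.DataFrame, AggregationReport]:
    """Collapse a variant-level table to one record per (sample, gene).

    For each gene the single most expressed variant (highest total count)
    represents the gene.  Ties break deterministically on ascending
    (contig, position, variant_id).  Unmapped variants are dropped and
    counted in the returned report.
    """
    if isinstance(variant_to_gene, pd.DataFrame):
        variant_to_gene = assign_genes(variants, variant_to_gene)
    mapping = pd.Series(variant_to_gene, dtype=str)
    if mapping.index.duplicated().any():
        vid = mapping.index[mapping.index.duplicated()][0]
        raise ValidationError(f"variant '{vid}' maps to multiple genes")

    n_in = len(variants)
    if n_in == 0:
        empty = pd.DataFrame(columns=GENE_COLUMNS)
        return empty, AggregationReport(0, 0, 0)

    df = variants.copy()
    df["gene_id"] = df["variant_id"].map(mapping)
    dropped = int(df["gene_id"].isna().sum())
    df = df.dropna(subset=["gene_id"])

    df = df.sort_values(
        ["sample_id", "gene_id", "total_count", "contig", "position", "variant_id"],
        ascending=[True, True, False, True, True, True],
        kind="mergesort",
    )
    best = df.groupby(["sample_id", "gene_id"], as_index=False, sort=True).head(1)
    out = best[GENE_COLUMNS].reset_index(drop=True)
    return out, AggregationReport(n_in, dropped, len(out))


def write_results(result, out_prefix) -> tuple[Path, Path]:
    """Write per-sample scores and the cohort summary.

    Emits ``<prefix>.samples.tsv`` (sample_id, n_genes_used, mu_hat, sigma_hat,
    loglik, converged, pass; sorted by sample_id) and ``<prefix>.summary.json``
    with the threshold report.  Returns the two paths.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for fit in sorted(result.fits, key=lambda f: f.sample_id):
        rows.append(
            {
                "sample_id": fit.sample_id,
                "n_genes_used": fit.n_genes_used,
                "mu_hat": repr(float(fit.mu_hat)),
                "sigma_hat": repr(float(fit.sigma_hat)),
                "loglik": repr(float(fit.loglik)),
                "converged": fit.converged,
                "pass": result.flags[fit.sample_id] == "pass",
            }
        )
    table = pd.DataFrame(rows)
    tsv_path = Path(f"{out_prefix}.samples.tsv")
    table.to_csv(tsv_path, sep="\t", index=False)

    summary = {
        "q1": result.q1,
        "median": result.median,
        "q3": result.q3,
        "medcouple": result.medcouple,
        "sigma_t": result.sigma_t,
        "n_samples": len(result.fits),
        "n_pass": sum(1 for v in result.flags.values() if v == "pass"),
        "n_fail": sum(1 for v in result.flags.values() if v == "fail"),
        "n_nonconverged": sum(1 for f in result.fits if not f.converged),
    }
    json_path = Path(f"{out_prefix}.summary.json")
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return tsv_path, json_path


def read_results(tsv_path) -> pd.DataFrame:
    """Read back a per-sample results table written by :func:`write_results`."""
    df = pd.read_csv(
        tsv_path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip"
    )
    for col in ("mu_hat", "sigma_hat", "loglik"):
        df[col] = df[col].astype(float)
    return df
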