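"""Reading, validation and writing of all standard-format inputs and outputs.

Input tables are plain TSV/BED/BEDPE-like/GMT text files.  Each reader returns
a validated :class:`pandas.DataFrame` (or :class:`networkx.Graph` for the
interaction network) with the column names used throughout the package.

Coordinate conventions: BED/BEDPE intervals are 0-based half-open; point
positions (GWAS variants, TSS) are 1-based.  Gene identity is by case-sensitive
symbol; no alias resolution is attempted.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ValidationError",
    "read_variants",
    "read_genes",
    "read_ld",
    "read_hic",
    "read_eqtl",
    "read_network",
    "read_drug_targets",
    "read_gmt",
    "read_inputs",
    "read_rating_matrix",
    "write_results",
    "write_manifest",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A value in an input table violates its documented invariant."""


def _require_columns(df: pd.DataFrame, columns: list[str], path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check(condition: pd.Series, message: str, path: str) -> None:
    if not bool(condition.all()):
        bad = condition.index[~condition][:5].tolist()
        raise ValidationError(f"{path}: {message} (row index {bad})")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t")


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read GWAS summary statistics: variant_id, chromosome, position, pvalue.

    Positions are 1-based; p-values must lie in (0, 1].
    """
    df = _read_tsv(path)
    _require_columns(df, ["variant_id", "chromosome", "position", "pvalue"], str(path))
    df = df.astype({"variant_id": str, "chromosome": str, "position": int, "pvalue": float})
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate variant_id {dup!r}")
    _check(df["position"] >= 1, "position must be >= 1", str(path))
    _check((df["pvalue"] > 0) & (df["pvalue"] <= 1), "pvalue must be in (0,1]", str(path))
    logger.info("read %d variants from %s", len(df), path)
    return df


def read_genes(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation table: gene, chromosome, tss (1-based), strand."""
    df = _read_tsv(path)
    _require_columns(df, ["gene", "chromosome", "tss", "strand"], str(path))
    df = df.astype({"gene": str, "chromosome": str, "tss": int, "strand": str})
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene {dup!r}")
    _check(df["tss"] >= 1, "tss must be >= 1", str(path))
    _check(df["strand"].isin(["+", "-"]), "strand must be + or -", str(path))
    return df


def read_ld(path: str | Path) -> pd.DataFrame:
    """Read LD pairs: variant_a, variant_b, r2 in [0,1]."""
    df = _read_tsv(path)
    _require_columns(df, ["variant_a", "variant_b", "r2"], str(path))
    df = df.astype({"variant_a": str, "variant_b": str, "r2": float})
    _check((df["r2"] >= 0) & (df["r2"] <= 1), "r2 must be in [0,1]", str(path))
    return df


def read_hic(path: str | Path) -> pd.DataFrame:
    """Read promoter-capture Hi-C links (BEDPE-like fragment -> gene).

    Fragment intervals are 0-based half-open; start must be strictly below end.
    """
    df = _read_tsv(path)
    _require_columns(
        df, ["fragment_chrom", "fragment_start", "fragment_end", "gene", "link_score"], str(path)
    )
    df = df.astype(
        {
            "fragment_chrom": str,
            "fragment_start": int,
            "fragment_end": int,
            "gene": str,
            "link_score": float,
        }
    )
    _check(df["fragment_start"] < df["fragment_end"], "fragment start must be < end", str(path))
    _check(df["fragment_start"] >= 0, "fragment start must be >= 0", str(path))
    _check(df["link_score"] >= 0, "link_score must be >= 0", str(path))
    return df


def read_eqtl(path: str | Path) -> pd.DataFrame:
    """Read eQTL links: variant_id, gene, eqtl_pvalue in (0,1]."""
    df = _read_tsv(path)
    _require_columns(df, ["variant_id", "gene", "eqtl_pvalue"], str(path))
    df = df.astype({"variant_id": str, "gene": str, "eqtl_pvalue": float})
    _check(
        (df["eqtl_pvalue"] > 0) & (df["eqtl_pvalue"] <= 1),
        "eqtl_pvalue must be in (0,1]",
        str(path),
    )
    return df


def read_network(path: str | Path) -> nx.Graph:
    """Read an undirected PPI edge list: gene_a, gene_b [, weight].

    Self-loops are dropped (with a logged count); duplicate edges collapse to
    one, keeping the maximum weight.
    """
    df = _read_tsv(path)
    _require_columns(df, ["gene_a", "gene_b"], str(path))
    has_weight = "weight" in df.columns
    if has_weight:
        _check(df["weight"] > 0, "edge weight must be > 0", str(path))
    graph = nx.Graph()
    n_loops = 0
    for row in df.itertuples(index=False):
        a, b = str(row.gene_a), str(row.gene_b)
        if a == b:
            n_loops += 1
            continue
        w = float(row.weight) if has_weight else 1.0
        if graph.has_edge(a, b):
            graph[a][b]["weight"] = max(graph[a][b]["weight"], w)
        else:
            graph.add_edge(a, b, weight=w)
    if n_loops:
        logger.info("dropped %d self-loop(s) from %s", n_loops, path)
    return graph


def read_drug_targets(path: str | Path) -> pd.DataFrame:
    """Read drug-target annotations: gene, drug, max_phase (0-4), mechanism, indication."""
    df = _read_tsv(path)
    _require_columns(df, ["gene", "drug", "max_phase", "mechanism", "indication"], str(path))
    df = df.astype(
        {"gene": str, "drug": str, "max_phase": int, "mechanism": str, "indication": str}
    )
    _check((df["max_phase"] >= 0) & (df["max_phase"] <= 4), "max_phase must be in [0,4]", str(path))
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file into ``{set_name: {genes}}``.

    Each line is ``name<TAB>description<TAB>gene...``; duplicate genes within a
    line are deduplicated, duplicate set names are an error.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    if not sets:
        warnings.warn(f"{path}: GMT file contains no gene sets", stacklevel=2)
    return sets


def read_rating_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x diseases rating matrix (TSV, first column = gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"{path}: rating matrix contains missing entries")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: rating matrix needs >= 2 diseases")
    return df.astype(float)


_READERS = {
    "variants": read_variants,
    "genes": read_genes,
    "ld": read_ld,
    "hic": read_hic,
    "eqtl": read_eqtl,
    "network": read_network,
    "drug_targets": read_drug_targets,
    "gene_sets": read_gmt,
    "ratings": read_rating_matrix,
}


def read_inputs(paths: Mapping[str, str | Path]) -> dict[str, object]:
    """Read every input named in ``paths`` with its format-specific reader.

    Recognised keys: variants, genes, ld, hic, eqtl, network, drug_targets,
    gene_sets, ratings.  Unknown keys raise ``KeyError``.
    """
    out: dict[str, object] = {}
    for key, path in paths.items():
        if key not in _READERS:
            raise KeyError(f"unknown input kind {key!r}; expected one of {sorted(_READERS)}")
        out[key] = _READERS[key](path)
    return out


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: format(v, ".10g"))
    return out


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    manifest: Mapping[str, object] | None = None,
) -> list[Path]:
    """Write each result table as ``<name>.tsv`` under ``out_dir``.

    Floats are serialized to 10 significant digits so a write/read round trip
    is value-preserving at that precision.  If ``manifest`` is given it is
    written alongside as ``manifest.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        _format_frame(table).to_csv(path, sep="\t", index=False)
        written.append(path)
    if manifest is not None:
        written.append(write_manifest(manifest, out_dir / "manifest.yaml"))
    return written


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, for provenance in the run manifest."""
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(manifest: Mapping[str, object], path: str | Path) -> Path:
    """Write the run manifest (seed, parameters, input checksums) as YAML."""
    path = Path(path)
    with open(path, "w") as handle:
        yaml.safe_dump(dict(manifest), handle, sort_keys=True)
    return path
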