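"""Readers and writers for every external artifact.

Conventions: count and result tables are tab-separated; genotype, map
and covariate files comma-separated; lines starting with ``#`` are
comments; trees are newick; configuration is YAML.  Readers validate
aggressively and name the offending row/column in their error messages,
because silent coercion of a malformed genotype or count file is the
most expensive failure mode of this kind of pipeline.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .core import (
    MISSING_GENOTYPE,
    CountTable,
    CovariateTable,
    FormatError,
    GeneticMap,
    GenotypeMatrix,
    TraitMatrix,
)

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_genotypes",
    "read_map",
    "read_covariates",
    "read_tree",
    "write_tree",
    "read_trait_matrix",
    "write_trait_matrix",
    "write_qtl_table",
    "read_qtl_table",
    "read_config",
    "write_config",
]

_QTL_COLUMNS = [
    "qtl_id",
    "trait_id",
    "model",
    "chromosome",
    "left_marker",
    "left_Mb",
    "top_marker",
    "top_Mb",
    "right_marker",
    "right_Mb",
    "lod",
    "significance",
    "effect_het",
    "effect_hom",
    "pct_var_marker",
    "pct_var_sex",
    "pct_var_diet",
]


def _read_table(path, sep):
    return pd.read_csv(path, sep=sep, comment="#", index_col=0)


def read_count_table(
    path: str | Path,
    orientation: str = "asv_rows",
    taxonomy_path: str | Path | None = None,
) -> CountTable:
    """Read a TSV count table in either orientation.

    ``orientation`` declares what the file's *rows* are; the returned
    table is always samples x ASVs.  Non-integer or negative cells are
    format errors that name their coordinates.
    """
    if orientation not in ("asv_rows", "sample_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_table(path, "\t")
    if orientation == "asv_rows":
        raw = raw.T
    arr = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            row = raw.index[bad.to_numpy()][0]
            raise FormatError(
                f"non-integer count at sample {row!r}, ASV {col!r} in {path}"
            )
        if (vals < 0).any():
            row = raw.index[(vals < 0).to_numpy()][0]
            raise FormatError(
                f"negative count at sample {row!r}, ASV {col!r} in {path}"
            )
        arr[:, j] = vals.astype(np.int64)
    taxonomy = None
    if taxonomy_path is not None:
        tx = _read_table(taxonomy_path, "\t")
        taxonomy = {str(a): {c: str(v) for c, v in row.items()} for a, row in tx.iterrows()}
    return CountTable(
        [str(s) for s in raw.index], [str(a) for a in raw.columns], arr, taxonomy
    )


def write_count_table(table: CountTable, path: str | Path, orientation: str = "asv_rows") -> None:
    frame = table.to_frame()
    if orientation == "asv_rows":
        frame = frame.T
        frame.to_csv(path, sep="\t", index_label="asv_id")
    else:
        frame.to_csv(path, sep="\t", index_label="sample_id")


def read_map(path: str | Path) -> GeneticMap:
    """Read a marker map CSV (marker_id, chromosome, cM, Mb)."""
    tab = _read_table(path, ",")
    rename = {c: c.strip() for c in tab.columns}
    tab = tab.rename(columns=rename)
    for col in ("chromosome", "cM", "Mb"):
        if col not in tab.columns:
            raise FormatError(f"map file {path} missing column {col!r}")
    tab["chromosome"] = tab["chromosome"].astype(int)
    tab[["cM", "Mb"]] = tab[["cM", "Mb"]].astype(float)
    tab = tab.sort_values(["chromosome", "cM"], kind="stable")
    return GeneticMap(tab)


def read_genotypes(
    genotype_path: str | Path,
    map_path: str | Path,
    missing_token: str = "NA",
) -> GenotypeMatrix:
    """Read genotypes (CSV, rows = individuals) against a marker map.

    Codes must be 0/1/2 or the missing token; marker columns without a
    map entry are rejected; output markers are sorted by (chromosome, cM).
    """
    map_ = read_map(map_path)
    raw = pd.read_csv(
        genotype_path, comment="#", index_col=0, dtype=str, keep_default_na=False
    )
    unmapped = [c for c in raw.columns if c not in set(map_.marker_ids)]
    if unmapped:
        raise FormatError(
            f"genotype marker {unmapped[0]!r} has no map entry ({genotype_path})"
        )
    # restrict map to present markers, keep map order
    keep = [m for m in map_.marker_ids if m in set(raw.columns)]
    map_ = GeneticMap(map_.table.loc[keep])
    raw = raw[keep]
    arr = np.empty(raw.shape, dtype=np.int8)
    for j, col in enumerate(raw.columns):
        vals = raw[col].astype(str).str.strip()
        missing = vals == missing_token
        ok = vals.isin(("0", "1", "2")) | missing
        if not ok.all():
            row = raw.index[~ok.to_numpy()][0]
            raise FormatError(
                f"invalid genotype code {vals.loc[row]!r} at sample {row!r}, "
                f"marker {col!r} in {genotype_path}"
            )
        arr[:, j] = np.where(missing, MISSING_GENOTYPE, pd.to_numeric(vals.where(~missing, "0")))
    return GenotypeMatrix([str(s) for s in raw.index], arr, map_)


def read_covariates(path: str | Path) -> CovariateTable:
    tab = pd.read_csv(path, comment="#", index_col=0)
    tab.index = tab.index.astype(str)
    return CovariateTable(tab)


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree; edges without lengths get length 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"unparsable newick in {path}: {exc}") from exc
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise FormatError(f"duplicate leaf {dup!r} in {path}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    if tree.length is None:
        tree.length = 0.0
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    buf = _io.StringIO()
    tree.write(buf)
    Path(path).write_text(buf.getvalue())


def read_trait_matrix(path: str | Path) -> TraitMatrix:
    """Read a TraitMatrix TSV written by :func:`write_trait_matrix`."""
    classes = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#class:"):
                _, trait, cls = line.strip().split("\t")
                classes[trait] = cls
    tab = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    tab.index = tab.index.astype(str)
    return TraitMatrix(tab, {t: classes[t] for t in tab.columns})


def write_trait_matrix(traits: TraitMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in traits.trait_ids:
            fh.write(f"#class:\t{t}\t{traits.trait_class[t]}\n")
        traits.values.to_csv(fh, sep="\t", index_label="sample_id")


def write_qtl_table(calls: list, path: str | Path) -> None:
    """Write QTL calls as a TSV with the standard report schema.

    Columns: identifier, trait, model, chromosome, the left/top/right
    markers of the 1.5-LOD support interval with their Mb positions, the
    peak LOD, significance level, allele effects relative to B6/B6, and
    percent-variance partitions.  Numbers round-trip at 6 significant
    digits.
    """
    tested = {"marginal": "marker", "by_diet": "marker:diet", "by_sex": "marker:sex"}
    rows = []
    for c in calls:
        vp = c.variance_components
        term = tested.get(c.model, "marker")
        rows.append(
            {
                "qtl_id": c.qtl_id,
                "trait_id": c.trait_id,
                "model": c.model,
                "chromosome": c.chromosome,
                "left_marker": c.left_marker,
                "left_Mb": _sig6(c.left_Mb),
                "top_marker": c.top_marker,
                "top_Mb": _sig6(c.top_Mb),
                "right_marker": c.right_marker,
                "right_Mb": _sig6(c.right_Mb),
                "lod": _sig6(c.lod_peak),
                "significance": c.significance_level,
                "effect_het": _sig6(c.effect_het),
                "effect_hom": _sig6(c.effect_hom),
                "pct_var_marker": _sig6(vp.get(term, (np.nan, np.nan))[0]),
                "pct_var_sex": _sig6(vp.get("sex", (np.nan, np.nan))[0]),
                "pct_var_diet": _sig6(vp.get("diet", (np.nan, np.nan))[0]),
            }
        )
    pd.DataFrame(rows, columns=_QTL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_qtl_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _sig6(x) -> float:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return np.nan
    if x == 0:
        return 0.0
    return float(f"{x:.6g}")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
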