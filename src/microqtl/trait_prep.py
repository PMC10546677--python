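"""Trait preparation: marker QC, core-microbiota filters, normalization.

Turns raw tables into the TraitMatrix the genome scans consume:

* marker QC masks low-confidence genotype calls and drops monomorphic
  markers;
* the prevalence filter removes ASVs not seen more than ``min_count``
  times in at least ``min_sample_fraction`` of samples (defaults 5 and
  5%);
* the core measurable microbiota (CMM) is the set of ASVs present
  (nonzero post-rarefaction) in at least 20% of individuals;
* CMM abundance columns are quantile normalized across traits so that
  every abundance trait shares one empirical distribution — which is
  what makes a single class-wide permutation threshold meaningful.

Diversity and metabolic traits are never quantile normalized; they
enter the scans untransformed.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .core import (
    MISSING_GENOTYPE,
    ConsistencyError,
    CountTable,
    CovariateTable,
    GeneticMap,
    GenotypeMatrix,
    TraitMatrix,
)

__all__ = [
    "marker_qc",
    "prevalence_filter",
    "define_cmm",
    "quantile_normalize",
    "assemble_traits",
]


def marker_qc(
    g: GenotypeMatrix,
    confidence: np.ndarray | None = None,
    min_confidence: float = 0.7,
) -> tuple[GenotypeMatrix, dict]:
    """Mask low-confidence calls, drop monomorphic markers.

    ``confidence`` is an optional per-call score array (samples x
    markers); calls strictly below ``min_confidence`` are set missing.
    Markers with a single observed genotype state (or none) are removed.
    Returns the cleaned matrix and a report of what changed.
    """
    geno = g.genotypes.copy()
    n_masked = 0
    if confidence is not None:
        confidence = np.asarray(confidence, dtype=float)
        if confidence.shape != geno.shape:
            raise ConsistencyError("confidence array shape does not match genotypes")
        mask = confidence < min_confidence
        n_masked = int(mask.sum())
        geno[mask] = MISSING_GENOTYPE
    keep = []
    removed = []
    for j, marker in enumerate(g.marker_ids):
        observed = set(geno[:, j][geno[:, j] != MISSING_GENOTYPE].tolist())
        if len(observed) >= 2:
            keep.append(j)
        else:
            removed.append(marker)
    new_map = GeneticMap(g.map.table.iloc[keep])
    out = GenotypeMatrix(list(g.sample_ids), geno[:, keep], new_map)
    report = {
        "n_calls_masked": n_masked,
        "removed_markers": removed,
        "n_markers_kept": len(keep),
    }
    return out, report


def prevalence_filter(
    counts: CountTable, min_count: int = 5, min_sample_fraction: float = 0.05
) -> CountTable:
    """Keep ASVs seen more than ``min_count`` times in enough samples.

    An ASV is retained iff the number of samples with count strictly
    greater than ``min_count`` is at least
    ``ceil(min_sample_fraction * n_samples)``.
    """
    if not (0.0 <= min_sample_fraction <= 1.0):
        raise ValueError("min_sample_fraction must be in [0, 1]")
    need = math.ceil(min_sample_fraction * counts.n_samples)
    hits = (counts.counts > min_count).sum(axis=0)
    keep = [a for a, h in zip(counts.asv_ids, hits) if h >= need]
    return counts.select_asvs(keep)


def define_cmm(counts: CountTable, presence_fraction: float = 0.20) -> list[str]:
    """Core measurable microbiota: ASVs present in >= ``presence_fraction``
    of samples (boundary inclusive; presence means a nonzero count)."""
    if not (0.0 < presence_fraction <= 1.0):
        raise ValueError("presence_fraction must be in (0, 1]")
    present = (counts.counts > 0).sum(axis=0)
    cutoff = presence_fraction * counts.n_samples
    return [a for a, p in zip(counts.asv_ids, present) if p + 1e-9 >= cutoff]


def quantile_normalize(traits: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns onto their common reference distribution.

    Classic semantics: sort each column, average across columns at each
    rank to build the reference, then give each observation the
    reference value at its rank.  Ties within a column receive the mean
    of the reference values spanning their rank range.  Missing values
    are excluded from ranking and preserved; columns of unequal
    completeness are aligned to the reference by linear interpolation on
    the rank scale.  Columns with fewer than two non-missing values are
    dropped with a warning.
    """
    if traits.shape[1] < 1 or traits.shape[0] < 2:
        raise ValueError("need at least one column and two rows")
    n = traits.shape[0]
    usable = []
    for col in traits.columns:
        if traits[col].notna().sum() >= 2:
            usable.append(col)
        else:
            warnings.warn(
                f"column {col!r} has < 2 non-missing values; excluded", stacklevel=2
            )
    if not usable:
        raise ValueError("no column with >= 2 non-missing values")

    grid = np.arange(n, dtype=float)  # reference rank positions 0 .. n-1
    ref_stack = np.empty((len(usable), n))
    for i, col in enumerate(usable):
        vals = np.sort(traits[col].dropna().to_numpy(float))
        m = len(vals)
        if m == n:
            ref_stack[i] = vals
        else:
            # stretch the column's sorted values onto the n-point grid
            ref_stack[i] = np.interp(grid / (n - 1), np.arange(m) / (m - 1), vals)
    reference = ref_stack.mean(axis=0)

    out = pd.DataFrame(index=traits.index, columns=usable, dtype=float)
    for col in usable:
        series = traits[col]
        mask = series.notna().to_numpy()
        vals = series.to_numpy(float)[mask]
        m = len(vals)
        order = np.argsort(vals, kind="stable")
        # reference value at each within-column rank, on the n-point grid
        rank_pos = np.arange(m) / (m - 1) * (n - 1) if m > 1 else np.array([0.0])
        ref_at_rank = np.interp(rank_pos, grid, reference)
        assigned = np.empty(m)
        sorted_vals = vals[order]
        i = 0
        while i < m:
            j = i
            while j + 1 < m and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            assigned[i : j + 1] = ref_at_rank[i : j + 1].mean()
            i = j + 1
        col_out = np.full(len(series), np.nan)
        unsorted = np.empty(m)
        unsorted[order] = assigned
        col_out[mask] = unsorted
        out[col] = col_out
    return out


def assemble_traits(
    normalized_abundances: pd.DataFrame | None,
    diversity_traits: pd.DataFrame | None = None,
    metabolic_traits: pd.DataFrame | None = None,
    genotypes: GenotypeMatrix | None = None,
    covariates: CovariateTable | None = None,
) -> TraitMatrix:
    """Merge trait blocks into one class-labelled matrix.

    The result is restricted to samples present in every provided block
    (and in the genotype/covariate tables when given), preserving
    genotype sample order.  Zero overlapping samples is an error.
    """
    blocks = []
    classes: dict[str, str] = {}
    for frame, cls in (
        (normalized_abundances, "asv_abundance"),
        (diversity_traits, "diversity"),
        (metabolic_traits, "metabolic"),
    ):
        if frame is not None and frame.shape[1] > 0:
            blocks.append(frame)
            for t in frame.columns:
                if t in classes:
                    raise ConsistencyError(f"duplicate trait id {t!r} across blocks")
                classes[t] = cls
    if not blocks:
        raise ValueError("no trait columns provided")

    common = set(blocks[0].index)
    for b in blocks[1:]:
        common &= set(b.index)
    if genotypes is not None:
        common &= set(genotypes.sample_ids)
    if covariates is not None:
        common &= set(covariates.sample_ids)
    if not common:
        raise ConsistencyError("no overlapping samples across trait blocks")
    if genotypes is not None:
        order = [s for s in genotypes.sample_ids if s in common]
    else:
        order = [s for s in blocks[0].index if s in common]
    merged = pd.concat([b.loc[order] for b in blocks], axis=1)
    merged.index.name = "sample_id"
    return TraitMatrix(merged, classes)
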