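"""Rarefaction, alpha/beta diversity and PCoA trait construction.

The trait-construction stage of the pipeline: rarefy the raw ASV table
to a fixed depth, compute Shannon diversity (log base 2, the QIIME2
convention) and observed species per sample, build the four
beta-diversity distance matrices (Bray-Curtis, Jaccard, unweighted and
weighted UniFrac), ordinate each by principal coordinate analysis, and
extract the leading PCo axes as quantitative traits for linkage
analysis.

The pairwise distances themselves are delegated to scikit-bio; this
module pins the conventions around them (zero-zero pair handling, the
non-normalized default for weighted UniFrac, PCoA axis-sign fixing) and
validates count/tree consistency up front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity import beta_diversity

from .core import ConfigError, ConsistencyError, CountTable, MicroQtlError

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "rarefy",
    "shannon",
    "observed_species",
    "alpha_diversity_table",
    "bray_curtis",
    "jaccard",
    "unweighted_unifrac",
    "weighted_unifrac",
    "pcoa",
    "eigenvector_traits",
]

BETA_METRICS = ("bray_curtis", "jaccard", "unweighted_unifrac", "weighted_unifrac")


class UndefinedSampleError(MicroQtlError):
    """A sample with no counts where the metric requires abundances."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances for one beta-diversity metric."""

    sample_ids: list[str]
    D: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        n = len(self.sample_ids)
        if D.shape != (n, n):
            raise ConsistencyError("distance matrix shape does not match ids")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ConsistencyError("distance matrix not symmetric")
        if np.any(np.diag(D) != 0):
            raise ConsistencyError("nonzero diagonal in distance matrix")
        if (D < -1e-12).any():
            raise ConsistencyError("negative distances")
        self.D = D

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix.

    ``eigenvalues`` contains the full spectrum (negative values retained
    for inspection); coordinates and ``proportion_explained`` cover the
    positive axes only.
    """

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x positive axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all, sorted descending
    proportion_explained: np.ndarray  # per positive axis

    def axis(self, k: int) -> np.ndarray:
        """1-based axis accessor (PCo1 = axis(1))."""
        if not (1 <= k <= self.coordinates.shape[1]):
            raise ConfigError(f"PCo{k} not available ({self.coordinates.shape[1]} axes)")
        return self.coordinates[:, k - 1]


def rarefy(table: CountTable, depth: int, seed: int = 0) -> tuple[CountTable, list[str]]:
    """Single rarefaction: subsample each sample to exactly ``depth``.

    Sampling is without replacement (multivariate hypergeometric).
    Samples whose total is below the depth are dropped; the list of
    dropped sample ids is returned alongside the rarefied table.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.any():
        raise MicroQtlError(f"no sample reaches rarefaction depth {depth}")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    rng = np.random.default_rng(seed)
    rows = []
    for i in np.flatnonzero(keep):
        rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
    out = CountTable(
        [s for s, k in zip(table.sample_ids, keep) if k],
        list(table.asv_ids),
        np.asarray(rows, dtype=np.int64),
        table.taxonomy,
    )
    return out, dropped


def shannon(counts: np.ndarray, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log(p_i), base-2 by default (bits)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise UndefinedSampleError("Shannon diversity undefined for an all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def observed_species(counts: np.ndarray) -> int:
    """Number of taxa with a positive count."""
    return int(np.count_nonzero(np.asarray(counts) > 0))


def alpha_diversity_table(table: CountTable) -> pd.DataFrame:
    """Per-sample Shannon (bits) and observed-species columns."""
    return pd.DataFrame(
        {
            "shannon": [shannon(row) for row in table.counts],
            "observed_species": [observed_species(row) for row in table.counts],
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def _zero_pairs_to_zero(D: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Convention: a pair of all-zero samples is at distance 0."""
    empty = totals == 0
    if empty.any():
        ij = np.ix_(empty, empty)
        D[ij] = 0.0
        np.fill_diagonal(D, 0.0)
    return D


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) per sample pair."""
    _require_pairs(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dm = beta_diversity("braycurtis", table.counts, ids=table.sample_ids)
    D = np.nan_to_num(dm.data, nan=0.0)
    D = _zero_pairs_to_zero(D, table.sample_totals())
    return DistanceMatrix(list(table.sample_ids), D, "bray_curtis")


def jaccard(table: CountTable) -> DistanceMatrix:
    """Binary Jaccard distance 1 - |shared| / |union| on presence."""
    _require_pairs(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dm = beta_diversity("jaccard", table.counts > 0, ids=table.sample_ids)
    D = np.nan_to_num(dm.data, nan=0.0)
    D = _zero_pairs_to_zero(D, table.sample_totals())
    return DistanceMatrix(list(table.sample_ids), D, "jaccard")


def _require_pairs(table: CountTable) -> None:
    if table.n_samples < 2:
        raise ValueError("beta diversity requires at least 2 samples")


def _check_tree_coverage(table: CountTable, tree: TreeNode) -> None:
    leaves = {t.name for t in tree.tips()}
    present = np.asarray(table.counts).sum(axis=0) > 0
    missing = [a for a, p in zip(table.asv_ids, present) if p and a not in leaves]
    if missing:
        raise ConsistencyError(
            f"ASVs with counts absent from the tree: {missing[:3]}"
        )


def unweighted_unifrac(table: CountTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: unique branch length / observed branch length.

    Branches leading to taxa present in exactly one of the two samples
    count as unique; branches ancestral to neither sample are excluded
    from both sums.
    """
    _require_pairs(table)
    _check_tree_coverage(table, tree)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dm = beta_diversity(
            "unweighted_unifrac",
            table.counts,
            ids=table.sample_ids,
            taxa=table.asv_ids,
            tree=tree,
        )
    D = np.nan_to_num(dm.data, nan=0.0)
    D = _zero_pairs_to_zero(D, table.sample_totals())
    return DistanceMatrix(list(table.sample_ids), D, "unweighted_unifrac")


def weighted_unifrac(
    table: CountTable, tree: TreeNode, normalized: bool = False
) -> DistanceMatrix:
    """Weighted UniFrac sum_b l_b |A_b - B_b| over branch proportions.

    ``A_b``/``B_b`` are the fractions of each sample's counts descending
    from branch b.  Non-normalized by default (the plain QIIME2 metric);
    with ``normalized`` the sum is divided by sum_b l_b (A_b + B_b).
    """
    _require_pairs(table)
    _check_tree_coverage(table, tree)
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = table.sample_ids[int(np.flatnonzero(totals == 0)[0])]
        raise UndefinedSampleError(
            f"weighted UniFrac undefined for zero-total sample {bad!r}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dm = beta_diversity(
            "weighted_unifrac",
            table.counts,
            ids=table.sample_ids,
            taxa=table.asv_ids,
            tree=tree,
            normalized=normalized,
        )
    name = "weighted_unifrac_normalized" if normalized else "weighted_unifrac"
    return DistanceMatrix(list(table.sample_ids), dm.data.copy(), name)


def pcoa(D: DistanceMatrix, n_axes: int | None = None, tol: float = 1e-10) -> PcoaResult:
    """Classical PCoA by Gower double-centering and eigendecomposition.

    B = -1/2 J D^2 J with J = I - 11'/n; coordinates are eigenvectors
    scaled by sqrt(eigenvalue) for eigenvalues above ``tol`` times the
    spectral magnitude.  Negative eigenvalues are retained in the
    reported spectrum but excluded from coordinates and from the
    proportion-explained denominator.  Axis signs are fixed by forcing
    each axis's largest-magnitude loading positive.
    """
    n = len(D.sample_ids)
    d2 = D.D**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), abs(eigval[-1]), 1.0)
    positive = eigval > tol * scale
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    # sign convention for reproducibility
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigval[positive].sum()
    prop = eigval[positive] / pos_sum if pos_sum > 0 else eigval[positive]
    if n_axes is not None:
        if n_axes > coords.shape[1]:
            warnings.warn(
                f"requested {n_axes} axes but only {coords.shape[1]} positive; truncating",
                stacklevel=2,
            )
        coords = coords[:, :n_axes]
    return PcoaResult(list(D.sample_ids), coords, eigval, prop)


def eigenvector_traits(
    pcoa_results: dict[str, PcoaResult],
    axes: list[int],
    alpha_traits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble PCo-axis trait columns, one per (metric, axis).

    Columns are named ``<metric>_PCo<k>``; alpha-diversity columns
    (shannon, observed_species) are appended when provided.  Requesting
    an axis beyond a result's positive spectrum is a configuration
    error.
    """
    cols = {}
    index = None
    for metric, res in pcoa_results.items():
        if index is None:
            index = pd.Index(res.sample_ids, name="sample_id")
        elif list(index) != list(res.sample_ids):
            raise ConsistencyError("PCoA results cover different sample sets")
        for k in axes:
            cols[f"{metric}_PCo{k}"] = res.axis(k)
    out = pd.DataFrame(cols, index=index)
    if alpha_traits is not None:
        if index is not None and not alpha_traits.index.equals(out.index):
            alpha_traits = alpha_traits.loc[out.index]
        out = pd.concat([out, alpha_traits], axis=1)
    return out
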