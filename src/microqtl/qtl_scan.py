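"""Genome-scan engine: nested-model LOD scans, thresholds, QTL calls.

Three nested linear models are scanned at every marker, with the
genotype entered as an unordered two-degree-of-freedom factor
(heterozygote and homozygote indicators relative to B6/B6), so both
additive and dominance effects are captured:

* ``marginal``  — null: y ~ sex + diet + sex:diet; alt adds marker.
* ``by_diet``   — null: y ~ sex + diet + marker;   alt adds marker:diet.
* ``by_sex``    — null: y ~ sex + diet + marker;   alt adds marker:sex.

The statistic is the marker-regression LOD,

    LOD = (n/2) * log10(RSS_null / RSS_alt),

clamped at zero.  Genome-wide significance is calibrated by permuting
the trait vector across individuals (covariates and genotypes fixed),
recording the genome-wide maximum LOD per permutation, and taking
empirical quantiles; the thresholds applied to a trait class are the
average of the per-trait thresholds in that class.  Because
quantile-normalized abundance traits share one empirical distribution,
their permutation null depends only on that shared multiset of values
and a single permutation batch serves the whole class (the shared-null
shortcut, exact for complete tie-free columns and applied whenever
columns share identical sorted values).

Peaks above the 5% threshold are called (at most one per chromosome per
trait per model), support intervals are the 1.5-LOD drop around the
peak, allele effects are reported relative to B6/B6 (within the
American or male stratum for the interaction models), and the variance
partition is a sequential (type-I) ANOVA with a fixed term order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    MISSING_GENOTYPE,
    ConfigError,
    CovariateTable,
    GenotypeMatrix,
    TraitMatrix,
)

__all__ = [
    "MODELS",
    "ScanResult",
    "Thresholds",
    "Peak",
    "QtlCall",
    "AlleleEffects",
    "lod_at_marker",
    "genome_scan",
    "scan_lod_matrix",
    "permutation_thresholds",
    "call_peaks",
    "support_interval",
    "allele_effects",
    "variance_partition",
    "call_qtl",
    "overlap_qtl",
]

MODELS = ("marginal", "by_diet", "by_sex")

_BASIS_TOL = 1e-9


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _covariate_columns(covariates: CovariateTable) -> tuple[np.ndarray, np.ndarray]:
    return covariates.male_indicator(), covariates.keto_indicator()


def _marker_dummies(g: np.ndarray) -> np.ndarray:
    """Two-df factor coding: indicators for het (1) and hom FVB (2)."""
    return np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])


def _model_blocks(model: str, male: np.ndarray, keto: np.ndarray, g: np.ndarray):
    """Ordered (term, columns) blocks of the alternative model.

    The null model is everything except the last block.  Term order is
    also the sequential-ANOVA order.
    """
    n = len(male)
    one = np.ones((n, 1))
    gd = _marker_dummies(g)
    if model == "marginal":
        blocks = [
            ("intercept", one),
            ("sex", male[:, None]),
            ("diet", keto[:, None]),
            ("sex:diet", (male * keto)[:, None]),
            ("marker", gd),
        ]
    elif model == "by_diet":
        blocks = [
            ("intercept", one),
            ("sex", male[:, None]),
            ("diet", keto[:, None]),
            ("marker", gd),
            ("marker:diet", gd * keto[:, None]),
        ]
    elif model == "by_sex":
        blocks = [
            ("intercept", one),
            ("sex", male[:, None]),
            ("diet", keto[:, None]),
            ("marker", gd),
            ("marker:sex", gd * male[:, None]),
        ]
    else:
        raise ConfigError(f"unknown scan model {model!r}")
    return blocks


def _ortho_basis(X: np.ndarray, tol: float = _BASIS_TOL) -> np.ndarray:
    """Orthonormal basis of col(X) with rank detection (SVD)."""
    if X.size == 0:
        return np.empty((X.shape[0], 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > tol * max(1.0, s[0] if len(s) else 0.0) * np.sqrt(X.shape[0])
    return U[:, keep]


def _extend_basis(Q: np.ndarray, Z: np.ndarray, tol: float = _BASIS_TOL) -> np.ndarray:
    """Orthonormal basis of the part of col(Z) orthogonal to col(Q)."""
    R = Z - Q @ (Q.T @ Z)
    R = R - Q @ (Q.T @ R)  # second pass for numerical safety
    return _ortho_basis(R, tol)


def _rss_reduction(Qextra: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Sum-of-squares explained by extra orthonormal directions, per column."""
    if Qextra.shape[1] == 0:
        return np.zeros(Y.shape[1])
    P = Qextra.T @ Y
    return np.einsum("ij,ij->j", P, P)


def _lod_from_rss(rss0: np.ndarray, rss1: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rss1 > 0, rss0 / np.maximum(rss1, 1e-300), np.inf)
        lod = (n / 2.0) * np.log10(np.maximum(ratio, 1.0))
    return np.where(np.isfinite(lod), lod, np.inf)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-marker LOD curve for one trait under one model."""

    trait_id: str
    model: str
    marker_ids: list[str]
    chromosome: np.ndarray
    position_cM: np.ndarray
    position_Mb: np.ndarray
    lod: np.ndarray
    n_used: np.ndarray
    rss_null: np.ndarray
    rss_alt: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chromosome": self.chromosome,
                "cM": self.position_cM,
                "Mb": self.position_Mb,
                "lod": self.lod,
                "n_used": self.n_used,
            }
        )

    def max_lod(self) -> float:
        finite = self.lod[np.isfinite(self.lod)]
        return float(finite.max()) if len(finite) else float("nan")


@dataclass
class Thresholds:
    """Permutation-derived genome-wide LOD thresholds for a trait class."""

    trait_class: str
    model: str
    n_perm: int
    alphas: tuple[float, ...]
    class_thresholds: dict[float, float]
    per_trait: dict[str, dict[float, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        alphas = sorted(self.alphas)
        for lo, hi in zip(alphas, alphas[1:]):
            if self.class_thresholds[lo] < self.class_thresholds[hi] - 1e-12:
                raise ConfigError("thresholds must decrease with alpha")

    def lod_cutoff(self, alpha: float) -> float:
        return self.class_thresholds[alpha]


@dataclass
class Peak:
    trait_id: str
    model: str
    chromosome: int
    marker_index: int
    marker_id: str
    lod: float
    significance_level: float


@dataclass
class AlleleEffects:
    """Genotype-class effects relative to B6/B6 (trait units).

    For interaction models the effects are within the reference stratum
    (American diet for ``by_diet``, males for ``by_sex``).
    """

    effect_het: float
    effect_hom: float
    se_het: float
    se_hom: float
    stratum: str | None = None


@dataclass
class QtlCall:
    qtl_id: str
    trait_id: str
    model: str
    chromosome: int
    top_marker: str
    top_Mb: float
    left_marker: str
    left_Mb: float
    right_marker: str
    right_Mb: float
    lod_peak: float
    significance_level: float
    effect_het: float
    effect_hom: float
    variance_components: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_used: int = 0

    def interval(self) -> tuple[float, float]:
        return (self.left_Mb, self.right_Mb)


# ---------------------------------------------------------------------------
# LOD computation
# ---------------------------------------------------------------------------

def lod_at_marker(
    y: np.ndarray,
    covariates: CovariateTable,
    g: np.ndarray,
    model: str,
) -> tuple[float, float, float, int]:
    """LOD for one trait at one marker: (lod, rss_null, rss_alt, n_used).

    Rows with missing trait value or missing genotype are deleted.  A
    marker with too few usable rows (n_used <= alt-model columns) is
    skipped with LOD = nan.  Rank-deficient designs (e.g. an absent
    genotype class) are fit on the reduced column space.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    male, keto = _covariate_columns(covariates)
    mask = np.isfinite(y) & (g != MISSING_GENOTYPE)
    ym, gm = y[mask], g[mask]
    blocks = _model_blocks(model, male[mask], keto[mask], gm)
    n_used = int(mask.sum())
    p_alt = sum(b.shape[1] for _, b in blocks)
    if n_used <= p_alt:
        return float("nan"), float("nan"), float("nan"), n_used
    X0 = np.hstack([b for _, b in blocks[:-1]])
    Q0 = _ortho_basis(X0)
    Qa = _extend_basis(Q0, blocks[-1][1])
    yc = ym[:, None]
    tss = float(np.sum(ym**2))
    rss0 = tss - float(_rss_reduction(Q0, yc)[0])
    rss1 = rss0 - float(_rss_reduction(Qa, yc)[0])
    lod = float(_lod_from_rss(np.array([rss0]), np.array([rss1]), n_used)[0])
    return max(lod, 0.0), rss0, rss1, n_used


def genome_scan(
    trait: pd.Series | np.ndarray,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    model: str = "marginal",
    trait_id: str | None = None,
) -> ScanResult:
    """Scan one trait at every marker of the map."""
    if isinstance(trait, pd.Series):
        trait_id = trait_id or str(trait.name)
        y = trait.reindex(genotypes.sample_ids).to_numpy(float)
    else:
        y = np.asarray(trait, dtype=float)
        trait_id = trait_id or "trait"
    if len(y) != genotypes.n_samples:
        raise ConfigError("trait length does not match genotype samples")
    _check_alignment(genotypes, covariates)

    obs = np.isfinite(y)
    complete_geno = not (genotypes.genotypes[obs] == MISSING_GENOTYPE).any()
    m = genotypes.map.n_markers
    tab = genotypes.map.table
    if complete_geno:
        sub_cov = covariates.select_samples(
            [s for s, o in zip(genotypes.sample_ids, obs) if o]
        )
        lod, rss0, rss1, n_used = _scan_complete(
            y[obs, None], genotypes.genotypes[obs], sub_cov, model
        )
        lod, rss0, rss1 = lod[:, 0], rss0[:, 0], rss1[:, 0]
    else:
        lod = np.empty(m)
        rss0 = np.empty(m)
        rss1 = np.empty(m)
        n_used = np.empty(m, dtype=int)
        for j in range(m):
            lod[j], rss0[j], rss1[j], n_used[j] = lod_at_marker(
                y, covariates, genotypes.genotypes[:, j], model
            )
    return ScanResult(
        trait_id=trait_id,
        model=model,
        marker_ids=list(tab.index),
        chromosome=tab["chromosome"].to_numpy(),
        position_cM=tab["cM"].to_numpy(float),
        position_Mb=tab["Mb"].to_numpy(float),
        lod=np.maximum(lod, 0.0),
        n_used=np.broadcast_to(np.asarray(n_used), (m,)).copy()
        if np.ndim(n_used)
        else np.full(m, n_used),
        rss_null=rss0,
        rss_alt=rss1,
    )


def _check_alignment(genotypes: GenotypeMatrix, covariates: CovariateTable) -> None:
    if list(genotypes.sample_ids) != list(covariates.sample_ids):
        raise ConfigError("genotype and covariate sample ids must align")


def _scan_complete(
    Y: np.ndarray,
    geno: np.ndarray,
    covariates: CovariateTable,
    model: str,
):
    """Vectorized scan of complete-data trait columns.

    Y is samples x k (no missing); geno has no missing codes.  Returns
    (lod, rss_null, rss_alt) each markers x k, and n_used.
    """
    n, k = Y.shape
    m = geno.shape[1]
    male, keto = _covariate_columns(covariates)
    one = np.ones((n, 1))
    if model == "marginal":
        Qc = _ortho_basis(np.column_stack([one, male, keto, male * keto]))
    else:
        Qc = _ortho_basis(np.column_stack([one, male, keto]))
    tss = np.einsum("ij,ij->j", Y, Y)
    rss_c = tss - _rss_reduction(Qc, Y)
    stratum = keto if model == "by_diet" else male

    lod = np.empty((m, k))
    rss0 = np.empty((m, k))
    rss1 = np.empty((m, k))
    for j in range(m):
        gd = _marker_dummies(geno[:, j])
        Qg = _extend_basis(Qc, gd)
        red_g = _rss_reduction(Qg, Y)
        if model == "marginal":
            r0 = rss_c
            r1 = rss_c - red_g
        else:
            r0 = rss_c - red_g
            Qi = _extend_basis(np.hstack([Qc, Qg]), gd * stratum[:, None])
            r1 = r0 - _rss_reduction(Qi, Y)
        rss0[j] = r0
        rss1[j] = np.maximum(r1, 0.0)
        lod[j] = _lod_from_rss(r0, rss1[j], n)
    return np.maximum(lod, 0.0), rss0, rss1, n


def scan_lod_matrix(
    Y: pd.DataFrame | np.ndarray,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    model: str = "marginal",
) -> np.ndarray:
    """LOD matrix (markers x traits) for complete trait columns.

    A fast path for permutation work and multi-trait scans; requires
    complete (non-missing) trait values and genotypes.
    """
    _check_alignment(genotypes, covariates)
    Ym = np.asarray(Y, dtype=float)
    if not np.isfinite(Ym).all():
        raise ConfigError("scan_lod_matrix requires complete trait columns")
    if (genotypes.genotypes == MISSING_GENOTYPE).any():
        raise ConfigError("scan_lod_matrix requires complete genotypes")
    lod, _, _, _ = _scan_complete(Ym, genotypes.genotypes, covariates, model)
    return lod


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------

def permutation_thresholds(
    traits: TraitMatrix,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    model: str = "marginal",
    n_perm: int = 1000,
    alphas: tuple[float, ...] = (0.05, 0.01),
    seed: int = 0,
    trait_class: str | None = None,
    stratify_by: str | None = None,
    batch: int = 256,
) -> Thresholds:
    """Genome-wide LOD thresholds by trait permutation.

    For each trait the trait values are shuffled across individuals
    (optionally within diet or sex strata via ``stratify_by``), the
    genome is rescanned, and the per-permutation maximum LOD recorded;
    the per-trait threshold is the empirical (1 - alpha) quantile of
    those maxima, and the class threshold is the mean over traits.

    Traits whose complete columns share identical sorted values (as
    quantile-normalized columns do) share one permutation batch — their
    null distribution depends only on that common multiset.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if any(not (0 < a < 1) for a in alphas):
        raise ValueError("alphas must lie in (0, 1)")
    _check_alignment(genotypes, covariates)
    rng = np.random.default_rng(seed)

    # group traits that provably share a permutation null
    groups: dict[bytes, list[str]] = {}
    for t in traits.trait_ids:
        col = traits.values[t].reindex(genotypes.sample_ids).to_numpy(float)
        if np.isfinite(col).all():
            key = np.round(np.sort(col), 12).tobytes()
        else:
            key = f"__solo__{t}".encode()
        groups.setdefault(key, []).append(t)

    strata = _permutation_strata(covariates, stratify_by)
    per_trait: dict[str, dict[float, float]] = {}
    for members in groups.values():
        rep = traits.values[members[0]].reindex(genotypes.sample_ids).to_numpy(float)
        maxima = _null_max_lods(
            rep, genotypes, covariates, model, n_perm, rng, strata, batch
        )
        thr = {a: float(np.quantile(maxima, 1.0 - a)) for a in alphas}
        for t in members:
            per_trait[t] = dict(thr)

    class_thr = {
        a: float(np.mean([per_trait[t][a] for t in traits.trait_ids])) for a in alphas
    }
    return Thresholds(
        trait_class=trait_class or "all",
        model=model,
        n_perm=n_perm,
        alphas=tuple(alphas),
        class_thresholds=class_thr,
        per_trait=per_trait,
        seed=seed,
    )


def _permutation_strata(covariates, stratify_by):
    if stratify_by is None:
        return None
    if stratify_by == "diet":
        return covariates.keto_indicator().astype(int)
    if stratify_by == "sex":
        return covariates.male_indicator().astype(int)
    raise ConfigError(f"unknown stratification {stratify_by!r}")


def _null_max_lods(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    model: str,
    n_perm: int,
    rng: np.random.Generator,
    strata: np.ndarray | None,
    batch: int,
) -> np.ndarray:
    """Genome-wide max LOD of n_perm trait permutations."""
    obs = np.isfinite(y)
    yv = y[obs]
    sub_ids = [s for s, o in zip(genotypes.sample_ids, obs) if o]
    geno = genotypes.genotypes[obs]
    cov = covariates.select_samples(sub_ids)
    strat = strata[obs] if strata is not None else None
    n = len(yv)
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        Y = np.empty((n, b))
        for c in range(b):
            if strat is None:
                Y[:, c] = yv[rng.permutation(n)]
            else:
                perm = np.arange(n)
                for s in np.unique(strat):
                    idx = np.flatnonzero(strat == s)
                    perm[idx] = idx[rng.permutation(len(idx))]
                Y[:, c] = yv[perm]
        lod, _, _, _ = _scan_complete(Y, geno, cov, model)
        maxima[done : done + b] = lod.max(axis=0)
        done += b
    return maxima


# ---------------------------------------------------------------------------
# peak calling, intervals, effects
# ---------------------------------------------------------------------------

def call_peaks(scan: ScanResult, thresholds: Thresholds) -> list[Peak]:
    """Call at most one peak per chromosome above the 5% class threshold."""
    if thresholds.model != scan.model:
        raise ConfigError(
            f"thresholds for model {thresholds.model!r} applied to {scan.model!r} scan"
        )
    alphas = sorted(thresholds.alphas, reverse=True)  # e.g. 0.05 then 0.01
    cut = thresholds.lod_cutoff(alphas[0])
    peaks = []
    for chrom in pd.unique(scan.chromosome):
        on = np.flatnonzero(scan.chromosome == chrom)
        lods = np.where(np.isfinite(scan.lod[on]), scan.lod[on], -np.inf)
        j = on[int(np.argmax(lods))]
        if not np.isfinite(scan.lod[j]) or scan.lod[j] <= cut:
            continue
        sig = alphas[0]
        for a in alphas[1:]:
            if scan.lod[j] > thresholds.lod_cutoff(a):
                sig = a
        peaks.append(
            Peak(
                trait_id=scan.trait_id,
                model=scan.model,
                chromosome=int(chrom),
                marker_index=int(j),
                marker_id=scan.marker_ids[j],
                lod=float(scan.lod[j]),
                significance_level=sig,
            )
        )
    return peaks


def support_interval(scan: ScanResult, peak: Peak, drop: float = 1.5) -> tuple[str, str]:
    """1.5-LOD support interval: walk outward to the first markers whose
    LOD falls below (peak - drop); those flanking markers are included.
    The chromosome end caps the interval."""
    on = np.flatnonzero(scan.chromosome == peak.chromosome)
    pos = int(np.flatnonzero(on == peak.marker_index)[0])
    cut = peak.lod - drop
    left = pos
    while left > 0:
        left -= 1
        lj = scan.lod[on[left]]
        if np.isfinite(lj) and lj < cut:
            break
    right = pos
    while right < len(on) - 1:
        right += 1
        lj = scan.lod[on[right]]
        if np.isfinite(lj) and lj < cut:
            break
    return scan.marker_ids[on[left]], scan.marker_ids[on[right]]


def allele_effects(
    y: np.ndarray | pd.Series,
    covariates: CovariateTable,
    g: np.ndarray,
    model: str = "marginal",
) -> AlleleEffects:
    """Genotype-class effects at the top marker, relative to B6/B6.

    marginal: coefficients of the het/hom indicators in the alternative
    fit.  Interaction models: a genotype x stratum cell-means
    parameterization (sex adjusted); effects reported within the
    reference stratum — American diet (by_diet) or males (by_sex).
    """
    if isinstance(y, pd.Series):
        y = y.reindex(covariates.sample_ids).to_numpy(float)
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    male, keto = _covariate_columns(covariates)
    mask = np.isfinite(y) & (g != MISSING_GENOTYPE)
    ym, gm, malem, ketom = y[mask], g[mask], male[mask], keto[mask]
    n = len(ym)
    one = np.ones(n)

    if model == "marginal":
        X = np.column_stack([one, malem, ketom, malem * ketom, (gm == 1), (gm == 2)])
        target = [4, 5]
        stratum = None
    else:
        if model == "by_diet":
            in_ref = ketom == 0
            stratum = "American"
        elif model == "by_sex":
            in_ref = malem == 1
            stratum = "male"
        else:
            raise ConfigError(f"unknown model {model!r}")
        adj = ketom if model == "by_sex" else malem
        # cell dummies relative to (B6/B6, reference stratum)
        cells = [
            (gm == 1) & in_ref,
            (gm == 2) & in_ref,
            (gm == 0) & ~in_ref,
            (gm == 1) & ~in_ref,
            (gm == 2) & ~in_ref,
        ]
        X = np.column_stack([one, adj] + [c.astype(float) for c in cells])
        target = [2, 3]

    coef, se = _ols_coef_se(X.astype(float), ym)
    eh, es = coef[target[0]], coef[target[1]]
    seh, ses = se[target[0]], se[target[1]]
    return AlleleEffects(float(eh), float(es), float(seh), float(ses), stratum)


def _ols_coef_se(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and standard errors; empty columns give nan."""
    empty = np.all(X == 0, axis=0)
    XtX = X.T @ X
    XtX_pinv = np.linalg.pinv(XtX)
    coef = XtX_pinv @ (X.T @ y)
    resid = y - X @ coef
    rank = np.linalg.matrix_rank(X)
    dof = max(len(y) - rank, 1)
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.maximum(np.diag(XtX_pinv) * sigma2, 0.0))
    coef[empty] = np.nan
    se[empty] = np.nan
    return coef, se


def variance_partition(
    y: np.ndarray | pd.Series,
    covariates: CovariateTable,
    g: np.ndarray,
    model: str = "marginal",
) -> dict[str, tuple[float, float]]:
    """Sequential (type-I) ANOVA of the alternative model.

    Term order: sex, diet, sex:diet, marker (marginal) or sex, diet,
    marker, marker-interaction.  Each term's share is
    100 * SS(term) / total SS of y (centered); p-values come from the
    term F tests against the full-model residual.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(covariates.sample_ids).to_numpy(float)
    y = np.asarray(y, dtype=float)
    g = np.asarray(g)
    male, keto = _covariate_columns(covariates)
    mask = np.isfinite(y) & (g != MISSING_GENOTYPE)
    ym = y[mask]
    blocks = _model_blocks(model, male[mask], keto[mask], g[mask])
    n = len(ym)
    sst = float(np.sum((ym - ym.mean()) ** 2))
    if sst == 0:
        return {name: (0.0, 1.0) for name, _ in blocks[1:]}

    Q = _ortho_basis(blocks[0][1])  # intercept
    rss_prev = float(np.sum(ym**2) - _rss_reduction(Q, ym[:, None])[0])
    out_ss: dict[str, tuple[float, int]] = {}
    for name, cols in blocks[1:]:
        Qe = _extend_basis(Q, cols)
        red = float(_rss_reduction(Qe, ym[:, None])[0])
        out_ss[name] = (red, Qe.shape[1])
        Q = np.hstack([Q, Qe])
        rss_prev -= red
    rss_full = rss_prev
    df_resid = n - Q.shape[1]
    result: dict[str, tuple[float, float]] = {}
    for name, (ss, df) in out_ss.items():
        pct = 100.0 * ss / sst
        if df > 0 and df_resid > 0 and rss_full > 0:
            F = (ss / df) / (rss_full / df_resid)
            p = float(stats.f.sf(F, df, df_resid))
        elif df == 0:
            p = float("nan")
        else:
            p = 0.0 if ss > 0 else 1.0
        result[name] = (pct, p)
    return result


def call_qtl(
    scan: ScanResult,
    thresholds: Thresholds,
    y: pd.Series | np.ndarray,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    drop: float = 1.5,
    qtl_prefix: str | None = None,
) -> list[QtlCall]:
    """Full QTL calls for a scan: peaks, intervals, effects, partitions."""
    mb = dict(zip(scan.marker_ids, scan.position_Mb))
    peaks = call_peaks(scan, thresholds)
    calls = []
    for k, peak in enumerate(peaks, start=1):
        left, right = support_interval(scan, peak, drop)
        g_top = genotypes.marker_column(peak.marker_id)
        eff = allele_effects(y, covariates, g_top, scan.model)
        vp = variance_partition(y, covariates, g_top, scan.model)
        yv = y.reindex(genotypes.sample_ids).to_numpy(float) if isinstance(y, pd.Series) else np.asarray(y, float)
        n_used = int((np.isfinite(yv) & (g_top != MISSING_GENOTYPE)).sum())
        prefix = qtl_prefix or f"{scan.trait_id}_{scan.model}"
        calls.append(
            QtlCall(
                qtl_id=f"{prefix}_q{k}",
                trait_id=scan.trait_id,
                model=scan.model,
                chromosome=peak.chromosome,
                top_marker=peak.marker_id,
                top_Mb=float(mb[peak.marker_id]),
                left_marker=left,
                left_Mb=float(mb[left]),
                right_marker=right,
                right_Mb=float(mb[right]),
                lod_peak=peak.lod,
                significance_level=peak.significance_level,
                effect_het=eff.effect_het,
                effect_hom=eff.effect_hom,
                variance_components=vp,
                n_used=n_used,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def overlap_qtl(
    calls: list[QtlCall], metabolic_calls: list[QtlCall] | None = None
) -> list[dict]:
    """Group QTL whose closed Mb support intervals intersect.

    Two QTL overlap iff they sit on the same chromosome and their
    [left_Mb, right_Mb] intervals intersect (touching endpoints count).
    Groups are connected components of the overlap graph; interval
    containment is flagged per ordered pair.  Only groups with at least
    two members are reported.
    """
    all_calls = list(calls) + list(metabolic_calls or [])
    graph = nx.Graph()
    graph.add_nodes_from(c.qtl_id for c in all_calls)
    by_id = {c.qtl_id: c for c in all_calls}
    items = list(by_id.values())
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            if a.chromosome != b.chromosome:
                continue
            if a.left_Mb <= b.right_Mb and b.left_Mb <= a.right_Mb:
                graph.add_edge(a.qtl_id, b.qtl_id)
    groups = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        members = sorted(comp)
        contain = []
        for a_id in members:
            for b_id in members:
                if a_id == b_id:
                    continue
                a, b = by_id[a_id], by_id[b_id]
                if b.left_Mb <= a.left_Mb and a.right_Mb <= b.right_Mb:
                    contain.append((a_id, b_id))  # a inside b
        groups.append(
            {
                "chromosome": by_id[members[0]].chromosome,
                "members": members,
                "contained_in": contain,
            }
        )
    groups.sort(key=lambda g: (g["chromosome"], g["members"]))
    return groups
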