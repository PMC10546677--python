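"""Structural path models for keystone-taxon inference.

Traits mapping to a shared locus (e.g. taxa abundances, a diversity
axis, a metabolic trait, plus the locus genotype and diet) are first
collapsed into k ordinal quantiles (k = 4 by default) and then fit as a
recursive path system: each endogenous variable is regressed, on the
standardized ordinal scores, on its specified parents; residual
correlations implement covariance paths.  Backward refinement removes
the single least-significant path at a time until every retained path
coefficient differs significantly from zero; a taxon whose path into
the diversity axis survives refinement is a candidate keystone
organism.

The estimator is deliberately simple — equationwise least squares on
standardized ordinal scores rather than a latent-variable engine over
polychoric correlations — because the inferential surface of interest
is the set of standardized path coefficients and their significance.
Genotype enters as the additive allele dose (0/1/2 FVB alleles) of the
chosen locus; genotype-by-diet structures use a precomputed product
variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigError

__all__ = [
    "PathModelSpec",
    "PathModelFit",
    "PathEstimate",
    "quantile_collapse",
    "fit_path_model",
    "refine_path_model",
]


def quantile_collapse(values: np.ndarray | pd.Series, k: int = 4) -> np.ndarray:
    """Collapse a trait into k ordinal quantile bins (1..k).

    Empirical (type-7) quantiles define the bin edges; a value lands in
    the smallest bin q with value <= quantile(q/k), so boundary ties go
    to the lower bin.  An all-constant input collapses to bin 1 with a
    warning.  Missing values stay missing.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = np.isfinite(x)
    xv = x[obs]
    if len(xv) == 0:
        return out
    if np.all(xv == xv[0]):
        warnings.warn("constant input collapses to a single bin", stacklevel=2)
        out[obs] = 1.0
        return out
    edges = np.quantile(xv, np.arange(1, k) / k)  # type-7 (linear) quantiles
    bins = np.ones(len(xv), dtype=float)
    for e in edges:
        bins += (xv > e).astype(float)
    out[obs] = bins
    return out


@dataclass
class PathModelSpec:
    """A recursive path system: directed paths plus covariance paths.

    ``directed_paths`` are (source, target) pairs forming an acyclic
    graph; ``covariance_paths`` are unordered pairs whose residual
    correlation is freed.  ``alpha`` is the retention level used by
    refinement.
    """

    variables: list[str]
    directed_paths: list[tuple[str, str]]
    covariance_paths: list[tuple[str, str]] = field(default_factory=list)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        vars_ = set(self.variables)
        for s, t in self.directed_paths:
            if s == t:
                raise ConfigError(f"self-path {s!r} -> {t!r}")
            if s not in vars_ or t not in vars_:
                raise ConfigError(f"path {s!r} -> {t!r} uses unknown variable")
        for a, b in self.covariance_paths:
            if a == b or a not in vars_ or b not in vars_:
                raise ConfigError(f"invalid covariance path ({a!r}, {b!r})")
        g = nx.DiGraph(self.directed_paths)
        if not nx.is_directed_acyclic_graph(g):
            raise ConfigError("directed paths contain a cycle")

    def endogenous(self) -> list[str]:
        targets = {t for _, t in self.directed_paths}
        return [v for v in self.variables if v in targets]

    def parents(self, v: str) -> list[str]:
        return [s for s, t in self.directed_paths if t == v]

    def without_edge(self, edge: tuple, kind: str) -> "PathModelSpec":
        if kind == "directed":
            directed = [e for e in self.directed_paths if e != tuple(edge)]
            cov = list(self.covariance_paths)
        else:
            directed = list(self.directed_paths)
            cov = [e for e in self.covariance_paths if frozenset(e) != frozenset(edge)]
        used = {v for e in directed for v in e} | {v for e in cov for v in e}
        variables = [v for v in self.variables if v in used]
        return PathModelSpec(variables, directed, cov, self.alpha)


@dataclass
class PathEstimate:
    edge: tuple[str, str]
    kind: str  # directed | covariance
    coefficient: float
    p_value: float
    t_stat: float = float("nan")


@dataclass
class PathModelFit:
    """Estimated path system: coefficients, p-values, refinement trace."""

    spec: PathModelSpec
    paths: list[PathEstimate]
    n: int
    refinement_trace: list[dict] = field(default_factory=list)

    def get(self, edge: tuple[str, str], kind: str = "directed") -> PathEstimate:
        for p in self.paths:
            if p.kind != kind:
                continue
            if kind == "directed" and p.edge == tuple(edge):
                return p
            if kind == "covariance" and frozenset(p.edge) == frozenset(edge):
                return p
        raise KeyError(f"{kind} path {edge} not in fit")

    def all_significant(self, alpha: float | None = None) -> bool:
        a = alpha if alpha is not None else self.spec.alpha
        return all(p.p_value < a for p in self.paths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "edge": f"{p.edge[0]}->{p.edge[1]}" if p.kind == "directed" else f"{p.edge[0]}~~{p.edge[1]}",
                    "kind": p.kind,
                    "coefficient": p.coefficient,
                    "t": p.t_stat,
                    "p_value": p.p_value,
                }
                for p in self.paths
            ]
        )

    def to_dot(self) -> str:
        """DOT export: arrow weight proportional to |coefficient|."""
        lines = ["digraph path_model {"]
        for p in self.paths:
            style = (
                f'[label="{p.coefficient:+.2f}", penwidth={max(0.5, 4 * abs(p.coefficient)):.2f}'
            )
            if p.kind == "covariance":
                style += ", dir=both, style=dashed]"
                lines.append(f'  "{p.edge[0]}" -> "{p.edge[1]}" {style};')
            else:
                style += "]"
                lines.append(f'  "{p.edge[0]}" -> "{p.edge[1]}" {style};')
        lines.append("}")
        return "\n".join(lines)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def fit_path_model(
    spec: PathModelSpec,
    data: pd.DataFrame,
    collapse: bool = True,
    k: int = 4,
) -> PathModelFit:
    """Fit the recursive system equation by equation.

    ``data`` holds one column per spec variable; complete cases only
    (listwise deletion).  With ``collapse`` each variable is first
    binned into k ordinal quantiles.  Path coefficients are
    standardized slopes with t-test p-values; covariance paths are
    residual correlations with Fisher-z p-values.  Collinear parents
    are dropped from their equation with a warning.
    """
    missing = [v for v in spec.variables if v not in data.columns]
    if missing:
        raise ConfigError(f"data lacks variables {missing}")
    frame = data[spec.variables].dropna()
    n = len(frame)
    if n <= len(spec.variables) + 2:
        raise ConfigError(f"too few complete cases (n={n}) for the path model")
    cols = {}
    for v in spec.variables:
        x = frame[v].to_numpy(float)
        if collapse:
            x = quantile_collapse(x, k)
        cols[v] = _standardize(x)

    estimates: list[PathEstimate] = []
    residuals: dict[str, np.ndarray] = {}
    for v in spec.variables:
        parents = spec.parents(v)
        if not parents:
            residuals[v] = cols[v]
            continue
        X = np.column_stack([cols[p] for p in parents])
        Xd = np.column_stack([np.ones(n), X])
        # collinearity: drop dependent parent columns
        rank = np.linalg.matrix_rank(Xd)
        if rank < Xd.shape[1]:
            warnings.warn(
                f"collinear parents in equation for {v!r}; coefficients pinv-resolved",
                stacklevel=2,
            )
        coef, se = _ols(Xd, cols[v])
        resid = cols[v] - Xd @ coef
        residuals[v] = resid
        dof = n - rank
        for i, p in enumerate(parents):
            b, s = coef[i + 1], se[i + 1]
            if s > 0 and np.isfinite(s):
                t = b / s
                pval = 2.0 * stats.t.sf(abs(t), dof)
            else:
                t, pval = float("nan"), 1.0
            estimates.append(PathEstimate((p, v), "directed", float(b), float(pval), float(t)))

    for a, b in spec.covariance_paths:
        ra, rb = residuals[a], residuals[b]
        if ra.std() == 0 or rb.std() == 0:
            estimates.append(PathEstimate((a, b), "covariance", 0.0, 1.0))
            continue
        r = float(np.corrcoef(ra, rb)[0, 1])
        # Fisher z test of the residual correlation
        r_clip = np.clip(r, -0.999999, 0.999999)
        z = np.arctanh(r_clip) * np.sqrt(max(n - 3, 1))
        pval = 2.0 * stats.norm.sf(abs(z))
        estimates.append(PathEstimate((a, b), "covariance", r, float(pval), float(z)))

    return PathModelFit(spec=spec, paths=estimates, n=n)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    XtX_pinv = np.linalg.pinv(X.T @ X)
    coef = XtX_pinv @ (X.T @ y)
    resid = y - X @ coef
    dof = max(len(y) - np.linalg.matrix_rank(X), 1)
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.maximum(np.diag(XtX_pinv) * sigma2, 0.0))
    return coef, se


def refine_path_model(
    spec: PathModelSpec,
    data: pd.DataFrame,
    collapse: bool = True,
    k: int = 4,
) -> PathModelFit:
    """Backward-refine: drop the worst path until all retained are significant.

    Deterministic elimination: largest p first, ties broken by smaller
    absolute coefficient, then lexicographic edge name.  Variables left
    without any path are dropped.  The trace of removals is recorded on
    the returned fit.
    """
    trace: list[dict] = []
    current = spec
    while True:
        if not current.directed_paths and not current.covariance_paths:
            fit = PathModelFit(spec=current, paths=[], n=0, refinement_trace=trace)
            return fit
        fit = fit_path_model(current, data, collapse=collapse, k=k)
        weak = [p for p in fit.paths if p.p_value >= current.alpha]
        if not weak:
            fit.refinement_trace = trace
            return fit
        weak.sort(key=lambda p: (-p.p_value, abs(p.coefficient), str(p.edge)))
        worst = weak[0]
        trace.append(
            {
                "removed": worst.edge,
                "kind": worst.kind,
                "p_value": worst.p_value,
                "coefficient": worst.coefficient,
            }
        )
        current = current.without_edge(worst.edge, worst.kind)
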