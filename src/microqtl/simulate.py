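"""Synthetic F2 microbiome-QTL studies.

Generates every input the pipeline consumes — a genetic map, F2
intercross genotypes, sex/diet covariates, a rooted ASV phylogeny and a
zero-inflated negative-binomial ASV count table with planted marginal,
diet-interaction and sex-interaction QTL — so the full analysis chain is
testable end to end without any external data.

The genetic model is a standard F2 between two inbred lines (B6 x FVB):
each individual is the sum of two independent gametes per chromosome,
with crossovers placed by Haldane's map function (no interference),
r = (1 - exp(-2d/100)) / 2 for an inter-marker distance of d cM.  At any
single marker the three genotype classes therefore segregate 1:2:1.

Counts follow a log-linear mean model per taxon,

    log mu = baseline + diet_effect * 1[keto] + sex_effect * 1[male]
             + a * g + d * 1[het] + interaction term,

scaled by a lognormal per-sample library-size factor, with
negative-binomial noise and an independent point mass of extra zeros.
Every planted effect is recorded in the bundle's truth list so that
downstream scan-recovery tests can score themselves against it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .core import (
    ConfigError,
    CountTable,
    CovariateTable,
    GeneticMap,
    GenotypeMatrix,
)

__all__ = [
    "EffectConfig",
    "StudyConfig",
    "StudyBundle",
    "simulate_map",
    "simulate_f2_genotypes",
    "simulate_covariates",
    "simulate_tree",
    "simulate_counts",
    "make_study",
    "write_bundle",
    "haldane_r",
]

#: fixed linear cM -> Mb conversion used for reporting positions
MB_PER_CM = 2.0


def haldane_r(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Haldane recombination fraction for a map distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM) / 100.0))


@dataclass
class EffectConfig:
    """Planted generative effects for one taxon (trait).

    ``additive_effect`` is the per-FVB-allele shift of the log mean;
    ``dominance_effect`` the extra shift for heterozygotes.
    ``interaction_mode`` routes ``interaction_effect`` to an extra
    additive slope in the ketogenic (by_diet) or male (by_sex) stratum.
    ``dispersion`` is the negative-binomial size parameter.
    """

    trait_id: str
    baseline_log_mean: float = 0.0
    diet_effect: float = 0.0
    sex_effect: float = 0.0
    qtl_marker: str | None = None
    additive_effect: float = 0.0
    dominance_effect: float = 0.0
    interaction_mode: str = "none"  # none | by_diet | by_sex
    interaction_effect: float = 0.0
    dispersion: float = 1.0
    zero_inflation: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.zero_inflation < 1.0):
            raise ConfigError(
                f"{self.trait_id}: zero_inflation must be in [0, 1)"
            )
        if self.dispersion <= 0:
            raise ConfigError(f"{self.trait_id}: dispersion must be positive")
        if self.interaction_mode not in ("none", "by_diet", "by_sex"):
            raise ConfigError(
                f"{self.trait_id}: unknown interaction_mode {self.interaction_mode!r}"
            )


def simulate_map(
    n_chromosomes: int,
    markers_per_chromosome: int,
    chrom_length_cM: float = 90.0,
    seed: int = 0,
) -> GeneticMap:
    """Random marker map: sorted uniform cM positions per chromosome.

    Physical positions are a fixed linear rescaling (2 Mb per cM).
    """
    if n_chromosomes < 1 or markers_per_chromosome < 2 or chrom_length_cM <= 0:
        raise ValueError(
            "need n_chromosomes >= 1, markers_per_chromosome >= 2, positive length"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in range(1, n_chromosomes + 1):
        pos = np.sort(rng.uniform(0.0, chrom_length_cM, markers_per_chromosome))
        # enforce strict increase (ties are measure-zero but be safe)
        pos += np.arange(markers_per_chromosome) * 1e-9
        for k, cm in enumerate(pos, start=1):
            rows.append((f"chr{chrom}_m{k:03d}", chrom, float(cm), float(cm) * MB_PER_CM))
    tab = pd.DataFrame(rows, columns=["marker_id", "chromosome", "cM", "Mb"])
    return GeneticMap(tab.set_index("marker_id"))


def _simulate_gametes(map_: GeneticMap, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate n_gametes haploid allele vectors (0 = B6, 1 = FVB)."""
    out = np.empty((n_gametes, map_.n_markers), dtype=np.int8)
    col = 0
    for _, sub in map_.table.groupby("chromosome", sort=False):
        m = len(sub)
        r = haldane_r(np.diff(sub["cM"].to_numpy(float)))
        alleles = np.empty((n_gametes, m), dtype=np.int8)
        alleles[:, 0] = rng.integers(0, 2, n_gametes)
        if m > 1:
            switches = rng.random((n_gametes, m - 1)) < r
            alleles[:, 1:] = (
                alleles[:, [0]] + np.cumsum(switches, axis=1)
            ) % 2
        out[:, col : col + m] = alleles
        col += m
    return out


def simulate_f2_genotypes(
    map_: GeneticMap, n_individuals: int, seed: int = 0
) -> GenotypeMatrix:
    """F2 genotypes as the sum of two independent gametes per individual."""
    if map_.n_markers == 0:
        raise ValueError("empty genetic map")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    maternal = _simulate_gametes(map_, n_individuals, rng)
    paternal = _simulate_gametes(map_, n_individuals, rng)
    genotypes = (maternal + paternal).astype(np.int8)
    samples = [f"F2_{i:04d}" for i in range(1, n_individuals + 1)]
    return GenotypeMatrix(samples, genotypes, map_)


def simulate_covariates(
    n_individuals: int, diet_fraction: float = 0.5, seed: int = 0
) -> CovariateTable:
    """Assign sex (random, balanced in expectation) and diet.

    Diet counts are balanced deterministically: round(n * diet_fraction)
    individuals receive the American diet, assignment order randomized.
    """
    if not (0.0 < diet_fraction < 1.0):
        raise ValueError("diet_fraction must be in (0, 1)")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    n_american = int(round(n_individuals * diet_fraction))
    diet = np.array(["American"] * n_american + ["ketogenic"] * (n_individuals - n_american))
    rng.shuffle(diet)
    sex = np.where(rng.random(n_individuals) < 0.5, "male", "female")
    samples = [f"F2_{i:04d}" for i in range(1, n_individuals + 1)]
    tab = pd.DataFrame({"sex": sex, "diet": diet}, index=pd.Index(samples, name="sample_id"))
    return CovariateTable(tab)


def simulate_tree(taxa_ids: list[str], seed: int = 0) -> TreeNode:
    """Random rooted binary tree over the taxa by sequential joining.

    Branch lengths are exponential with mean 1; every taxon appears
    exactly once as a leaf.
    """
    if len(taxa_ids) < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(taxa_ids)) != len(taxa_ids):
        raise ValueError("duplicate taxa ids")
    rng = np.random.default_rng(seed)

    def leaf(name: str) -> TreeNode:
        node = TreeNode(name=name)
        node.length = float(rng.exponential(1.0))
        return node

    order = list(taxa_ids)
    rng.shuffle(order)
    subtrees = [leaf(order[0]), leaf(order[1])]
    for name in order[2:]:
        # join the new leaf with a randomly chosen current subtree
        j = rng.integers(0, len(subtrees))
        joined = TreeNode(children=[subtrees.pop(int(j)), leaf(name)])
        joined.length = float(rng.exponential(1.0))
        subtrees.append(joined)
    while len(subtrees) > 1:
        b = subtrees.pop(int(rng.integers(0, len(subtrees))))
        a = subtrees.pop(int(rng.integers(0, len(subtrees))))
        joined = TreeNode(children=[a, b])
        joined.length = float(rng.exponential(1.0))
        subtrees.append(joined)
    root = subtrees[0]
    root.length = None
    return root


def simulate_counts(
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    effects: list[EffectConfig],
    library_size_mean: float = 26000.0,
    library_size_sigma: float = 0.3,
    seed: int = 0,
) -> CountTable:
    """Zero-inflated negative-binomial counts under the planted effects.

    ``baseline_log_mean`` is on the relative-abundance scale: the
    expected count is ``exp(log-linear predictor) * library factor``,
    with the library factor lognormal with mean ``library_size_mean``.
    """
    ids = [e.trait_id for e in effects]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate trait ids in effect configs")
    marker_ids = set(genotypes.map.marker_ids)
    for e in effects:
        if e.qtl_marker is not None and e.qtl_marker not in marker_ids:
            raise ConfigError(
                f"{e.trait_id}: qtl_marker {e.qtl_marker!r} not in map"
            )
    if list(covariates.sample_ids) != list(genotypes.sample_ids):
        raise ConfigError("covariate and genotype sample ids disagree")

    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    keto = covariates.keto_indicator()
    male = covariates.male_indicator()
    # lognormal library factor with arithmetic mean = library_size_mean
    mu_log = np.log(library_size_mean) - 0.5 * library_size_sigma**2
    lib = rng.lognormal(mu_log, library_size_sigma, n)

    counts = np.empty((n, len(effects)), dtype=np.int64)
    for j, e in enumerate(effects):
        eta = np.full(n, e.baseline_log_mean)
        eta += e.diet_effect * keto + e.sex_effect * male
        if e.qtl_marker is not None:
            g = genotypes.marker_column(e.qtl_marker).astype(float)
            het = (g == 1).astype(float)
            eta += e.additive_effect * g + e.dominance_effect * het
            if e.interaction_mode == "by_diet":
                eta += e.interaction_effect * g * keto
            elif e.interaction_mode == "by_sex":
                eta += e.interaction_effect * g * male
        mu = np.exp(eta) * lib
        size = e.dispersion
        p = size / (size + mu)
        draws = rng.negative_binomial(size, p)
        if e.zero_inflation > 0:
            draws = np.where(rng.random(n) < e.zero_inflation, 0, draws)
        counts[:, j] = draws
    return CountTable(list(genotypes.sample_ids), ids, counts)


@dataclass
class StudyConfig:
    """Sizes and planted-effect layout of a synthetic study.

    Defaults mirror the study design the pipeline targets: 469 F2
    individuals on two diets (half each), 19 autosomes with ~88 markers
    each (~1670 informative markers), and an ASV panel dominated by
    strong diet main effects with a handful of planted QTL.
    """

    n_individuals: int = 469
    n_chromosomes: int = 19
    markers_per_chromosome: int = 88
    chrom_length_cM: float = 90.0
    diet_fraction: float = 0.5
    n_asvs: int = 150
    library_size_mean: float = 26000.0
    library_size_sigma: float = 0.3
    #: (count, additive log effect) of planted marginal QTL
    n_marginal_qtl: int = 3
    marginal_effect: float = float(np.log(1.6))
    n_diet_qtl: int = 2
    diet_interaction_effect: float = float(np.log(1.8))
    n_sex_qtl: int = 1
    sex_interaction_effect: float = float(np.log(1.8))
    #: fraction of taxa with a (large) diet main effect, and its SD in log units
    diet_effect_fraction: float = 0.6
    diet_effect_sd: float = 1.0
    zero_inflation: float = 0.10
    dispersion: float = 1.5
    seed: int = 0


@dataclass
class StudyBundle:
    """A complete synthetic study plus the ground truth that generated it."""

    genotypes: GenotypeMatrix
    map: GeneticMap
    covariates: CovariateTable
    counts: CountTable
    tree: TreeNode
    truth: list[EffectConfig]
    seed: int

    def __post_init__(self) -> None:
        if list(self.genotypes.sample_ids) != list(self.covariates.sample_ids):
            raise ConfigError("sample ids disagree between genotypes and covariates")
        if list(self.counts.sample_ids) != list(self.genotypes.sample_ids):
            raise ConfigError("sample ids disagree between counts and genotypes")

    def planted_qtl(self) -> list[EffectConfig]:
        return [e for e in self.truth if e.qtl_marker is not None]


def _default_effects(cfg: StudyConfig, map_: GeneticMap, rng: np.random.Generator) -> list[EffectConfig]:
    """Lay out per-taxon effects: rank-abundance baselines, diet mains, QTL."""
    n = cfg.n_asvs
    # lognormal relative-abundance profile normalized to sum ~1
    weights = rng.lognormal(0.0, 1.5, n)
    weights /= weights.sum()
    baselines = np.log(weights)
    diet_mask = rng.random(n) < cfg.diet_effect_fraction
    diet_effects = np.where(diet_mask, rng.normal(0.0, cfg.diet_effect_sd, n), 0.0)
    sex_effects = rng.normal(0.0, 0.15, n)

    n_qtl = cfg.n_marginal_qtl + cfg.n_diet_qtl + cfg.n_sex_qtl
    if n_qtl > n:
        raise ConfigError("more planted QTL than taxa")
    # QTL land on the most abundant taxa so the traits survive CMM filtering
    qtl_taxa = np.argsort(weights)[::-1][:n_qtl]
    markers = rng.choice(map_.n_markers, size=n_qtl, replace=False)
    marker_ids = [map_.marker_ids[m] for m in markers]

    effects = []
    for j in range(n):
        e = EffectConfig(
            trait_id=f"ASV_{j + 1:04d}",
            baseline_log_mean=float(baselines[j]),
            diet_effect=float(diet_effects[j]),
            sex_effect=float(sex_effects[j]),
            dispersion=cfg.dispersion,
            zero_inflation=cfg.zero_inflation,
        )
        effects.append(e)
    for i, j in enumerate(qtl_taxa):
        e = effects[j]
        e.qtl_marker = marker_ids[i]
        if i < cfg.n_marginal_qtl:
            e.additive_effect = cfg.marginal_effect
        elif i < cfg.n_marginal_qtl + cfg.n_diet_qtl:
            e.interaction_mode = "by_diet"
            e.interaction_effect = cfg.diet_interaction_effect
        else:
            e.interaction_mode = "by_sex"
            e.interaction_effect = cfg.sex_interaction_effect
    return effects


def make_study(
    config: StudyConfig | None = None,
    effects: list[EffectConfig] | None = None,
    seed: int | None = None,
) -> StudyBundle:
    """Compose the five simulators into a reproducible study bundle.

    When ``effects`` is omitted a default layout is drawn (see
    :class:`StudyConfig`); the planted truth is always recorded.
    """
    cfg = config or StudyConfig()
    if seed is not None:
        cfg.seed = seed
    root = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(6)]

    map_ = simulate_map(
        cfg.n_chromosomes, cfg.markers_per_chromosome, cfg.chrom_length_cM, seeds[0]
    )
    genotypes = simulate_f2_genotypes(map_, cfg.n_individuals, seeds[1])
    covariates = simulate_covariates(cfg.n_individuals, cfg.diet_fraction, seeds[2])
    if effects is None:
        effects = _default_effects(cfg, map_, np.random.default_rng(seeds[3]))
    tree = simulate_tree([e.trait_id for e in effects], seeds[4])
    counts = simulate_counts(
        genotypes,
        covariates,
        effects,
        cfg.library_size_mean,
        cfg.library_size_sigma,
        seeds[5],
    )
    return StudyBundle(genotypes, map_, covariates, counts, tree, effects, cfg.seed)


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialize a bundle to the canonical on-disk layout.

    genotypes.csv (individuals x markers, codes 0/1/2/NA), map.csv,
    covariates.csv, counts.tsv (ASV rows x sample columns), tree.nwk and
    truth.yaml; all re-readable through :mod:`microqtl.io_formats`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    gt = bundle.genotypes.to_frame().astype(object)
    gt[bundle.genotypes.genotypes == -1] = "NA"
    paths["genotypes"] = outdir / "genotypes.csv"
    gt.to_csv(paths["genotypes"], index_label="sample_id")

    paths["map"] = outdir / "map.csv"
    bundle.map.table.to_csv(paths["map"], index_label="marker_id")

    paths["covariates"] = outdir / "covariates.csv"
    bundle.covariates.table.to_csv(paths["covariates"], index_label="sample_id")

    paths["counts"] = outdir / "counts.tsv"
    bundle.counts.to_frame().T.to_csv(paths["counts"], sep="\t", index_label="asv_id")

    paths["tree"] = outdir / "tree.nwk"
    buf = io.StringIO()
    bundle.tree.write(buf)
    paths["tree"].write_text(buf.getvalue())

    paths["truth"] = outdir / "truth.yaml"
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(
            {"seed": bundle.seed, "effects": [asdict(e) for e in bundle.truth]},
            fh,
            sort_keys=False,
        )
    return paths
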