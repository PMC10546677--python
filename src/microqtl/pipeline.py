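"""End-to-end orchestration: simulate/load -> traits -> scans -> report.

``run_pipeline`` executes the full analysis in order — study input (from
disk or the synthetic generator), rarefaction and diversity traits,
core-microbiota definition and quantile normalization, the three
genome scans with permutation thresholds, QTL calling with support
intervals and variance partitions, colocalization, and an optional
structural path model — writing one artifact per stage into a run
directory together with a manifest (seed, config, versions, input
checksums) that suffices to reproduce the run.

Defaults follow the target study design: rarefaction depth 4500, CMM
presence fraction 0.20, prevalence filter (>5 counts in >=5% of
samples), 1.5-LOD support intervals, thresholds at alpha 0.05/0.01.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import CountTable, CovariateTable, GenotypeMatrix, TraitMatrix
from . import diversity as dv
from . import io_formats as iof
from . import trait_prep as tp
from . import qtl_scan as qs
from .path_model import PathModelSpec, refine_path_model
from .simulate import StudyBundle, StudyConfig, make_study, write_bundle

logger = logging.getLogger("microqtl")

__all__ = ["RunConfig", "run_pipeline", "report", "scan_all_traits", "build_traits"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run (defaults = the study design)."""

    output_dir: str = "microqtl_run"
    input_dir: str | None = None  # read a serialized bundle instead of simulating
    simulation: dict = field(default_factory=dict)  # StudyConfig overrides
    rarefaction_depth: int = 4500
    cmm_fraction: float = 0.20
    prevalence_min_count: int = 5
    prevalence_min_fraction: float = 0.05
    models: tuple[str, ...] = ("marginal", "by_diet", "by_sex")
    n_perm: int = 1000
    alphas: tuple[float, ...] = (0.05, 0.01)
    lod_drop: float = 1.5
    pcoa_axes: tuple[int, ...] = (1, 2)
    path_spec: dict | None = None
    make_plots: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = iof.read_config(path)
        raw.update(overrides)
        cfg = cls(**raw)
        cfg.models = tuple(cfg.models)
        cfg.alphas = tuple(cfg.alphas)
        cfg.pcoa_axes = tuple(cfg.pcoa_axes)
        return cfg


def _load_bundle(input_dir: Path) -> StudyBundle:
    genotypes = iof.read_genotypes(input_dir / "genotypes.csv", input_dir / "map.csv")
    covariates = iof.read_covariates(input_dir / "covariates.csv")
    counts = iof.read_count_table(input_dir / "counts.tsv", orientation="asv_rows")
    tree = iof.read_tree(input_dir / "tree.nwk")
    truth = []
    truth_path = input_dir / "truth.yaml"
    seed = 0
    if truth_path.exists():
        raw = iof.read_config(truth_path)
        seed = raw.get("seed", 0)
        from .simulate import EffectConfig

        truth = [EffectConfig(**e) for e in raw.get("effects", [])]
    return StudyBundle(genotypes, genotypes.map, covariates, counts, tree, truth, seed)


def build_traits(
    bundle: StudyBundle,
    depth: int = 4500,
    cmm_fraction: float = 0.20,
    pcoa_axes: tuple[int, ...] = (1, 2),
    seed: int = 0,
) -> tuple[TraitMatrix, dict, CountTable, dict]:
    """Diversity + normalized-abundance trait construction for a bundle.

    Returns the assembled TraitMatrix and a stage summary (dropped
    samples, CMM size, PCoA variance fractions).
    """
    rarefied, dropped = dv.rarefy(bundle.counts, depth, seed=seed)
    alpha = dv.alpha_diversity_table(rarefied)
    dms = {
        "bray_curtis": dv.bray_curtis(rarefied),
        "jaccard": dv.jaccard(rarefied),
        "unweighted_unifrac": dv.unweighted_unifrac(rarefied, bundle.tree),
        "weighted_unifrac": dv.weighted_unifrac(rarefied, bundle.tree),
    }
    pcoas = {m: dv.pcoa(d) for m, d in dms.items()}
    diversity_traits = dv.eigenvector_traits(pcoas, list(pcoa_axes), alpha)

    cmm = tp.define_cmm(rarefied, cmm_fraction)
    abundance = None
    if cmm:
        cmm_counts = rarefied.select_asvs(cmm).to_frame().astype(float)
        abundance = tp.quantile_normalize(cmm_counts)
    metabolic = bundle.covariates.metabolic_traits()
    traits = tp.assemble_traits(
        abundance,
        diversity_traits,
        metabolic if metabolic.shape[1] else None,
        genotypes=bundle.genotypes,
        covariates=bundle.covariates,
    )
    info = {
        "rarefaction_depth": depth,
        "samples_dropped_at_rarefaction": dropped,
        "n_samples_used": len(traits.sample_ids),
        "cmm_size": len(cmm),
        "cmm_asvs": cmm,
        "pcoa_proportion_explained": {
            m: [float(x) for x in p.proportion_explained[:2]] for m, p in pcoas.items()
        },
    }
    return traits, info, rarefied, pcoas


def scan_all_traits(
    traits: TraitMatrix,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    model: str,
) -> dict[str, qs.ScanResult]:
    """Scan every trait under one model, batching complete columns."""
    sub_ids = traits.sample_ids
    geno = GenotypeMatrix(
        list(sub_ids),
        genotypes.to_frame().loc[sub_ids].to_numpy(),
        genotypes.map,
    )
    cov = covariates.select_samples(sub_ids)
    results: dict[str, qs.ScanResult] = {}
    vals = traits.values
    complete_geno = not (geno.genotypes == qs.MISSING_GENOTYPE).any()
    complete_cols = [t for t in traits.trait_ids if vals[t].notna().all()]
    other_cols = [t for t in traits.trait_ids if t not in set(complete_cols)]
    tab = geno.map.table
    if complete_geno and complete_cols:
        lod = qs.scan_lod_matrix(vals[complete_cols], geno, cov, model)
        for i, t in enumerate(complete_cols):
            results[t] = qs.ScanResult(
                trait_id=t,
                model=model,
                marker_ids=list(tab.index),
                chromosome=tab["chromosome"].to_numpy(),
                position_cM=tab["cM"].to_numpy(float),
                position_Mb=tab["Mb"].to_numpy(float),
                lod=lod[:, i],
                n_used=np.full(geno.map.n_markers, len(sub_ids)),
                rss_null=np.full(geno.map.n_markers, np.nan),
                rss_alt=np.full(geno.map.n_markers, np.nan),
            )
        todo = other_cols
    else:
        todo = traits.trait_ids
    for t in todo:
        results[t] = qs.genome_scan(vals[t], geno, cov, model, trait_id=t)
    return results


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("run starts (seed=%d)", config.seed)

    # --- stage: study input -------------------------------------------------
    if config.input_dir is not None:
        bundle = _load_bundle(Path(config.input_dir))
        logger.info("loaded study from %s", config.input_dir)
    else:
        sim_cfg = StudyConfig(**config.simulation)
        bundle = make_study(sim_cfg, seed=config.seed)
        write_bundle(bundle, outdir / "study")
        logger.info(
            "simulated study: %d individuals, %d markers, %d ASVs",
            bundle.genotypes.n_samples,
            bundle.map.n_markers,
            bundle.counts.n_asvs,
        )

    # --- stage: traits ------------------------------------------------------
    traits, trait_info, rarefied, pcoas = build_traits(
        bundle,
        depth=config.rarefaction_depth,
        cmm_fraction=config.cmm_fraction,
        pcoa_axes=config.pcoa_axes,
        seed=config.seed,
    )
    prevalent = tp.prevalence_filter(
        rarefied, config.prevalence_min_count, config.prevalence_min_fraction
    )
    trait_info["n_asvs_passing_prevalence_filter"] = prevalent.n_asvs
    iof.write_trait_matrix(traits, outdir / "traits.tsv")
    logger.info(
        "traits assembled: CMM size %d, %d trait columns",
        trait_info["cmm_size"],
        len(traits.trait_ids),
    )

    # --- stage: scans + thresholds + calls ----------------------------------
    calls: list[qs.QtlCall] = []
    thresholds_out: dict = {}
    scan_summaries = []
    sub_geno = GenotypeMatrix(
        list(traits.sample_ids),
        bundle.genotypes.to_frame().loc[traits.sample_ids].to_numpy(),
        bundle.map,
    )
    sub_cov = bundle.covariates.select_samples(traits.sample_ids)
    if config.n_perm > 0:
        for model in config.models:
            scans = scan_all_traits(traits, bundle.genotypes, bundle.covariates, model)
            for cls in ("asv_abundance", "diversity", "metabolic"):
                cls_traits = traits.traits_of_class(cls)
                if not cls_traits:
                    continue
                thr = qs.permutation_thresholds(
                    traits.subset(cls_traits),
                    sub_geno,
                    sub_cov,
                    model=model,
                    n_perm=config.n_perm,
                    alphas=config.alphas,
                    seed=config.seed,
                    trait_class=cls,
                )
                thresholds_out[f"{model}/{cls}"] = {
                    "class_thresholds": {str(a): v for a, v in thr.class_thresholds.items()},
                    "n_perm": thr.n_perm,
                }
                for t in cls_traits:
                    res = scans[t]
                    y = traits.values[t]
                    calls.extend(
                        qs.call_qtl(
                            res, thr, y, sub_geno, sub_cov, drop=config.lod_drop
                        )
                    )
            scan_summaries.append(
                {
                    "model": model,
                    "max_lod": float(max(s.max_lod() for s in scans.values())),
                }
            )
            logger.info("model %s: %d calls so far", model, len(calls))
        iof.write_qtl_table(calls, outdir / "qtl_calls.tsv")
        with open(outdir / "thresholds.yaml", "w") as fh:
            yaml.safe_dump(thresholds_out, fh, sort_keys=True)
    else:
        logger.info("n_perm = 0: thresholds and QTL calling skipped")

    # --- stage: colocalization ----------------------------------------------
    groups = qs.overlap_qtl(calls) if calls else []
    if calls:
        rows = [
            {
                "group": i + 1,
                "chromosome": g["chromosome"],
                "members": ";".join(g["members"]),
                "contained_pairs": ";".join(f"{a}<{b}" for a, b in g["contained_in"]),
            }
            for i, g in enumerate(groups)
        ]
        pd.DataFrame(
            rows, columns=["group", "chromosome", "members", "contained_pairs"]
        ).to_csv(outdir / "colocalization.tsv", sep="\t", index=False)

    # --- stage: path model ---------------------------------------------------
    path_summary = None
    if config.path_spec is not None:
        spec = PathModelSpec(
            variables=list(config.path_spec["variables"]),
            directed_paths=[tuple(e) for e in config.path_spec["directed_paths"]],
            covariance_paths=[tuple(e) for e in config.path_spec.get("covariance_paths", [])],
            alpha=config.path_spec.get("alpha", 0.05),
        )
        data = _path_data(spec, traits, sub_geno, sub_cov)
        fit = refine_path_model(spec, data)
        fit.to_frame().to_csv(outdir / "path_model.tsv", sep="\t", index=False)
        (outdir / "path_model.dot").write_text(fit.to_dot())
        path_summary = {
            "n_paths_retained": len(fit.paths),
            "n_paths_removed": len(fit.refinement_trace),
        }

    # --- stage: report + manifest -------------------------------------------
    summary = {
        "seed": config.seed,
        "n_samples": bundle.genotypes.n_samples,
        "n_markers": bundle.map.n_markers,
        "n_asvs": bundle.counts.n_asvs,
        **{k: v for k, v in trait_info.items() if k != "cmm_asvs"},
        "n_qtl_calls": len(calls),
        "qtl_calls_by_model": {
            m: sum(1 for c in calls if c.model == m) for m in config.models
        },
        "n_colocalization_groups": len(groups),
        "scan_summaries": scan_summaries,
        "path_model": path_summary,
    }
    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    _write_manifest(outdir, config)
    if config.make_plots:
        _plots(outdir, pcoas, sub_cov, calls)
    logger.info("run complete: %d QTL calls, %d colocalization groups", len(calls), len(groups))
    return outdir


def _path_data(spec, traits, genotypes, covariates) -> pd.DataFrame:
    """Assemble path-model columns: traits, covariate codes, marker doses.

    A variable named ``genotype:<marker>`` becomes the additive FVB
    allele dose at that marker; ``genotype:<marker>:diet`` its product
    with the ketogenic-diet indicator; ``diet``/``sex`` the 0/1 codes.
    """
    cols = {}
    for v in spec.variables:
        if v in traits.values.columns:
            cols[v] = traits.values[v].to_numpy(float)
        elif v == "diet":
            cols[v] = covariates.keto_indicator()
        elif v == "sex":
            cols[v] = covariates.male_indicator()
        elif v.startswith("genotype:"):
            parts = v.split(":")
            g = genotypes.marker_column(parts[1]).astype(float)
            g[g == qs.MISSING_GENOTYPE] = np.nan
            if len(parts) == 3 and parts[2] == "diet":
                g = g * covariates.keto_indicator()
            cols[v] = g
        else:
            raise KeyError(f"path-model variable {v!r} not found")
    return pd.DataFrame(cols, index=traits.values.index)


def _write_manifest(outdir: Path, config: RunConfig) -> None:
    checksums = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.yaml" and p.suffix not in (".png", ".log"):
            checksums[str(p.relative_to(outdir))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    manifest = {
        "microqtl_version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "artifact_checksums": checksums,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def _plots(outdir, pcoas, covariates, calls) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = pcoas.get("bray_curtis")
    if res is not None and res.coordinates.shape[1] >= 2:
        keep = [s for s in res.sample_ids if s in set(covariates.sample_ids)]
        idx = [res.sample_ids.index(s) for s in keep]
        keto = covariates.select_samples(keep).keto_indicator().astype(bool)
        xy = res.coordinates[idx][:, :2]
        fig, ax = plt.subplots(figsize=(5, 4))
        for mask, label, color in ((~keto, "American", "#c23b22"), (keto, "ketogenic", "#2266aa")):
            ax.scatter(xy[mask, 0], xy[mask, 1], s=8, alpha=0.7, label=label, color=color)
        pe = res.proportion_explained
        ax.set_xlabel(f"PCo1 ({100 * pe[0]:.1f}%)")
        ax.set_ylabel(f"PCo2 ({100 * pe[1]:.1f}%)")
        ax.legend(frameon=False)
        ax.set_title("Bray-Curtis PCoA by diet")
        fig.tight_layout()
        fig.savefig(outdir / "pcoa_bray_curtis.png", dpi=120)
        plt.close(fig)


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler) for h in logger.handlers):
        fh = logging.FileHandler(outdir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run directory."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.yaml"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.yaml in {run_dir}; did the run complete?")
    summary = iof.read_config(summary_path)
    lines = ["microqtl run summary", "=" * 22]
    lines.append(f"samples: {summary['n_samples']}   markers: {summary['n_markers']}   ASVs: {summary['n_asvs']}")
    lines.append(
        f"CMM size: {summary.get('cmm_size')}   "
        f"samples used: {summary.get('n_samples_used')}"
    )
    pe = summary.get("pcoa_proportion_explained", {})
    for metric, fr in pe.items():
        pct = ", ".join(f"{100 * f:.1f}%" for f in fr)
        lines.append(f"  {metric}: PCo1/PCo2 explain {pct}")
    lines.append(f"QTL calls: {summary.get('n_qtl_calls')} {summary.get('qtl_calls_by_model')}")
    lines.append(f"colocalization groups: {summary.get('n_colocalization_groups')}")
    if summary.get("path_model"):
        pm = summary["path_model"]
        lines.append(
            f"path model: {pm['n_paths_retained']} paths retained, "
            f"{pm['n_paths_removed']} removed in refinement"
        )
    qtl_path = run_dir / "qtl_calls.tsv"
    if qtl_path.exists():
        tab = iof.read_qtl_table(qtl_path)
        if len(tab):
            lines.append("")
            lines.append(tab.to_string(index=False, max_rows=30))
    else:
        lines.append("QTL stage: skipped")
    return "\n".join(lines)
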