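"""Core containers shared across the pipeline.

The pipeline operates on four tabular objects — a genetic map, an F2
genotype matrix bound to that map, a sample x ASV count table, and a
covariate table (sex, diet, optional metabolic traits) — plus a rooted
phylogeny (a :class:`skbio.TreeNode`) and the trait matrix the genome
scans consume.  All containers are thin, validated wrappers around
pandas/numpy structures; they exist to pin the orientation, dtype and
identifier conventions that the statistical stages rely on.

Genotype codes are fixed as 0 = B6/B6, 1 = B6/FVB (heterozygote),
2 = FVB/FVB, with ``-1`` as the in-memory missing code.  All allele
effects downstream are reported relative to B6/B6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_GENOTYPE = -1
GENOTYPE_LABELS = {0: "B6/B6", 1: "B6/FVB", 2: "FVB/FVB"}

#: taxonomy rank naming convention (D0 Kingdom ... D6 Species)
TAXONOMY_RANKS = [
    "D0_Kingdom",
    "D1_Phylum",
    "D2_Class",
    "D3_Order",
    "D4_Family",
    "D5_Genus",
    "D6_Species",
]


class MicroQtlError(Exception):
    """Base class for all package errors."""


class FormatError(MicroQtlError):
    """Malformed external file or table (names the offending cell)."""


class ConfigError(MicroQtlError):
    """Inconsistent configuration or specification."""


class ConsistencyError(MicroQtlError):
    """Cross-object identifier mismatch (samples, markers, taxa)."""


@dataclass
class GeneticMap:
    """Marker map: chromosome, genetic (cM) and physical (Mb) positions.

    Markers must be strictly increasing in cM and non-decreasing in Mb
    within each chromosome; ids must be unique.
    """

    table: pd.DataFrame  # index = marker_id; columns chromosome, cM, Mb

    def __post_init__(self) -> None:
        required = {"chromosome", "cM", "Mb"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"map requires columns {sorted(required)}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate marker id {dup!r} in map")
        for chrom, sub in self.table.groupby("chromosome", sort=False):
            cm = sub["cM"].to_numpy(float)
            if np.any(np.diff(cm) <= 0):
                raise FormatError(
                    f"marker cM positions not strictly increasing on chromosome {chrom}"
                )
            mb = sub["Mb"].to_numpy(float)
            if np.any(np.diff(mb) < 0):
                raise FormatError(
                    f"marker Mb positions decreasing on chromosome {chrom}"
                )
            if (cm < 0).any() or (mb < 0).any():
                raise FormatError(f"negative position on chromosome {chrom}")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chromosomes(self) -> list:
        seen: list = []
        for c in self.table["chromosome"]:
            if c not in seen:
                seen.append(c)
        return seen

    def sorted_by_position(self) -> "GeneticMap":
        tab = self.table.sort_values(["chromosome", "cM"], kind="stable")
        return GeneticMap(tab)


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype codes bound to a :class:`GeneticMap`.

    ``genotypes`` entries are in {0, 1, 2, -1(missing)}; rows are samples,
    columns follow ``map`` order.
    """

    sample_ids: list[str]
    genotypes: np.ndarray  # int8/int16, samples x markers
    map: GeneticMap

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.shape != (len(self.sample_ids), self.map.n_markers):
            raise ConsistencyError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.map.n_markers} markers"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING_GENOTYPE))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid genotype code {self.genotypes[i, j]} for sample "
                f"{self.sample_ids[i]!r}, marker {self.map.marker_ids[j]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in genotype matrix")

    @property
    def marker_ids(self) -> list[str]:
        return self.map.marker_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def marker_column(self, marker_id: str) -> np.ndarray:
        j = self.map.marker_ids.index(marker_id)
        return self.genotypes[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.genotypes, index=self.sample_ids, columns=self.marker_ids
        )


@dataclass
class CountTable:
    """Samples x ASVs non-negative integer counts, with optional taxonomy."""

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray  # samples x ASVs, integer
    taxonomy: dict[str, dict[str, str]] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ConsistencyError(
                f"count matrix shape {self.counts.shape} does not match ids"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count for sample {self.sample_ids[i]!r}, "
                f"ASV {self.asv_ids[j]!r}"
            )
        for name, ids in (("sample", self.sample_ids), ("ASV", self.asv_ids)):
            if len(set(ids)) != len(ids):
                raise FormatError(f"duplicate {name} ids in count table")
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.asv_ids)
            if unknown:
                raise ConsistencyError(
                    f"taxonomy for unknown ASVs: {sorted(unknown)[:3]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    def select_samples(self, keep: list[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return CountTable(list(keep), list(self.asv_ids), self.counts[idx], self.taxonomy)

    def select_asvs(self, keep: list[str]) -> "CountTable":
        idx = [self.asv_ids.index(a) for a in keep]
        tax = {a: self.taxonomy[a] for a in keep if a in self.taxonomy} if self.taxonomy else None
        return CountTable(list(self.sample_ids), list(keep), self.counts[:, idx], tax)


@dataclass
class CovariateTable:
    """Per-sample sex/diet assignment plus optional numeric traits.

    ``sex`` takes values {male, female}; ``diet`` {American, ketogenic}.
    Extra numeric columns (e.g. fat mass gain, serum HDL) ride along as
    metabolic traits.
    """

    table: pd.DataFrame  # index = sample_id; columns sex, diet, extras

    SEXES = ("male", "female")
    DIETS = ("American", "ketogenic")

    def __post_init__(self) -> None:
        for col in ("sex", "diet"):
            if col not in self.table.columns:
                raise FormatError(f"covariate table missing column {col!r}")
        if self.table.index.duplicated().any():
            raise FormatError("duplicate sample ids in covariate table")
        bad_sex = ~self.table["sex"].isin(self.SEXES)
        if bad_sex.any():
            sid = self.table.index[bad_sex][0]
            raise FormatError(f"invalid sex value for sample {sid!r}")
        bad_diet = ~self.table["diet"].isin(self.DIETS)
        if bad_diet.any():
            sid = self.table.index[bad_diet][0]
            raise FormatError(f"invalid diet value for sample {sid!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def male_indicator(self) -> np.ndarray:
        return (self.table["sex"] == "male").to_numpy(float)

    def keto_indicator(self) -> np.ndarray:
        return (self.table["diet"] == "ketogenic").to_numpy(float)

    def metabolic_traits(self) -> pd.DataFrame:
        extras = [c for c in self.table.columns if c not in ("sex", "diet")]
        return self.table[extras].astype(float)

    def select_samples(self, keep: list[str]) -> "CovariateTable":
        return CovariateTable(self.table.loc[list(keep)].copy())


TRAIT_CLASSES = ("asv_abundance", "diversity", "metabolic")


@dataclass
class TraitMatrix:
    """Samples x traits phenotype values consumed by the genome scans.

    Each trait carries a class label (asv_abundance / diversity /
    metabolic); the class determines which permutation threshold applies.
    Missing values are allowed and handled by per-marker case deletion.
    """

    values: pd.DataFrame  # index = sample_id, columns = trait_id
    trait_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.trait_class)
        if missing:
            raise ConsistencyError(f"traits without class label: {sorted(missing)[:3]}")
        bad = {t: c for t, c in self.trait_class.items() if c not in TRAIT_CLASSES}
        if bad:
            raise ConfigError(f"unknown trait classes: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)

    def traits_of_class(self, cls: str) -> list[str]:
        return [t for t in self.values.columns if self.trait_class[t] == cls]

    def subset(self, traits: list[str]) -> "TraitMatrix":
        return TraitMatrix(
            self.values[list(traits)].copy(),
            {t: self.trait_class[t] for t in traits},
        )
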