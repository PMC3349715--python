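"""Shared domain containers for the lung-adenocarcinoma multi-omic pipeline.

All genomic coordinates are 0-based, half-open intervals. Copy number is on a
log-ratio scale (0 = diploid / normal dosage). Expression matrices are on a
log scale with genes as rows and samples as columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical subtype order; ties everywhere break in this order.
SUBTYPES = ("Bronchioid", "Magnoid", "Squamoid")

MUTATION_CLASSES = ("nonsynonymous", "splice_site", "synonymous", "other")

#: Classifications counted as "mutations" throughout the analysis.
DAMAGING_CLASSES = frozenset({"nonsynonymous", "splice_site"})

TUMOR = "tumor"
NORMAL = "normal"


@dataclass(frozen=True)
class GenomicRegion:
    """A named genomic interval (0-based, half-open).

    ``direction`` annotates recurrent amplification (+1) or deletion (-1);
    0 means unannotated. It is metadata only — the GACN procedure works on
    absolute copy number.
    """

    chromosome: str
    start: int
    end: int
    name: str
    direction: int = 0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"region {self.name}: negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"region {self.name}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.start <= position < self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class MutationTable:
    """Mutation calls plus the assay mask.

    ``calls``: long table with columns ``sample_id``, ``gene``,
    ``classification``. ``assayed``: boolean genes x samples frame; a call for
    a (gene, sample) pair implies the pair was assayed.
    """

    calls: pd.DataFrame
    assayed: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "gene", "classification"}
        missing = required - set(self.calls.columns)
        if missing:
            raise ValueError(f"mutation calls missing columns {sorted(missing)}")
        bad = set(self.calls["classification"]) - set(MUTATION_CLASSES)
        if bad:
            raise ValueError(f"unknown mutation classifications {sorted(bad)}")
        for _, row in self.calls.iterrows():
            g, s = row["gene"], row["sample_id"]
            if g in self.assayed.index and s in self.assayed.columns:
                if not bool(self.assayed.loc[g, s]):
                    raise ValueError(
                        f"mutation recorded for unassayed pair ({s}, {g})"
                    )

    @property
    def genes(self) -> list[str]:
        return list(self.assayed.index)

    @property
    def samples(self) -> list[str]:
        return list(self.assayed.columns)

    def mutant_matrix(self, classes: frozenset[str] = DAMAGING_CLASSES) -> pd.DataFrame:
        """Boolean genes x samples matrix of damaging-mutation status."""
        mat = pd.DataFrame(
            False, index=self.assayed.index, columns=self.assayed.columns
        )
        sel = self.calls[self.calls["classification"].isin(classes)]
        for gene, sub in sel.groupby("gene"):
            if gene in mat.index:
                cols = [s for s in sub["sample_id"].unique() if s in mat.columns]
                mat.loc[gene, cols] = True
        return mat

    def mutant_counts(self, classes: frozenset[str] = DAMAGING_CLASSES) -> pd.Series:
        """Per-gene number of distinct mutated samples."""
        sel = self.calls[self.calls["classification"].isin(classes)]
        return sel.groupby("gene")["sample_id"].nunique()


@dataclass
class MethylationTable:
    """MSNP site metadata with per-sample digested/undigested abundances.

    ``sites``: frame indexed by site id with columns ``chromosome``,
    ``position``, ``site_class`` ('methylation' or 'control').
    ``undigested`` / ``hpaii``: non-negative abundance matrices, sites x
    samples.
    """

    sites: pd.DataFrame
    undigested: pd.DataFrame
    hpaii: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.undigested.to_numpy() < 0).any():
            raise ValueError("negative undigested abundance")
        if (self.hpaii.to_numpy() < 0).any():
            raise ValueError("negative HpaII abundance")
        if not self.undigested.index.equals(self.hpaii.index):
            raise ValueError("undigested/hpaii site ids differ")
        if list(self.undigested.columns) != list(self.hpaii.columns):
            raise ValueError("undigested/hpaii sample ids differ")

    @property
    def methylation_site_ids(self) -> pd.Index:
        return self.sites.index[self.sites["site_class"] == "methylation"]


@dataclass
class OmicsCohort:
    """Aligned per-sample multi-omic tables for one cohort.

    Any layer may be ``None`` when the cohort was not assayed for it; sample
    ids are shared across the layers that are present.
    """

    expression: pd.DataFrame | None = None
    cn: pd.DataFrame | None = None  # columns: chromosome, position, <samples>
    mutations: MutationTable | None = None
    methylation: MethylationTable | None = None
    clinical: pd.DataFrame | None = None
    sample_roles: pd.Series | None = None  # sample -> 'tumor' | 'normal'
    sequenced_bases: pd.Series | None = None
    arms: pd.DataFrame | None = None  # arm_id, chromosome, start, end
    regions: list[GenomicRegion] = field(default_factory=list)
    gene_positions: pd.DataFrame | None = None  # gene -> chromosome, position
    signature: "ExpressionSignature | None" = None

    @property
    def tumor_ids(self) -> list[str]:
        if self.sample_roles is None:
            raise ValueError("cohort has no sample roles")
        return list(self.sample_roles.index[self.sample_roles == TUMOR])

    @property
    def normal_ids(self) -> list[str]:
        if self.sample_roles is None:
            return []
        return list(self.sample_roles.index[self.sample_roles == NORMAL])

    def cn_values(self) -> pd.DataFrame:
        """Sample columns of the CN probe table (drops coordinate columns)."""
        if self.cn is None:
            raise ValueError("cohort has no copy-number layer")
        return self.cn.drop(columns=["chromosome", "position"])


@dataclass(frozen=True)
class ExpressionSignature:
    """Two disjoint gene lists defining a mean-difference expression score."""

    overexpressed: tuple[str, ...]
    underexpressed: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.overexpressed or not self.underexpressed:
            raise ValueError("both signature gene lists must be non-empty")
        if set(self.overexpressed) & set(self.underexpressed):
            raise ValueError("signature gene lists overlap")


@dataclass
class GroundTruth:
    """Generator-side truth for a synthetic cohort."""

    subtype: pd.Series  # tumor sample -> subtype
    region_gacn: dict[str, str] = field(default_factory=dict)
    region_effect: dict[str, float] = field(default_factory=dict)
    region_direction: dict[str, int] = field(default_factory=dict)
    gene_enriched: dict[str, str] = field(default_factory=dict)


def check_labels(labels: pd.Series, require_all: bool = True) -> pd.Series:
    """Validate a subtype label series; optionally require all three subtypes."""
    bad = set(labels.dropna()) - set(SUBTYPES)
    if bad:
        raise ValueError(f"unknown subtype labels {sorted(bad)}")
    if require_all:
        present = set(labels.dropna())
        if present != set(SUBTYPES):
            raise ValueError(
                f"expected all three subtypes, found {sorted(present)}"
            )
    return labels


def median_or_nan(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    return float(np.median(v)) if v.size else float("nan")
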