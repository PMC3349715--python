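"""Synthetic multi-omic lung-adenocarcinoma cohort generator.

The generator emits cohorts with the statistical structure the downstream
analysis assumes, together with ground-truth labels, so that every stage of
the pipeline (subtype discovery, mutation association, CIN/GACN, methylation,
integration, outcomes) can be exercised and scored without patient data.

Structure emulated
------------------
* Three latent expression subtypes (Bronchioid, Magnoid, Squamoid) with
  distinct centroids: each subtype elevates its own third of the informative
  genes by ``centroid_shift`` standard deviations over iid N(0, 1) noise.
* Subtype-specific driver mutation frequencies; defaults are the reported
  discovery-cohort frequencies for EGFR, KRAS, TP53 and STK11.
* A genomewide background mutation process with per-subtype rates ordered
  Bronchioid < Squamoid < Magnoid (1:2:4).
* Arm-level copy-number noise scaled per subtype (Magnoid most unstable),
  plus recurrent regions in which one subtype carries a directional CN
  effect (the true "GACN" subtype) and the others an attenuated one.
* Optional coupling of expression to regional CN, and of driver mutations to
  focal CN / expression changes at the driver locus (integrated alterations).
* Genomewide methylation percent-change shifted per subtype relative to
  normal lung (Magnoid hypermethylated).
* Exponential survival with per-subtype baseline hazards and a per-subtype
  treatment hazard ratio (benefit in Magnoid only by default), with uniform
  censoring.

The synthetic genome has 22 autosomes of 100 Mb, split into equal p/q arms,
with 100 CN probes and 50 methylation sites per arm. All randomness flows
from a single seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    ExpressionSignature,
    GenomicRegion,
    GroundTruth,
    MutationTable,
    MethylationTable,
    NORMAL,
    OmicsCohort,
    SUBTYPES,
    TUMOR,
)

# synthetic genome geometry
N_CHROMOSOMES = 22
CHROM_LENGTH = 100_000_000
ARM_LENGTH = CHROM_LENGTH // 2
CN_PROBE_SPACING = 500_000       # 100 probes per arm
METH_SITE_SPACING = 1_000_000    # 50 sites per arm


@dataclass(frozen=True)
class TrueRegion:
    """A ground-truth recurrent CN region with its associated subtype."""

    region: GenomicRegion
    gacn_subtype: str
    direction: int  # +1 amplification, -1 deletion
    effect: float   # log-ratio magnitude in the GACN subtype


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions.

    Subtype-keyed tuples are ordered (Bronchioid, Magnoid, Squamoid).
    """

    n_tumors_per_subtype: tuple[int, int, int] = (50, 50, 50)
    n_normals: int = 30
    n_genes: int = 1200
    n_informative_genes: int = 300
    centroid_shift: float = 1.0
    expression_noise_sd: float = 1.0
    # discovery-cohort driver mutation frequencies (B, M, S)
    mutation_freqs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "EGFR": (0.37, 0.09, 0.18),
            "KRAS": (0.16, 0.30, 0.18),
            "TP53": (0.22, 0.40, 0.33),
            "STK11": (0.13, 0.22, 0.08),
        }
    )
    # genomewide non-synonymous background mutation rate per sequenced base
    background_mutation_rate: dict[str, float] = field(
        default_factory=lambda: {
            "Bronchioid": 1e-6, "Magnoid": 4e-6, "Squamoid": 2e-6,
        }
    )
    n_background_genes: int = 600
    sequenced_bases: int = 1_000_000
    # copy number
    cin_scale: dict[str, float] = field(
        default_factory=lambda: {
            "Bronchioid": 0.1, "Magnoid": 0.4, "Squamoid": 0.2,
        }
    )
    normal_cin_scale: float = 0.02
    probe_noise_sd: float = 0.1
    true_regions: list[TrueRegion] = field(default_factory=lambda: _default_regions())
    region_attenuation: float = 0.2
    cn_expr_coupling: float = 1.0
    # drivers: gene -> (cn direction, expression direction); applied with
    # probability driver_coupling_prob to mutant tumors
    driver_effects: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "EGFR": (1, 1), "KRAS": (1, 1), "TP53": (-1, 0), "STK11": (-1, -1),
        }
    )
    driver_coupling_prob: float = 0.8
    driver_cn_effect: float = 0.5
    driver_expr_effect: float = 1.5
    # methylation percent-change shift vs normal lung
    methylation_shift: dict[str, float] = field(
        default_factory=lambda: {
            "Bronchioid": 0.02, "Magnoid": 0.10, "Squamoid": 0.05,
        }
    )
    methylation_site_noise_sd: float = 0.05
    methylation_sample_sd: float = 0.02
    methylation_arms: list[str] | None = None  # restrict the shift; None = genomewide
    # survival (months); hazards per month, tuple keyed like SUBTYPES
    baseline_hazard: dict[str, float] = field(
        default_factory=lambda: {
            "Bronchioid": 0.012, "Magnoid": 0.035, "Squamoid": 0.025,
        }
    )
    treatment_hr: dict[str, float] = field(
        default_factory=lambda: {
            "Bronchioid": 1.0, "Magnoid": 0.5, "Squamoid": 1.0,
        }
    )
    treatment_fraction: float = 0.5
    censor_range: tuple[float, float] = (6.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for gene, freqs in self.mutation_freqs.items():
            if not all(0.0 <= f <= 1.0 for f in freqs):
                raise ValueError(f"mutation frequency outside [0,1] for {gene}")
        if min(self.n_tumors_per_subtype) <= 0 or self.n_normals < 0:
            raise ValueError("sample counts must be positive")
        for i, a in enumerate(self.true_regions):
            for b in self.true_regions[i + 1:]:
                if a.region.overlaps(b.region):
                    raise ValueError(
                        f"true regions {a.region.name} and {b.region.name} overlap"
                    )


def _default_regions() -> list[TrueRegion]:
    """24 non-overlapping 10-Mb regions with varied effects and directions.

    8 regions per subtype; effects cycle over 0.3-0.8 so that region effect
    size varies (needed for a meaningful CN-expression coordination trend).
    """
    regions = []
    effects = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    for i in range(24):
        if i < 22:
            chrom, start = f"chr{i + 1}", 10_000_000
        else:
            chrom, start = f"chr{i - 21}", 60_000_000
        subtype = SUBTYPES[i % 3]
        direction = 1 if (i // 3) % 2 == 0 else -1
        regions.append(
            TrueRegion(
                region=GenomicRegion(chrom, start, start + 10_000_000, f"r{i + 1:02d}",
                                     direction),
                gacn_subtype=subtype,
                direction=direction,
                effect=effects[i % len(effects)],
            )
        )
    return regions


def default_config(**overrides) -> SimulationConfig:
    """The calibrated default simulation conditions."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def default_study_configs(seed: int = 0) -> tuple[SimulationConfig, SimulationConfig]:
    """Default two-cohort study conditions: a pooled discovery cohort of 300
    tumors per subtype and an independent validation cohort of 120 per
    subtype, both with 30 normal-lung references."""
    discovery = default_config(n_tumors_per_subtype=(300, 300, 300), seed=seed)
    validation = default_config(n_tumors_per_subtype=(120, 120, 120), seed=seed + 1)
    return discovery, validation


# ---------------------------------------------------------------------------
# genome scaffolding

def make_arm_table() -> pd.DataFrame:
    rows = []
    for c in range(1, N_CHROMOSOMES + 1):
        rows.append((f"{c}p", f"chr{c}", 0, ARM_LENGTH))
        rows.append((f"{c}q", f"chr{c}", ARM_LENGTH, CHROM_LENGTH))
    return pd.DataFrame(rows, columns=["arm_id", "chromosome", "start", "end"])


def make_cn_probe_positions() -> pd.DataFrame:
    chroms, positions, ids = [], [], []
    for c in range(1, N_CHROMOSOMES + 1):
        pos = np.arange(CN_PROBE_SPACING // 2, CHROM_LENGTH, CN_PROBE_SPACING)
        chroms += [f"chr{c}"] * len(pos)
        positions += list(pos)
        ids += [f"cn_{c}_{i}" for i in range(len(pos))]
    return pd.DataFrame(
        {"chromosome": chroms, "position": positions}, index=pd.Index(ids, name="probe_id")
    )


def make_methylation_sites() -> pd.DataFrame:
    chroms, positions, ids = [], [], []
    for c in range(1, N_CHROMOSOMES + 1):
        pos = np.arange(METH_SITE_SPACING // 2, CHROM_LENGTH, METH_SITE_SPACING)
        chroms += [f"chr{c}"] * len(pos)
        positions += list(pos)
        ids += [f"ms_{c}_{i}" for i in range(len(pos))]
    df = pd.DataFrame(
        {"chromosome": chroms, "position": positions},
        index=pd.Index(ids, name="site_id"),
    )
    df["site_class"] = "methylation"
    return df


def make_gene_positions(gene_ids: list[str]) -> pd.DataFrame:
    """Genes evenly spaced along the concatenated genome."""
    n = len(gene_ids)
    genome = N_CHROMOSOMES * CHROM_LENGTH
    linear = (np.arange(n) + 0.5) * genome / n
    chrom_idx = (linear // CHROM_LENGTH).astype(int)
    pos = (linear % CHROM_LENGTH).astype(int)
    return pd.DataFrame(
        {
            "chromosome": [f"chr{c + 1}" for c in chrom_idx],
            "position": pos,
        },
        index=pd.Index(gene_ids, name="gene"),
    )


# driver loci: q arms away from the default true regions
DRIVER_POSITIONS = {
    "EGFR": ("chr7", 80_000_000),
    "KRAS": ("chr12", 80_000_000),
    "TP53": ("chr17", 80_000_000),
    "STK11": ("chr19", 80_000_000),
}


# ---------------------------------------------------------------------------
# per-layer generators (usable standalone for focused simulations)

def simulate_labels(config: SimulationConfig, prefix: str = "T") -> tuple[list[str], pd.Series]:
    """Tumor/normal sample ids and true subtype labels."""
    tumor_ids, subtypes = [], []
    for subtype, n in zip(SUBTYPES, config.n_tumors_per_subtype):
        for i in range(n):
            tumor_ids.append(f"{prefix}_{subtype[:1]}{i + 1:04d}")
            subtypes.append(subtype)
    normal_ids = [f"{prefix}_N{i + 1:04d}" for i in range(config.n_normals)]
    truth = pd.Series(subtypes, index=tumor_ids, name="subtype")
    return normal_ids, truth


def gene_ids_for(config: SimulationConfig) -> list[str]:
    """Gene id list; driver genes replace four background gene slots."""
    ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    # drivers take deterministic slots at the configured loci
    positions = make_gene_positions(ids)
    for gene, (chrom, pos) in DRIVER_POSITIONS.items():
        on_chrom = positions.index[(positions["chromosome"] == chrom)]
        if len(on_chrom) == 0:
            continue
        sub = positions.loc[on_chrom]
        slot = (sub["position"] - pos).abs().idxmin()
        ids[ids.index(slot)] = gene
    return ids


def informative_gene_map(config: SimulationConfig, gene_ids: list[str]) -> dict[str, list[str]]:
    """Split the first ``n_informative_genes`` evenly among the subtypes.

    Driver genes and genes inside the true recurrent-CN regions are never
    subtype-informative, so the centroid signal and the regional CN signal
    stay orthogonal layers (a region's expression difference then reflects
    its CN effect, not the clustering structure).
    """
    positions = make_gene_positions(gene_ids)
    in_region = pd.Series(False, index=positions.index)
    for tr in config.true_regions:
        in_region |= (
            (positions["chromosome"] == tr.region.chromosome)
            & (positions["position"] >= tr.region.start)
            & (positions["position"] < tr.region.end)
        )
    pool = [
        g for g in gene_ids
        if g not in DRIVER_POSITIONS and not bool(in_region[g])
    ]
    chosen = pool[: config.n_informative_genes]
    per = len(chosen) // 3
    return {
        SUBTYPES[0]: chosen[:per],
        SUBTYPES[1]: chosen[per: 2 * per],
        SUBTYPES[2]: chosen[2 * per: 3 * per],
    }


def simulate_expression(
    config: SimulationConfig,
    truth: pd.Series,
    normal_ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Centroid + iid Gaussian noise expression for tumors and normals."""
    gene_ids = gene_ids_for(config)
    samples = list(truth.index) + list(normal_ids)
    values = rng.normal(0.0, config.expression_noise_sd, size=(len(gene_ids), len(samples)))
    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    info = informative_gene_map(config, gene_ids)
    for subtype, genes in info.items():
        cols = truth.index[truth == subtype]
        expr.loc[genes, cols] += config.centroid_shift
    return expr


def simulate_mutations(
    config: SimulationConfig,
    truth: pd.Series,
    rng: np.random.Generator,
) -> tuple[MutationTable, pd.Series]:
    """Driver Bernoulli mutations plus Poisson background; returns the table
    and the per-sample sequenced-base counts."""
    tumor_ids = list(truth.index)
    subtype_idx = truth.map({s: i for i, s in enumerate(SUBTYPES)}).to_numpy()
    records: list[tuple[str, str, str]] = []
    for gene, freqs in config.mutation_freqs.items():
        p = np.asarray(freqs)[subtype_idx]
        hits = rng.random(len(tumor_ids)) < p
        records += [(tumor_ids[i], gene, "nonsynonymous") for i in np.nonzero(hits)[0]]
    bg_genes = [f"RG{i + 1:04d}" for i in range(config.n_background_genes)]
    rates = truth.map(config.background_mutation_rate).to_numpy()
    counts = rng.poisson(rates * config.sequenced_bases)
    for i, c in enumerate(counts):
        if c > 0:
            genes = rng.choice(config.n_background_genes, size=c, replace=True)
            records += [(tumor_ids[i], bg_genes[g], "nonsynonymous") for g in genes]
    calls = pd.DataFrame(records, columns=["sample_id", "gene", "classification"])
    all_genes = list(config.mutation_freqs) + bg_genes
    assayed = pd.DataFrame(
        True, index=pd.Index(all_genes, name="gene"), columns=tumor_ids
    )
    bases = pd.Series(float(config.sequenced_bases), index=tumor_ids, name="bases")
    return MutationTable(calls=calls, assayed=assayed), bases


def simulate_cn(
    config: SimulationConfig,
    truth: pd.Series,
    normal_ids: list[str],
    rng: np.random.Generator,
    mutant: pd.DataFrame | None = None,
    driver_hit: pd.DataFrame | None = None,
    gene_positions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Probe-level CN: arm Gaussian baseline x cin_scale + region and driver
    effects + probe noise. Returns the wide probe table."""
    probes = make_cn_probe_positions()
    arms = make_arm_table()
    samples = list(truth.index) + list(normal_ids)
    scale = np.array(
        [config.cin_scale[truth[s]] if s in truth.index else config.normal_cin_scale
         for s in samples]
    )
    n_probes = len(probes)
    # per-arm baseline per sample
    arm_effects = rng.normal(0.0, 1.0, size=(len(arms), len(samples))) * scale
    probe_arm = np.empty(n_probes, dtype=int)
    for ai, arm in arms.iterrows():
        mask = (
            (probes["chromosome"] == arm["chromosome"])
            & (probes["position"] >= arm["start"])
            & (probes["position"] < arm["end"])
        ).to_numpy()
        probe_arm[mask] = ai
    values = arm_effects[probe_arm, :] + rng.normal(
        0.0, config.probe_noise_sd, size=(n_probes, len(samples))
    )
    cn = pd.DataFrame(values, index=probes.index, columns=samples)
    # recurrent region effects (tumors only)
    is_tumor = np.array([s in truth.index for s in samples])
    for tr in config.true_regions:
        pmask = (
            (probes["chromosome"] == tr.region.chromosome)
            & (probes["position"] >= tr.region.start)
            & (probes["position"] < tr.region.end)
        ).to_numpy()
        eff = np.zeros(len(samples))
        for j, s in enumerate(samples):
            if not is_tumor[j]:
                continue
            if truth[s] == tr.gacn_subtype:
                eff[j] = tr.direction * tr.effect
            else:
                eff[j] = tr.direction * tr.effect * config.region_attenuation
        cn.loc[pmask, :] += eff
    # driver focal CN effects in mutant tumors
    if driver_hit is not None:
        for gene, (cn_dir, _) in config.driver_effects.items():
            if cn_dir == 0 or gene not in driver_hit.index:
                continue
            chrom, pos = DRIVER_POSITIONS[gene]
            pmask = (
                (probes["chromosome"] == chrom)
                & (probes["position"] >= pos - 1_000_000)
                & (probes["position"] < pos + 1_000_000)
            ).to_numpy()
            hit_samples = [
                s for s in samples
                if s in driver_hit.columns and bool(driver_hit.loc[gene, s])
            ]
            cn.loc[pmask, hit_samples] += cn_dir * config.driver_cn_effect
    out = probes.copy()
    return pd.concat([out, cn], axis=1)


def simulate_methylation(
    config: SimulationConfig,
    truth: pd.Series,
    normal_ids: list[str],
    rng: np.random.Generator,
) -> MethylationTable:
    """Abundance pairs whose percent-change recovers the configured shifts."""
    sites = make_methylation_sites()
    arms = make_arm_table()
    samples = list(truth.index) + list(normal_ids)
    base = rng.uniform(0.2, 0.6, size=len(sites))  # per-site baseline methylation
    shift = np.array(
        [config.methylation_shift.get(truth[s], 0.0) if s in truth.index else 0.0
         for s in samples]
    )
    site_shift_mask = np.ones(len(sites), dtype=bool)
    if config.methylation_arms is not None:
        site_shift_mask[:] = False
        for arm_id in config.methylation_arms:
            arm = arms.set_index("arm_id").loc[arm_id]
            site_shift_mask |= (
                (sites["chromosome"] == arm["chromosome"])
                & (sites["position"] >= arm["start"])
                & (sites["position"] < arm["end"])
            ).to_numpy()
    sample_offset = rng.normal(0.0, config.methylation_sample_sd, size=len(samples))
    value = (
        base[:, None]
        + np.where(site_shift_mask[:, None], shift[None, :], 0.0)
        + sample_offset[None, :]
        + rng.normal(0.0, config.methylation_site_noise_sd, size=(len(sites), len(samples)))
    )
    value = np.clip(value, 0.01, 0.99)
    undigested = np.full_like(value, 100.0)
    hpaii = undigested * (1.0 - value)
    und = pd.DataFrame(undigested, index=sites.index, columns=samples)
    hpa = pd.DataFrame(hpaii, index=sites.index, columns=samples)
    return MethylationTable(sites=sites, undigested=und, hpaii=hpa)


def simulate_clinical(
    config: SimulationConfig,
    truth: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential survival with subtype hazards and treatment interaction."""
    tumor_ids = list(truth.index)
    n = len(tumor_ids)
    treated = rng.random(n) < config.treatment_fraction
    hazards = np.array(
        [
            config.baseline_hazard[truth[s]]
            * (config.treatment_hr[truth[s]] if treated[i] else 1.0)
            for i, s in enumerate(tumor_ids)
        ]
    )
    event_time = rng.exponential(1.0 / hazards)
    censor_time = rng.uniform(*config.censor_range, size=n)
    followup = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    stage_probs = {
        "Bronchioid": (0.7, 0.2, 0.1),
        "Magnoid": (0.5, 0.3, 0.2),
        "Squamoid": (0.5, 0.3, 0.2),
    }
    stages = [
        rng.choice(["I", "II", "III"], p=stage_probs[truth[s]]) for s in tumor_ids
    ]
    age = rng.normal(65.0, 8.0, size=n).round(1)
    return pd.DataFrame(
        {
            "followup_months": followup,
            "event": event,
            "treatment_arm": np.where(treated, "chemo", "observation"),
            "stage": stages,
            "age": age,
        },
        index=pd.Index(tumor_ids, name="sample_id"),
    )


def _default_signature(config: SimulationConfig) -> ExpressionSignature:
    """Gefitinib-sensitivity analogue: Bronchioid-informative genes over,
    Magnoid-informative genes under."""
    info = informative_gene_map(config, gene_ids_for(config))
    return ExpressionSignature(
        overexpressed=tuple(info["Bronchioid"][:10]),
        underexpressed=tuple(info["Magnoid"][:10]),
    )


# ---------------------------------------------------------------------------
# full cohort

def simulate_cohort(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    prefix: str = "T",
) -> tuple[OmicsCohort, GroundTruth]:
    """Generate a complete multi-omic cohort plus ground truth.

    ``seed`` overrides ``config.seed``; all layers draw from one generator in
    a fixed order, so a fixed (config, seed) pair is bitwise reproducible.
    """
    config = config or default_config()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    normal_ids, truth = simulate_labels(config, prefix=prefix)

    expression = simulate_expression(config, truth, normal_ids, rng)
    mutations, bases = simulate_mutations(config, truth, rng)
    mutant = mutations.mutant_matrix()
    # driver coupling: which mutant tumors also get the focal CN/expr effect
    driver_hit = pd.DataFrame(
        False, index=pd.Index(list(config.driver_effects), name="gene"),
        columns=list(truth.index),
    )
    for gene in config.driver_effects:
        if gene in mutant.index:
            coupled = rng.random(len(truth)) < config.driver_coupling_prob
            driver_hit.loc[gene] = mutant.loc[gene, truth.index].to_numpy() & coupled
    cn = simulate_cn(config, truth, normal_ids, rng, driver_hit=driver_hit)
    methylation = simulate_methylation(config, truth, normal_ids, rng)
    clinical = simulate_clinical(config, truth, rng)

    gene_positions = make_gene_positions(list(expression.index))
    for gene, (chrom, pos) in DRIVER_POSITIONS.items():
        if gene in gene_positions.index:
            gene_positions.loc[gene, ["chromosome", "position"]] = (chrom, pos)

    # couple expression to regional CN
    if config.cn_expr_coupling != 0.0:
        cn_vals = cn.drop(columns=["chromosome", "position"])
        for tr in config.true_regions:
            pmask = (
                (cn["chromosome"] == tr.region.chromosome)
                & (cn["position"] >= tr.region.start)
                & (cn["position"] < tr.region.end)
            )
            region_cn = cn_vals.loc[pmask.to_numpy()].median(axis=0)
            genes = gene_positions.index[
                (gene_positions["chromosome"] == tr.region.chromosome)
                & (gene_positions["position"] >= tr.region.start)
                & (gene_positions["position"] < tr.region.end)
            ]
            genes = [g for g in genes if g in expression.index]
            if genes:
                expression.loc[genes] = (
                    expression.loc[genes]
                    + config.cn_expr_coupling * region_cn[expression.columns].to_numpy()
                )

    # driver expression effects
    for gene, (_, expr_dir) in config.driver_effects.items():
        if expr_dir != 0 and gene in expression.index:
            hit_cols = driver_hit.columns[driver_hit.loc[gene]]
            expression.loc[gene, hit_cols] += expr_dir * config.driver_expr_effect

    roles = pd.Series(
        [TUMOR] * len(truth) + [NORMAL] * len(normal_ids),
        index=list(truth.index) + list(normal_ids),
        name="role",
    )
    regions = [tr.region for tr in config.true_regions]
    cohort = OmicsCohort(
        expression=expression,
        cn=cn,
        mutations=mutations,
        methylation=methylation,
        clinical=clinical,
        sample_roles=roles,
        sequenced_bases=bases,
        arms=make_arm_table(),
        regions=regions,
        gene_positions=gene_positions,
        signature=_default_signature(config),
    )
    enriched = {
        gene: SUBTYPES[int(np.argmax(freqs))]
        for gene, freqs in config.mutation_freqs.items()
    }
    truth_obj = GroundTruth(
        subtype=truth,
        region_gacn={tr.region.name: tr.gacn_subtype for tr in config.true_regions},
        region_effect={tr.region.name: tr.effect for tr in config.true_regions},
        region_direction={tr.region.name: tr.direction for tr in config.true_regions},
        gene_enriched=enriched,
    )
    return cohort, truth_obj
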