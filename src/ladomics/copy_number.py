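"""Copy-number analysis: CIN statistic, regional CN, GACN discovery and
validation, and CN-expression coordination.

CIN is a per-tumor chromosomal-instability summary: the median over
chromosome arms of the absolute arm-level copy number, where arm CN is the
median of probe log-ratios on the arm. Zero means a copy-neutral genome.

GACN ("greatest absolute copy number"): for each recurrent region whose CN
differs among subtypes (Kruskal-Wallis, BH-adjusted), the one-vs-rest
subtype partition with the greatest absolute difference in median CN is
taken, and the side of that partition farther from zero names the subtype.
Validation tests, one-sided, whether absolute region CN is greater in the
pre-registered GACN subtype in an independent cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GenomicRegion, SUBTYPES, check_labels
from .stats_core import (
    ONE_SIDED_GREATER,
    TWO_SIDED,
    TestResult,
    bh_adjust,
    kruskal_wallis,
    spearman_corr,
    wilcoxon_rank_sum,
)

log = logging.getLogger("ladomics.copy_number")

MIN_ARM_PROBES = 5


def _sample_columns(probes: pd.DataFrame) -> list[str]:
    return [c for c in probes.columns if c not in ("chromosome", "position")]


def bin_probes(probes: pd.DataFrame, bin_size: int) -> pd.DataFrame:
    """Median-summarise probes into fixed genomic bins per chromosome.

    Empty bins are omitted; the binned probe id encodes chromosome and bin
    start, with ``position`` at the bin start.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    samples = _sample_columns(probes)
    df = probes.copy()
    df["_bin"] = (df["position"] // bin_size) * bin_size
    grouped = df.groupby(["chromosome", "_bin"], sort=True)
    rows = grouped[samples].median()
    out = rows.reset_index().rename(columns={"_bin": "position"})
    out.index = pd.Index(
        [f"{c}:{p}" for c, p in zip(out["chromosome"], out["position"])],
        name="probe_id",
    )
    return out[["chromosome", "position"] + samples]


def cin(
    probes: pd.DataFrame,
    arms: pd.DataFrame,
    min_probes: int = MIN_ARM_PROBES,
) -> pd.Series:
    """Per-sample CIN: median over arms of |median probe CN on the arm|."""
    samples = _sample_columns(probes)
    arm_medians = []
    for _, arm in arms.iterrows():
        mask = (
            (probes["chromosome"] == arm["chromosome"])
            & (probes["position"] >= arm["start"])
            & (probes["position"] < arm["end"])
        )
        if int(mask.sum()) < min_probes:
            continue
        arm_medians.append(probes.loc[mask, samples].median(axis=0))
    if not arm_medians:
        raise ValueError(f"no arm has >= {min_probes} probes")
    arm_cn = pd.DataFrame(arm_medians)  # arms x samples
    return arm_cn.abs().median(axis=0).rename("cin")


def compare_cin(cin_values: pd.Series, labels: pd.Series, stage: str) -> TestResult:
    """Subtype comparison of CIN.

    ``discovery``: Kruskal-Wallis across the three subtypes (two-sided).
    ``validation``: one-sided Wilcoxon rank-sum of Magnoid versus the rest
    (alternative: Magnoid CIN greater).
    """
    check_labels(labels)
    common = [s for s in cin_values.index if s in labels.index]
    v = cin_values[common]
    lab = labels[common]
    if stage == "discovery":
        return kruskal_wallis([v[lab == s].to_numpy() for s in SUBTYPES])
    if stage == "validation":
        return wilcoxon_rank_sum(
            v[lab == "Magnoid"].to_numpy(),
            v[lab != "Magnoid"].to_numpy(),
            ONE_SIDED_GREATER,
        )
    raise ValueError(f"unknown stage {stage!r}")


def region_cn(probes: pd.DataFrame, regions: list[GenomicRegion]) -> pd.DataFrame:
    """Per-sample median CN within each region (half-open probe overlap).

    Regions without probes are excluded with a warning. Returns a regions x
    samples frame indexed by region name.
    """
    samples = _sample_columns(probes)
    rows, names = [], []
    for region in regions:
        mask = (
            (probes["chromosome"] == region.chromosome)
            & (probes["position"] >= region.start)
            & (probes["position"] < region.end)
        )
        if not mask.any():
            log.warning("region %s has no probes; excluded", region.name)
            continue
        rows.append(probes.loc[mask, samples].median(axis=0))
        names.append(region.name)
    return pd.DataFrame(rows, index=pd.Index(names, name="region"))


def gacn_discovery(
    region_values: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Subtype association and GACN assignment per region.

    Kruskal-Wallis across subtypes on per-sample region medians, BH across
    regions; regions with q < alpha get a GACN subtype via the maximal
    one-vs-rest |median difference| partition.
    """
    check_labels(labels)
    common = [s for s in region_values.columns if s in labels.index]
    lab = labels[common]
    rows = []
    for name, vals in region_values[common].iterrows():
        groups = {s: vals[lab == s].to_numpy() for s in SUBTYPES}
        kw = kruskal_wallis(list(groups.values()))
        row = {"region": name, "discovery_p": kw.p_value}
        for s in SUBTYPES:
            row[f"median_{s}"] = float(np.median(groups[s]))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("region")
    out["q_value"] = bh_adjust(out["discovery_p"].to_numpy())
    out["gacn_subtype"] = None
    out["gacn_flag"] = ""
    for name in out.index[out["q_value"] < alpha]:
        vals = region_values.loc[name, common]
        diffs = {}
        side_medians = {}
        for s in SUBTYPES:
            in_med = float(np.median(vals[(lab == s).to_numpy()]))
            out_med = float(np.median(vals[(lab != s).to_numpy()]))
            diffs[s] = abs(in_med - out_med)
            side_medians[s] = (in_med, out_med)
        best = max(diffs.values())
        winners = [s for s in SUBTYPES if np.isclose(diffs[s], best)]
        flag = "partition tie broken by subtype order" if len(winners) > 1 else ""
        winner = winners[0]
        in_med, out_med = side_medians[winner]
        if abs(in_med) >= abs(out_med):
            gacn = winner
        else:
            # the two-subtype side is farther from zero; name its more
            # extreme member and flag the ambiguity
            pair = [s for s in SUBTYPES if s != winner]
            pair_meds = {
                s: abs(float(np.median(vals[(lab == s).to_numpy()]))) for s in pair
            }
            gacn = max(pair, key=lambda s: (pair_meds[s], s))
            flag = (flag + "; " if flag else "") + "rest side farther from zero"
        out.loc[name, "gacn_subtype"] = gacn
        out.loc[name, "gacn_flag"] = flag
    return out


def gacn_validation(
    region_values: pd.DataFrame,
    labels: pd.Series,
    discovered: pd.DataFrame,
) -> pd.DataFrame:
    """One-sided validation of discovered GACN subtypes in a new cohort.

    Per region: Wilcoxon rank-sum on |per-sample region CN|, GACN subtype
    versus the rest; also records the directional confirmation indicator
    (GACN subtype's median |CN| greater, regardless of significance).
    """
    check_labels(labels)
    common = [s for s in region_values.columns if s in labels.index]
    lab = labels[common]
    out = discovered.copy()
    out["validation_p"] = np.nan
    out["confirmed_direction"] = False
    for name, row in discovered.iterrows():
        gacn = row["gacn_subtype"]
        if gacn is None or (isinstance(gacn, float) and np.isnan(gacn)):
            continue
        if name not in region_values.index:
            out.loc[name, "gacn_flag"] = (
                str(out.loc[name, "gacn_flag"]) + "; absent in validation"
            ).lstrip("; ")
            continue
        vals = region_values.loc[name, common].abs()
        x = vals[(lab == gacn).to_numpy()].to_numpy()
        y = vals[(lab != gacn).to_numpy()].to_numpy()
        res = wilcoxon_rank_sum(x, y, ONE_SIDED_GREATER)
        out.loc[name, "validation_p"] = res.p_value
        out.loc[name, "confirmed_direction"] = bool(
            np.median(x) > np.median(y)
        )
    return out


def cn_expression_coordination(
    region_values: pd.DataFrame,
    discovered: pd.DataFrame,
    expression: pd.DataFrame,
    labels: pd.Series,
    gene_positions: pd.DataFrame,
    regions: list[GenomicRegion],
) -> tuple[pd.DataFrame, TestResult]:
    """Per-region CN difference vs expression difference, GACN subtype
    against the rest, with a Spearman test of coordination across regions.

    cn_diff = median region CN in the GACN subtype minus the rest;
    expr_diff = median over region genes of the same subtype difference in
    median expression. Regions with no genes are excluded with a warning.
    """
    check_labels(labels)
    common = [s for s in region_values.columns if s in labels.index and s in expression.columns]
    lab = labels[common]
    region_map = {r.name: r for r in regions}
    rows = []
    for name, row in discovered.iterrows():
        gacn = row["gacn_subtype"]
        if gacn is None or (isinstance(gacn, float) and np.isnan(gacn)):
            continue
        if name not in region_values.index or name not in region_map:
            continue
        region = region_map[name]
        vals = region_values.loc[name, common]
        in_mask = (lab == gacn).to_numpy()
        cn_diff = float(np.median(vals[in_mask]) - np.median(vals[~in_mask]))
        genes = gene_positions.index[
            (gene_positions["chromosome"] == region.chromosome)
            & (gene_positions["position"] >= region.start)
            & (gene_positions["position"] < region.end)
        ]
        genes = [g for g in genes if g in expression.index]
        if not genes:
            log.warning("region %s has no genes; excluded from coordination", name)
            continue
        expr = expression.loc[genes, common]
        gene_diffs = (
            expr.loc[:, in_mask].median(axis=1) - expr.loc[:, ~in_mask].median(axis=1)
        )
        rows.append(
            {
                "region": name,
                "gacn_subtype": gacn,
                "cn_diff": cn_diff,
                "expr_diff": float(gene_diffs.median()),
                "n_genes": len(genes),
            }
        )
    table = pd.DataFrame(rows).set_index("region") if rows else pd.DataFrame(
        columns=["gacn_subtype", "cn_diff", "expr_diff", "n_genes"]
    )
    if len(table) >= 3:
        res = spearman_corr(table["cn_diff"].to_numpy(), table["expr_diff"].to_numpy())
    else:
        res = TestResult(float("nan"), float("nan"), TWO_SIDED, (len(table),),
                         flag="too few regions")
    return table, res
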