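"""MSNP methylation quantification and subtype comparisons.

Methylation at an HpaII site is quantified as the percent change of the
digested relative to the undigested DNA abundance,
``(undigested - hpaii) / undigested``: 1 when no digested signal remains,
0 when digested equals undigested; larger values mean more methylation.
Values are left unclamped — noisy abundances can push them slightly outside
[0, 1] — and sites whose undigested abundance falls below a floor (default:
its 1st percentile) are treated as missing rather than divided through.

Comparisons: genomewide per-sample medians (Kruskal-Wallis across the three
subtypes), per-site one-sided rank-sum contrasts with BH correction, and
per-chromosome-arm hypermethylated-site proportions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MethylationTable, SUBTYPES, check_labels
from .stats_core import TestResult, bh_adjust, kruskal_wallis

log = logging.getLogger("ladomics.methylation")

MIN_SITES_PER_SAMPLE = 10
ARM_MIN_SITES = 4


def quantify_methylation(
    table: MethylationTable,
    min_undigested: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent-change methylation matrix for the methylation-class sites.

    Returns ``(values, sites)`` where ``values`` is sites x samples and
    ``sites`` the matching coordinate frame. Control sites are excluded from
    the matrix (retained in ``table`` for QC). Entries with undigested
    abundance below ``min_undigested`` (default: 1st percentile of the
    undigested abundances) are missing; zero-undigested entries are always
    missing and counted in the log.
    """
    site_ids = table.methylation_site_ids
    und = table.undigested.loc[site_ids].to_numpy(dtype=float)
    hpa = table.hpaii.loc[site_ids].to_numpy(dtype=float)
    if min_undigested is None:
        positive = und[und > 0]
        min_undigested = float(np.percentile(positive, 1)) if positive.size else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (und - hpa) / und
    bad = (und <= 0) | (und < min_undigested)
    n_zero = int((und <= 0).sum())
    if n_zero:
        log.info("%d zero-undigested entries set to missing", n_zero)
    values[bad] = np.nan
    out = pd.DataFrame(values, index=site_ids, columns=table.undigested.columns)
    return out, table.sites.loc[site_ids]


def genomewide_comparison(
    values: pd.DataFrame,
    labels: pd.Series,
    min_sites: int = MIN_SITES_PER_SAMPLE,
) -> tuple[pd.Series, TestResult, float]:
    """Per-sample median methylation and its subtype Kruskal-Wallis test.

    ``labels`` covers tumors; samples absent from it are treated as normal
    lung and summarised alongside (their median of medians is returned).
    """
    counts = values.notna().sum(axis=0)
    if (counts < min_sites).any():
        bad = counts.index[counts < min_sites][0]
        raise ValueError(f"sample {bad!r} has < {min_sites} measured sites")
    medians = values.median(axis=0, skipna=True).rename("median_methylation")
    tumor = [s for s in medians.index if s in labels.index]
    lab = labels[tumor]
    check_labels(lab)
    kw = kruskal_wallis(
        [medians[lab.index[lab == s]].to_numpy() for s in SUBTYPES]
    )
    normals = [s for s in medians.index if s not in labels.index]
    normal_median = float(medians[normals].median()) if normals else float("nan")
    return medians, kw, normal_median


def per_site_differential(
    values: pd.DataFrame,
    class_a: list[str],
    class_b: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided per-site rank-sum contrast: class_a greater than class_b.

    Vectorised Wilcoxon rank-sum (normal approximation with tie correction)
    per site, BH across sites; ``significant`` marks q < alpha. A class with
    fewer than 2 samples is refused (degenerate contrast).
    """
    if len(class_a) < 2 or len(class_b) < 2:
        raise ValueError("each class needs >= 2 samples for a site-level contrast")
    a = values[class_a].to_numpy(dtype=float)
    b = values[class_b].to_numpy(dtype=float)
    res = stats.mannwhitneyu(
        a, b, axis=1, alternative="greater", method="asymptotic",
        nan_policy="omit",
    )
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # constant sites: no evidence
    out = pd.DataFrame(
        {
            "statistic": np.asarray(res.statistic, dtype=float),
            "p_value": p,
        },
        index=values.index,
    )
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < alpha
    return out


def arm_hypermethylation_profile(
    per_site: pd.DataFrame,
    sites: pd.DataFrame,
    arms: pd.DataFrame,
    min_sites: int = ARM_MIN_SITES,
) -> pd.DataFrame:
    """Per-arm proportion of significantly hypermethylated sites.

    Arms with fewer than ``min_sites`` tested sites are omitted.
    """
    rows = []
    for _, arm in arms.iterrows():
        mask = (
            (sites["chromosome"] == arm["chromosome"])
            & (sites["position"] >= arm["start"])
            & (sites["position"] < arm["end"])
        )
        ids = sites.index[mask]
        tested = [i for i in ids if i in per_site.index]
        if len(tested) < min_sites:
            continue
        n_sig = int(per_site.loc[tested, "significant"].sum())
        rows.append(
            {
                "arm_id": arm["arm_id"],
                "n_sites": len(tested),
                "n_hypermethylated": n_sig,
                "proportion": n_sig / len(tested),
            }
        )
    return pd.DataFrame(rows).set_index("arm_id")
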