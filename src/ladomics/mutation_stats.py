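"""Subtype-mutation association with the two-stage discovery/validation
design, plus genomewide mutation rates.

Discovery: per gene, a 2x3 exact test (mutant/wildtype x subtype) over
assayed samples; genes passing the two-sided gate (default P < 0.10) are
annotated with the subtype of greatest mutation frequency. Validation: for
each annotated gene, a one-sided 2x2 exact test in an independent cohort of
the pre-registered enriched subtype versus the other two. Denominators are
per-gene assayed counts, never cohort size.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import DAMAGING_CLASSES, MutationTable, SUBTYPES, check_labels
from .stats_core import (
    ONE_SIDED_GREATER,
    bh_adjust,
    bootstrap_ci,
    fisher_exact,
    kruskal_wallis,
)

log = logging.getLogger("ladomics.mutations")

DISCOVERY_GATE = 0.10


def filter_testable_genes(
    mutations: MutationTable, min_mutant_patients: int = 5
) -> list[str]:
    """Genes mutated in at least ``min_mutant_patients`` distinct patients."""
    if min_mutant_patients < 1:
        raise ValueError("min_mutant_patients must be >= 1")
    counts = mutations.mutant_counts()
    return sorted(counts.index[counts >= min_mutant_patients])


def _gene_subtype_counts(
    mutations: MutationTable, labels: pd.Series, gene: str
) -> pd.DataFrame | None:
    """Per-subtype assayed/mutant counts for one gene (assayed samples only)."""
    if gene not in mutations.assayed.index:
        return None
    assayed = mutations.assayed.loc[gene]
    samples = [s for s in labels.index if s in assayed.index and bool(assayed[s])]
    if not samples:
        return None
    mutant_samples = set(
        mutations.calls.loc[
            (mutations.calls["gene"] == gene)
            & mutations.calls["classification"].isin(DAMAGING_CLASSES),
            "sample_id",
        ]
    )
    rows = []
    for subtype in SUBTYPES:
        members = [s for s in samples if labels[s] == subtype]
        n_mut = sum(s in mutant_samples for s in members)
        rows.append((subtype, len(members), n_mut))
    return pd.DataFrame(rows, columns=["subtype", "n_assayed", "n_mutant"]).set_index(
        "subtype"
    )


def discovery_association(
    mutations: MutationTable,
    labels: pd.Series,
    genes: list[str],
    gate: float = DISCOVERY_GATE,
) -> pd.DataFrame:
    """Two-sided 2x3 exact association of mutation and subtype per gene.

    Returns one row per tested gene with per-subtype counts/frequencies,
    the discovery p, BH q across tested genes, and — for genes passing the
    gate — the enriched subtype (greatest mutation frequency).
    """
    check_labels(labels)
    rows = []
    for gene in genes:
        counts = _gene_subtype_counts(mutations, labels, gene)
        if counts is None or counts["n_assayed"].sum() == 0:
            log.warning("gene %s absent from mutation table; skipped", gene)
            continue
        table = np.array(
            [
                counts["n_mutant"].to_numpy(),
                (counts["n_assayed"] - counts["n_mutant"]).to_numpy(),
            ]
        )
        res = fisher_exact(table, "two_sided")
        freqs = counts["n_mutant"] / counts["n_assayed"].replace(0, np.nan)
        row = {"gene": gene, "discovery_p": res.p_value}
        for subtype in SUBTYPES:
            row[f"n_assayed_{subtype}"] = int(counts.loc[subtype, "n_assayed"])
            row[f"n_mutant_{subtype}"] = int(counts.loc[subtype, "n_mutant"])
            row[f"freq_{subtype}"] = float(freqs[subtype])
        row["enriched_subtype"] = (
            str(freqs.idxmax()) if res.p_value < gate else None
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["discovery_p"].to_numpy())
    return out


def validation_association(
    mutations: MutationTable,
    labels: pd.Series,
    summaries: pd.DataFrame,
) -> pd.DataFrame:
    """One-sided validation of pre-registered enriched subtypes.

    For each gene with an ``enriched_subtype`` from discovery, tests (in the
    independent cohort) whether the enriched subtype's mutation frequency is
    greater than that of the other subtypes pooled; the direction is used as
    registered even if validation frequencies reverse.
    """
    check_labels(labels)
    out = summaries.copy()
    out["validation_p"] = np.nan
    out["validation_flag"] = ""
    tested_idx = []
    pvals = []
    for idx, row in out.iterrows():
        enriched = row["enriched_subtype"]
        if enriched is None or (isinstance(enriched, float) and np.isnan(enriched)):
            continue
        counts = _gene_subtype_counts(mutations, labels, row["gene"])
        if counts is None:
            out.loc[idx, "validation_flag"] = "gene not assayed in validation"
            continue
        if counts.loc[enriched, "n_assayed"] == 0:
            out.loc[idx, "validation_flag"] = "enriched subtype absent in validation"
            continue
        rest = [s for s in SUBTYPES if s != enriched]
        a = int(counts.loc[enriched, "n_mutant"])
        b = int(counts.loc[rest, "n_mutant"].sum())
        table = np.array(
            [
                [a, b],
                [
                    int(counts.loc[enriched, "n_assayed"]) - a,
                    int(counts.loc[rest, "n_assayed"].sum()) - b,
                ],
            ]
        )
        res = fisher_exact(table, ONE_SIDED_GREATER)
        out.loc[idx, "validation_p"] = res.p_value
        for subtype in SUBTYPES:
            out.loc[idx, f"val_n_assayed_{subtype}"] = int(
                counts.loc[subtype, "n_assayed"]
            )
            out.loc[idx, f"val_n_mutant_{subtype}"] = int(
                counts.loc[subtype, "n_mutant"]
            )
        tested_idx.append(idx)
        pvals.append(res.p_value)
    if tested_idx:
        out.loc[tested_idx, "validation_q"] = bh_adjust(np.asarray(pvals))
    return out


def genomewide_mutation_rate(
    mutations: MutationTable,
    sequenced_bases: pd.Series,
    labels: pd.Series,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame, "TestResult"]:
    """Per-sample non-synonymous mutation rate and per-subtype summary.

    Rate = (# non-synonymous mutations) / (# sequenced bases) per sample.
    Subtype medians are compared by Kruskal-Wallis; per-subtype bootstrap
    percentile CIs of the median use ``n_bootstrap`` replicates.
    """
    check_labels(labels)
    nonsyn = mutations.calls[mutations.calls["classification"] == "nonsynonymous"]
    per_sample = nonsyn.groupby("sample_id").size()
    samples = []
    for s in labels.index:
        if s not in sequenced_bases.index or not sequenced_bases[s] > 0:
            log.warning("sample %s lacks a sequenced-base count; excluded", s)
            continue
        samples.append(s)
    rates = pd.Series(
        [per_sample.get(s, 0) / sequenced_bases[s] for s in samples],
        index=samples,
        name="mutation_rate",
        dtype=float,
    )
    groups = [rates[labels[rates.index] == s].to_numpy() for s in SUBTYPES]
    kw = kruskal_wallis(groups)
    rows = []
    rng = np.random.default_rng(seed)
    for subtype, values in zip(SUBTYPES, groups):
        lo, hi = bootstrap_ci(values, "median", n_reps=n_bootstrap, seed=rng)
        rows.append(
            {
                "subtype": subtype,
                "n": len(values),
                "median_rate": float(np.median(values)),
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
    return rates, pd.DataFrame(rows).set_index("subtype"), kw
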