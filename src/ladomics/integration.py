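"""Integrated per-gene alteration calls and subtype enrichment.

Each tumor x gene pair is trichotomised on three axes: mutation status
(mutant / wildtype / not assayed), gene-level copy number (amplified /
neutral / deleted, from the median log-ratio of probes around the gene's
genomic position), and expression (over / normal / under, from cohort
quantiles, default tertiles). Enrichment of a conjunction of states (e.g.
mutant AND amplified AND over) across the three subtypes is tested with a
2x3 exact test over samples evaluable on every referenced axis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    GenomicRegion,
    MutationTable,
    SUBTYPES,
    check_labels,
)
from .stats_core import TestResult, fisher_exact

log = logging.getLogger("ladomics.integration")

AMP_THRESHOLD = 0.3
DEL_THRESHOLD = -0.3
GENE_CN_FLANK = 100_000
OVER_QUANTILE = 2.0 / 3.0
UNDER_QUANTILE = 1.0 / 3.0

MISSING = "missing"


def call_gene_cn(
    probes: pd.DataFrame,
    gene_position: GenomicRegion,
    amp_thresh: float = AMP_THRESHOLD,
    del_thresh: float = DEL_THRESHOLD,
    flank: int = GENE_CN_FLANK,
) -> pd.Series:
    """Amplified/neutral/deleted call per sample at a gene locus.

    Uses the median CN of probes within the gene interval extended by
    ``flank`` on both sides; no probes in the window -> missing.
    """
    if not amp_thresh > 0 > del_thresh:
        raise ValueError("need amp_thresh > 0 > del_thresh")
    samples = [c for c in probes.columns if c not in ("chromosome", "position")]
    lo = max(0, gene_position.start - flank)
    hi = gene_position.end + flank
    mask = (
        (probes["chromosome"] == gene_position.chromosome)
        & (probes["position"] >= lo)
        & (probes["position"] < hi)
    )
    if not mask.any():
        return pd.Series(MISSING, index=samples, name="cn_call")
    med = probes.loc[mask, samples].median(axis=0)
    call = pd.Series("neutral", index=samples, name="cn_call")
    call[med > amp_thresh] = "amplified"
    call[med < del_thresh] = "deleted"
    call[med.isna()] = MISSING
    return call


def call_gene_expression(
    expression: pd.DataFrame,
    gene: str,
    over_q: float = OVER_QUANTILE,
    under_q: float = UNDER_QUANTILE,
) -> pd.Series:
    """Over/normal/under call per sample from cohort expression quantiles."""
    if not 0.0 < under_q < over_q < 1.0:
        raise ValueError("need 0 < under_q < over_q < 1")
    if gene not in expression.index:
        return pd.Series(MISSING, index=expression.columns, name="expr_call")
    values = expression.loc[gene]
    lo = values.quantile(under_q)
    hi = values.quantile(over_q)
    call = pd.Series("normal", index=expression.columns, name="expr_call")
    if hi > lo:  # constant gene -> everything normal
        call[values > hi] = "over"
        call[values < lo] = "under"
    call[values.isna()] = MISSING
    return call


def build_integrated_calls(
    gene: str,
    mutations: MutationTable | None,
    probes: pd.DataFrame | None,
    expression: pd.DataFrame | None,
    gene_position: GenomicRegion | None,
    samples: list[str],
    **call_kwargs,
) -> pd.DataFrame:
    """Per-sample trichotomised calls for one gene across the three axes."""
    out = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    out["gene"] = gene
    if mutations is not None and gene in mutations.assayed.index:
        mutant = mutations.mutant_matrix().loc[gene]
        assayed = mutations.assayed.loc[gene]
        status = []
        for s in samples:
            if s not in assayed.index or not bool(assayed.get(s, False)):
                status.append("not_assayed")
            else:
                status.append("mutant" if bool(mutant.get(s, False)) else "wildtype")
        out["mutation"] = status
    else:
        out["mutation"] = "not_assayed"
    if probes is not None and gene_position is not None:
        cn_call = call_gene_cn(probes, gene_position, **{
            k: v for k, v in call_kwargs.items()
            if k in ("amp_thresh", "del_thresh", "flank")
        })
        out["cn_call"] = cn_call.reindex(samples).fillna(MISSING)
    else:
        out["cn_call"] = MISSING
    if expression is not None:
        expr_call = call_gene_expression(expression, gene, **{
            k: v for k, v in call_kwargs.items() if k in ("over_q", "under_q")
        })
        out["expr_call"] = expr_call.reindex(samples).fillna(MISSING)
    else:
        out["expr_call"] = MISSING
    return out


_AXIS_MISSING = {
    "mutation": "not_assayed",
    "cn_call": MISSING,
    "expr_call": MISSING,
}


def integrated_enrichment(
    calls: pd.DataFrame,
    labels: pd.Series,
    combination: dict[str, str],
) -> tuple[pd.DataFrame, TestResult]:
    """Per-subtype prevalence and exact test of a call conjunction.

    ``combination`` maps axis -> required state, e.g.
    ``{"mutation": "mutant", "cn_call": "amplified", "expr_call": "over"}``.
    The evaluable denominator is samples non-missing on every referenced
    axis.
    """
    check_labels(labels)
    bad = set(combination) - set(_AXIS_MISSING)
    if bad:
        raise ValueError(f"unknown call axes {sorted(bad)}")
    common = [s for s in calls.index if s in labels.index]
    sub = calls.loc[common]
    lab = labels[common]
    evaluable = pd.Series(True, index=sub.index)
    for axis in combination:
        evaluable &= sub[axis] != _AXIS_MISSING[axis]
    if not evaluable.any():
        raise ValueError("no evaluable samples for this combination")
    satisfies = pd.Series(True, index=sub.index)
    for axis, state in combination.items():
        satisfies &= sub[axis] == state
    satisfies &= evaluable
    rows, table = [], []
    for subtype in SUBTYPES:
        members = (lab == subtype) & evaluable
        n_eval = int(members.sum())
        n_sat = int((satisfies & members).sum())
        pct = 100.0 * n_sat / n_eval if n_eval else float("nan")
        rows.append(
            {"subtype": subtype, "n_evaluable": n_eval, "n_satisfying": n_sat,
             "percent": pct}
        )
        table.append((n_sat, n_eval - n_sat))
    arr = np.array(table).T  # 2 x 3: satisfy / not x subtype
    if arr.sum() == 0 or arr[0].sum() == 0:
        res = TestResult(float("nan"), 1.0, "two_sided",
                         tuple(int(x) for x in arr.sum(axis=0)))
    else:
        res = fisher_exact(arr, "two_sided")
    return pd.DataFrame(rows).set_index("subtype"), res


def comutation_enrichment(
    mutations: MutationTable,
    labels: pd.Series,
    gene_pairs: list[tuple[str, str, str]],
) -> pd.DataFrame:
    """Subtype enrichment of mutation combinations.

    Each entry of ``gene_pairs`` is ``(kind, gene_a, gene_b)`` where kind is
    ``"both"`` (both genes mutant) or ``"solitary"`` (gene_a mutant and
    gene_b wildtype). Evaluable samples are assayed for both genes.
    """
    check_labels(labels)
    mutant = mutations.mutant_matrix()
    rows = []
    for kind, gene_a, gene_b in gene_pairs:
        if kind not in ("both", "solitary"):
            raise ValueError(f"unknown pair kind {kind!r}")
        name = f"{gene_a}&{gene_b}" if kind == "both" else f"{gene_a} solitary (no {gene_b})"
        if gene_a not in mutations.assayed.index or gene_b not in mutations.assayed.index:
            rows.append({"pair": name, "flag": "gene not assayed"})
            continue
        assayed_both = mutations.assayed.loc[gene_a] & mutations.assayed.loc[gene_b]
        samples = [s for s in labels.index if s in assayed_both.index and bool(assayed_both[s])]
        if not samples:
            rows.append({"pair": name, "flag": "zero evaluable tumors"})
            continue
        a = mutant.loc[gene_a, samples]
        b = mutant.loc[gene_b, samples]
        hit = (a & b) if kind == "both" else (a & ~b)
        lab = labels[samples]
        table, row = [], {"pair": name, "flag": ""}
        for subtype in SUBTYPES:
            members = lab == subtype
            n_eval = int(members.sum())
            n_hit = int((hit & members).sum())
            row[f"n_{subtype}"] = n_eval
            row[f"percent_{subtype}"] = 100.0 * n_hit / n_eval if n_eval else float("nan")
            table.append((n_hit, n_eval - n_hit))
        arr = np.array(table).T
        if arr[0].sum() == 0:
            row["p_value"] = 1.0
        else:
            row["p_value"] = fisher_exact(arr, "two_sided").p_value
        rows.append(row)
    return pd.DataFrame(rows).set_index("pair")
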