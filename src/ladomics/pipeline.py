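"""Discovery -> validation study orchestration.

``run_study`` wires the stages in the study's order: subtype discovery on
the discovery cohort (consensus clustering) and subtype prediction on the
validation cohort (nearest centroid), then the two-stage mutation
association, CIN and regional-CN/GACN two-stage analysis, CN-expression
coordination, methylation comparisons (validation cohort, which carries the
methylation assay), integrated and co-mutation enrichment, and patient
outcomes on the pooled cohorts. Every stage consumes and emits plain typed
tables, which are all written to the report bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import copy_number, integration, methylation, mutation_stats, outcomes, subtyping
from .containers import GenomicRegion, GroundTruth, OmicsCohort, SUBTYPES
from .io_formats import write_manifest, write_matrix

log = logging.getLogger("ladomics.pipeline")

DEFAULT_PARAMS: dict = {
    "variable_fraction": 0.25,
    "k_range": (2, 3, 4, 5),
    "consensus_reps": 500,
    "subsample_frac": 0.8,
    "delta_threshold": 0.1,
    "predictor_genes": 506,
    "min_mutant_patients": 5,
    "discovery_gate": 0.10,
    "gacn_alpha": 0.05,
    "cn_bin_size": None,  # optional pre-binning of probes (e.g. 2_000_000)
    "gene_cn_flank": 500_000,  # gene CN window half-width; >= probe spacing
    "min_followup_months": 1.0,
    "seed": 0,
}

DRIVER_COMBINATIONS = {
    "EGFR": {"mutation": "mutant", "cn_call": "amplified", "expr_call": "over"},
    "KRAS": {"mutation": "mutant", "cn_call": "amplified", "expr_call": "over"},
    "TP53": {"mutation": "mutant", "cn_call": "deleted"},
    "STK11": {"mutation": "mutant", "cn_call": "deleted", "expr_call": "under"},
}

COMUTATION_PAIRS = [
    ("both", "KRAS", "STK11"),
    ("both", "TP53", "STK11"),
    ("both", "TP53", "KRAS"),
    ("solitary", "EGFR", "TP53"),
]


@dataclass
class StudyReport:
    """Bundle of per-stage result tables plus the subtype assignments."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    labels_discovery: pd.Series | None = None
    labels_validation: pd.Series | None = None
    chosen_k: int | None = None
    subtype_model: subtyping.SubtypeModel | None = None


def _check_disjoint(discovery: OmicsCohort, validation: OmicsCohort) -> None:
    d = set(discovery.sample_roles.index)
    v = set(validation.sample_roles.index)
    overlap = sorted(d & v)
    if overlap:
        raise ValueError(
            f"discovery and validation cohorts share samples: {overlap[:10]}"
        )


def name_clusters(
    cluster_labels: pd.Series, reference: pd.Series
) -> pd.Series:
    """Rename integer cluster labels to subtype names by maximal overlap
    with reference labels (Hungarian assignment on the contingency table).

    Used to give discovered clusters canonical names; association statistics
    are invariant to the naming.
    """
    clusters = sorted(pd.unique(cluster_labels))
    common = [s for s in cluster_labels.index if s in reference.index]
    contingency = np.zeros((len(clusters), len(SUBTYPES)))
    for i, c in enumerate(clusters):
        for j, s in enumerate(SUBTYPES):
            contingency[i, j] = sum(
                cluster_labels[x] == c and reference[x] == s for x in common
            )
    ri, ci = linear_sum_assignment(-contingency)
    mapping = {clusters[i]: SUBTYPES[j] for i, j in zip(ri, ci)}
    # clusters beyond three (k > 3) keep a generic name
    for c in clusters:
        mapping.setdefault(c, f"cluster{c}")
    return cluster_labels.map(mapping).rename("subtype")


def assign_subtypes(
    discovery: OmicsCohort,
    params: dict,
    reference: pd.Series | None = None,
) -> tuple[pd.Series, subtyping.SubtypeModel, subtyping.ConsensusResult]:
    """Consensus-cluster discovery tumors and train the centroid predictor."""
    tumors = discovery.tumor_ids
    expr = subtyping.median_center(discovery.expression[tumors])
    genes = subtyping.select_variable_genes(expr, params["variable_fraction"])
    cons = subtyping.consensus_cluster(
        expr.loc[genes],
        k_range=tuple(params["k_range"]),
        n_reps=params["consensus_reps"],
        subsample_frac=params["subsample_frac"],
        seed=params["seed"],
        delta_threshold=params["delta_threshold"],
    )
    clusters = cons.labels[cons.chosen_k]
    if reference is not None:
        labels = name_clusters(clusters, reference)
    else:
        # stable generic naming by decreasing cluster size
        order = clusters.value_counts().index
        names = list(SUBTYPES) + [f"cluster{c}" for c in order[3:]]
        mapping = {c: names[i] for i, c in enumerate(order)}
        labels = clusters.map(mapping).rename("subtype")
        log.warning(
            "no reference labels: cluster names assigned by size order only"
        )
    model = subtyping.train_centroid_predictor(
        discovery.expression[tumors], labels, n_genes=params["predictor_genes"]
    )
    return labels, model, cons


def _driver_region(cohort: OmicsCohort, gene: str) -> GenomicRegion | None:
    if cohort.gene_positions is None or gene not in cohort.gene_positions.index:
        return None
    row = cohort.gene_positions.loc[gene]
    return GenomicRegion(str(row["chromosome"]), int(row["position"]),
                         int(row["position"]) + 1, gene)


def run_study(
    discovery: OmicsCohort,
    validation: OmicsCohort,
    truth_discovery: GroundTruth | None = None,
    truth_validation: GroundTruth | None = None,
    params: dict | None = None,
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Execute the full discovery -> validation analysis.

    ``truth_discovery`` (when available, i.e. on synthetic cohorts) is used
    only to give discovered clusters their canonical subtype names; all
    association statistics are computed from the data.
    """
    p = {**DEFAULT_PARAMS, **(params or {})}
    _check_disjoint(discovery, validation)
    report = StudyReport()

    # --- subtypes ---------------------------------------------------------
    reference = truth_discovery.subtype if truth_discovery is not None else None
    labels_d, model, cons = assign_subtypes(discovery, p, reference)
    pred = subtyping.predict_subtype(model, validation.expression[validation.tumor_ids])
    labels_v = pred["subtype"].rename("subtype")
    report.labels_discovery = labels_d
    report.labels_validation = labels_v
    report.chosen_k = cons.chosen_k
    report.subtype_model = model
    report.tables["subtype_labels_discovery"] = labels_d.to_frame()
    report.tables["subtype_labels_validation"] = pred
    report.tables["consensus_summary"] = pd.DataFrame(
        {
            "k": sorted(cons.area),
            "cdf_area": [cons.area[k] for k in sorted(cons.area)],
            "delta_area": [cons.delta_area[k] for k in sorted(cons.area)],
        }
    ).set_index("k")

    # --- mutations --------------------------------------------------------
    genes = mutation_stats.filter_testable_genes(
        discovery.mutations, p["min_mutant_patients"]
    )
    disc = mutation_stats.discovery_association(
        discovery.mutations, labels_d, genes, gate=p["discovery_gate"]
    )
    summaries = mutation_stats.validation_association(
        validation.mutations, labels_v, disc
    )
    report.tables["mutation_association"] = summaries.set_index("gene")
    rates, rate_summary, rate_kw = mutation_stats.genomewide_mutation_rate(
        discovery.mutations, discovery.sequenced_bases, labels_d, seed=p["seed"]
    )
    rate_summary["kw_p"] = rate_kw.p_value
    report.tables["mutation_rates"] = rate_summary

    # --- copy number ------------------------------------------------------
    cn_d, cn_v = discovery.cn, validation.cn
    if p["cn_bin_size"]:
        cn_d = copy_number.bin_probes(cn_d, p["cn_bin_size"])
        cn_v = copy_number.bin_probes(cn_v, p["cn_bin_size"])
    cin_d = copy_number.cin(cn_d, discovery.arms)
    cin_v = copy_number.cin(cn_v, validation.arms)
    kw = copy_number.compare_cin(cin_d[labels_d.index], labels_d, "discovery")
    wil = copy_number.compare_cin(cin_v[labels_v.index], labels_v, "validation")
    cin_rows = []
    for subtype in SUBTYPES:
        cin_rows.append(
            {
                "subtype": subtype,
                "discovery_median_cin": float(cin_d[labels_d.index[labels_d == subtype]].median()),
                "validation_median_cin": float(cin_v[labels_v.index[labels_v == subtype]].median()),
            }
        )
    cin_table = pd.DataFrame(cin_rows).set_index("subtype")
    cin_table["discovery_kw_p"] = kw.p_value
    cin_table["validation_magnoid_p"] = wil.p_value
    report.tables["cin"] = cin_table

    region_d = copy_number.region_cn(cn_d, discovery.regions)
    gacn = copy_number.gacn_discovery(
        region_d[labels_d.index], labels_d, alpha=p["gacn_alpha"]
    )
    region_v = copy_number.region_cn(cn_v, validation.regions)
    gacn = copy_number.gacn_validation(region_v[labels_v.index], labels_v, gacn)
    report.tables["gacn"] = gacn

    coord, coord_res = copy_number.cn_expression_coordination(
        region_d[labels_d.index],
        gacn,
        discovery.expression,
        labels_d,
        discovery.gene_positions,
        discovery.regions,
    )
    coord["spearman_rho"] = coord_res.statistic
    coord["spearman_p"] = coord_res.p_value
    report.tables["cn_expression_coordination"] = coord

    # --- methylation (validation cohort carries the assay) ----------------
    meth_values, meth_sites = methylation.quantify_methylation(validation.methylation)
    medians, meth_kw, normal_median = methylation.genomewide_comparison(
        meth_values, labels_v
    )
    meth_rows = [
        {
            "group": subtype,
            "median_methylation": float(medians[labels_v.index[labels_v == subtype]].median()),
        }
        for subtype in SUBTYPES
    ]
    meth_rows.append({"group": "normal", "median_methylation": normal_median})
    meth_table = pd.DataFrame(meth_rows).set_index("group")
    meth_table["kw_p"] = meth_kw.p_value
    report.tables["methylation_genomewide"] = meth_table

    normals = validation.normal_ids
    hyper_counts = {}
    arm_profiles = {}
    for subtype in SUBTYPES:
        members = list(labels_v.index[labels_v == subtype])
        per_site = methylation.per_site_differential(meth_values, members, normals)
        hyper_counts[subtype] = int(per_site["significant"].sum())
        arm_profiles[subtype] = methylation.arm_hypermethylation_profile(
            per_site, meth_sites, validation.arms
        )["proportion"]
    report.tables["methylation_hypermethylated_counts"] = pd.DataFrame(
        {"n_sites_vs_normal": hyper_counts}
    )
    report.tables["methylation_arm_profile"] = pd.DataFrame(arm_profiles)

    # --- integrated alterations (discovery cohort) ------------------------
    int_rows = []
    tumors_d = discovery.tumor_ids
    for gene, combo in DRIVER_COMBINATIONS.items():
        calls = integration.build_integrated_calls(
            gene,
            discovery.mutations,
            cn_d,
            discovery.expression[tumors_d],
            _driver_region(discovery, gene),
            tumors_d,
            flank=p["gene_cn_flank"],
        )
        try:
            summary, res = integration.integrated_enrichment(calls, labels_d, combo)
        except ValueError as exc:
            log.warning("integrated combination for %s skipped: %s", gene, exc)
            continue
        row = {"gene": gene, "combination": "+".join(sorted(combo.values())),
               "p_value": res.p_value}
        for subtype in SUBTYPES:
            row[f"percent_{subtype}"] = summary.loc[subtype, "percent"]
        int_rows.append(row)
    report.tables["integrated_alterations"] = pd.DataFrame(int_rows).set_index("gene")
    report.tables["comutations"] = integration.comutation_enrichment(
        discovery.mutations, labels_d, COMUTATION_PAIRS
    )

    # --- outcomes (pooled cohorts) ----------------------------------------
    clinical = pd.concat([discovery.clinical, validation.clinical])
    clinical = outcomes.filter_followup(clinical, p["min_followup_months"])
    labels_all = pd.concat([labels_d, labels_v])
    fit = outcomes.km_logrank(clinical, labels_all)
    km_rows = []
    for grp, curve in fit.curves.items():
        final = float(curve["survival"].iloc[-1]) if len(curve) else 1.0
        km_rows.append({"subtype": grp, "n": fit.group_sizes[grp],
                        "final_survival": final})
    km_table = pd.DataFrame(km_rows).set_index("subtype")
    km_table["logrank_p"] = fit.logrank.p_value
    report.tables["survival_logrank"] = km_table
    report.tables["treatment_hr"] = outcomes.treatment_hr_by_subtype(
        clinical, labels_all
    )

    sig = discovery.signature or validation.signature
    if sig is not None:
        scores = pd.concat(
            [
                outcomes.gefitinib_score(discovery.expression[tumors_d], sig),
                outcomes.gefitinib_score(
                    validation.expression[validation.tumor_ids], sig
                ),
            ]
        )
        egfr = pd.concat(
            [
                discovery.mutations.mutant_matrix().loc["EGFR"],
                validation.mutations.mutant_matrix().loc["EGFR"],
            ]
        )
        egfr = egfr[[s for s in scores.index if s in egfr.index]]
        report.tables["gefitinib_score_comparison"] = outcomes.score_group_comparison(
            scores, labels_all, egfr
        )
        report.tables["gefitinib_scores"] = scores.to_frame()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, table in report.tables.items():
            path = out / f"{name}.tsv"
            write_matrix(table, path)
            written.append(str(path.name))
        write_manifest(
            out,
            command="run_study",
            seed=p["seed"],
            parameters={k: str(v) for k, v in p.items()},
            inputs=["discovery cohort", "validation cohort"],
            outputs=written,
        )
    return report
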