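"""Patient outcomes: Kaplan-Meier / log-rank survival comparisons, per-
subtype treatment hazard ratios, and the gefitinib-sensitivity score.

The product-limit estimator and the k-group log-rank test are implemented
natively (they are the analysis's workhorses and are oracle-tested against
hand computation); Cox proportional-hazards fits delegate to lifelines.

Patients with follow-up shorter than one month are excluded from survival
analyses by default (early deaths attributed to surgical complications).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats as sps

from .containers import ExpressionSignature, SUBTYPES, check_labels
from .stats_core import (
    ONE_SIDED_GREATER,
    TWO_SIDED,
    TestResult,
    kruskal_wallis,
    wilcoxon_rank_sum,
)

log = logging.getLogger("ladomics.outcomes")

MIN_FOLLOWUP_MONTHS = 1.0


def filter_followup(
    clinical: pd.DataFrame, min_months: float = MIN_FOLLOWUP_MONTHS
) -> pd.DataFrame:
    """Drop patients with follow-up below ``min_months`` (>= rule keeps the
    boundary)."""
    if min_months < 0:
        raise ValueError("min_months must be >= 0")
    keep = clinical["followup_months"] >= min_months
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("removed %d patients with follow-up < %g months", n_removed, min_months)
    return clinical.loc[keep].copy()


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival curve: time, at-risk, events, survival."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    s = 1.0
    n = len(t)
    for u in np.unique(t[e]):
        at_risk = int((t >= u).sum())
        d = int(((t == u) & e).sum())
        s *= 1.0 - d / at_risk
        rows.append({"time": float(u), "n_at_risk": at_risk, "n_events": d,
                     "survival": s})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(times, events, groups) -> TestResult:
    """k-group log-rank chi-square test."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    uniq_groups = [x for x in pd.unique(g)]
    k = len(uniq_groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in np.unique(t[e]):
        at_risk = t >= u
        n = int(at_risk.sum())
        d = int(((t == u) & e).sum())
        if n <= 1 or d == 0:
            continue
        ni = np.array([int((at_risk & (g == grp)).sum()) for grp in uniq_groups])
        di = np.array([int(((t == u) & e & (g == grp)).sum()) for grp in uniq_groups])
        O += di
        E += ni * d / n
        factor = d * (n - d) / (n - 1) if n > 1 else 0.0
        V += factor * (np.diag(ni) / n - np.outer(ni, ni) / n**2)
    z = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    p = float(sps.chi2.sf(chi2, df=k - 1))
    sizes = tuple(int((g == grp).sum()) for grp in uniq_groups)
    return TestResult(chi2, p, TWO_SIDED, sizes)


@dataclass
class SurvivalFit:
    """Per-group KM curves with the group log-rank comparison."""

    curves: dict[str, pd.DataFrame]
    logrank: TestResult
    group_sizes: dict[str, int] = field(default_factory=dict)


def km_logrank(clinical: pd.DataFrame, labels: pd.Series) -> SurvivalFit:
    """KM curves per subtype plus the k-group log-rank test."""
    common = [s for s in clinical.index if s in labels.index]
    if not common:
        raise ValueError("no labelled patients with clinical data")
    df = clinical.loc[common]
    lab = labels[common]
    curves = {}
    for grp in pd.unique(lab):
        sub = df.loc[lab == grp]
        if len(sub) == 0:
            raise ValueError(f"group {grp!r} has no observations")
        curves[str(grp)] = km_curve(sub["followup_months"], sub["event"])
    lr = logrank_test(df["followup_months"], df["event"], lab.to_numpy())
    return SurvivalFit(
        curves=curves,
        logrank=lr,
        group_sizes={str(grp): int((lab == grp).sum()) for grp in pd.unique(lab)},
    )


def treatment_hr_by_subtype(
    clinical: pd.DataFrame,
    labels: pd.Series,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-subtype Cox hazard ratio of treatment versus observation.

    Returns one row per subtype with the HR, Wald 95% CI and p; a subtype
    missing one of the arms gets a flagged NaN row. ``covariates`` adds an
    adjusted multivariable fit on the listed clinical columns.
    """
    check_labels(labels)
    rows = []
    for subtype in SUBTYPES:
        members = [s for s in clinical.index if labels.get(s) == subtype]
        sub = clinical.loc[members]
        sub = sub[sub["treatment_arm"].isin(["observation", "chemo"])]
        arms = set(sub["treatment_arm"])
        row = {"subtype": subtype, "n": len(sub), "flag": ""}
        if arms != {"observation", "chemo"}:
            row.update({"hr": np.nan, "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan,
                        "flag": "an arm is empty"})
            rows.append(row)
            continue
        data = pd.DataFrame(
            {
                "T": sub["followup_months"].astype(float),
                "E": sub["event"].astype(int),
                "treated": (sub["treatment_arm"] == "chemo").astype(int),
            }
        )
        if covariates:
            for c in covariates:
                col = sub[c]
                if col.dtype == object:
                    data = pd.concat(
                        [data, pd.get_dummies(col, prefix=c, drop_first=True).astype(int)],
                        axis=1,
                    )
                else:
                    data[c] = col.astype(float)
        cph = CoxPHFitter()
        cph.fit(data, duration_col="T", event_col="E")
        coef = float(cph.params_["treated"])
        se = float(cph.standard_errors_["treated"])
        row.update(
            {
                "hr": float(np.exp(coef)),
                "ci_lo": float(np.exp(coef - 1.96 * se)),
                "ci_hi": float(np.exp(coef + 1.96 * se)),
                "p": float(cph.summary.loc["treated", "p"]),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("subtype")


def gefitinib_score(
    expression: pd.DataFrame, signature: ExpressionSignature
) -> pd.Series:
    """Per-sample sensitivity score: mean over present overexpressed-list
    genes minus mean over present underexpressed-list genes.

    Missing signature genes are dropped per sample (count logged); a list
    with no genes in the matrix at all is an error naming the list.
    """
    o = [g for g in signature.overexpressed if g in expression.index]
    u = [g for g in signature.underexpressed if g in expression.index]
    if not o:
        raise ValueError("no overexpressed-list genes present in the matrix")
    if not u:
        raise ValueError("no underexpressed-list genes present in the matrix")
    n_missing = (len(signature.overexpressed) - len(o)) + (
        len(signature.underexpressed) - len(u)
    )
    if n_missing:
        log.info("%d signature genes absent from the matrix", n_missing)
    score = expression.loc[o].mean(axis=0, skipna=True) - expression.loc[u].mean(
        axis=0, skipna=True
    )
    return score.rename("gefitinib_score")


def score_group_comparison(
    scores: pd.Series,
    labels: pd.Series,
    egfr_status: pd.Series,
) -> pd.DataFrame:
    """Score comparisons within EGFR strata and between them.

    Within each stratum (mutant / wildtype): Kruskal-Wallis across the three
    subtypes and a one-sided rank-sum of Bronchioid versus the rest
    (alternative: Bronchioid scores greater). Plus one overall one-sided
    rank-sum of mutant versus wildtype scores.
    """
    common = [s for s in scores.index if s in labels.index and s in egfr_status.index]
    sc, lab, mut = scores[common], labels[common], egfr_status[common].astype(bool)
    if mut.all() or (~mut).all():
        raise ValueError("both EGFR strata must be non-empty")
    rows = []
    for stratum, mask in (("EGFR mutant", mut), ("EGFR wildtype", ~mut)):
        s_s, s_l = sc[mask], lab[mask]
        present = [x for x in SUBTYPES if (s_l == x).any()]
        if len(present) >= 2:
            kw = kruskal_wallis([s_s[s_l == x].to_numpy() for x in present])
            rows.append({"contrast": f"{stratum}: subtype KW", "statistic": kw.statistic,
                         "p_value": kw.p_value, "flag": ""})
        if (s_l == "Bronchioid").any() and (s_l != "Bronchioid").any():
            w = wilcoxon_rank_sum(
                s_s[s_l == "Bronchioid"].to_numpy(),
                s_s[s_l != "Bronchioid"].to_numpy(),
                ONE_SIDED_GREATER,
            )
            rows.append({"contrast": f"{stratum}: Bronchioid > rest",
                         "statistic": w.statistic, "p_value": w.p_value, "flag": ""})
        else:
            rows.append({"contrast": f"{stratum}: Bronchioid > rest",
                         "statistic": np.nan, "p_value": np.nan,
                         "flag": "no Bronchioid samples in stratum"})
    w = wilcoxon_rank_sum(sc[mut].to_numpy(), sc[~mut].to_numpy(), ONE_SIDED_GREATER)
    rows.append({"contrast": "EGFR mutant > wildtype", "statistic": w.statistic,
                 "p_value": w.p_value, "flag": ""})
    return pd.DataFrame(rows).set_index("contrast")
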