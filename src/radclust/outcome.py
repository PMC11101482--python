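"""Cluster-outcome associations: survival, clinicopathology, mutations.

Survival is disease-specific (time from primary treatment to death from
disease; other exits censored): Kaplan-Meier curves per cluster with overall
and pairwise Mantel-Cox log-rank tests, and Cox proportional-hazards models,
unadjusted and adjusted for FIGO stage (III/IV vs I/II) and age. Categorical
clinicopathological variables use chi-square or Fisher's exact test as
appropriate; continuous ones Mann-Whitney (2 groups) or Kruskal-Wallis (>=3).
Per-gene mutation frequencies are compared cluster-vs-rest by Fisher's exact
test with FDR across tests, plus an oncogenic-pathway aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kaplan_meier", "cox_model", "clinicopathological_table",
    "per_gene_mutation_test", "pathway_aggregation", "DEFAULT_PATHWAYS",
]

#: Oncogenic-pathway map covering the default synthetic gene panel.
DEFAULT_PATHWAYS = {
    "PI3K": ("PIK3CA", "PTEN", "STK11"),
    "RTK-RAS": ("KRAS", "ERBB2", "MAPK1"),
    "p53": ("TP53",),
    "Cell cycle": ("RB1",),
    "TGF-beta": ("TGFBR2", "SMAD4"),
    "NOTCH": ("FBXW7",),
    "Chromatin": ("KMT2D", "EP300", "ARID1A", "CREBBP"),
}

_ADVANCED_FIGO = ("III", "IV")


class SurvivalError(ValueError):
    """Survival analysis cannot be run on these data (e.g. zero events)."""


@dataclass
class KaplanMeierResult:
    curves: dict                 # group -> survival function DataFrame
    event_tables: dict           # group -> at-risk/event table
    overall_logrank_p: float | None
    pairwise_logrank_p: dict     # (g1, g2) -> p


def kaplan_meier(clinical_table: pd.DataFrame, grouping: pd.Series,
                 require_logrank: bool = True,
                 adjust_pairwise: bool = False) -> KaplanMeierResult:
    """Product-limit survival per group with Mantel-Cox log-rank tests.

    With zero events overall the curves are still returned but the log-rank
    test is refused (set ``require_logrank=False`` to get curves only).
    Pairwise per-pair p-values are unadjusted by default;
    ``adjust_pairwise=True`` applies a Bonferroni correction over the pairs.
    """
    grouping = grouping.loc[clinical_table.index]
    time = clinical_table["dss_time"]
    event = clinical_table["dss_event"]
    curves, tables = {}, {}
    for g in sorted(grouping.unique()):
        mask = (grouping == g).to_numpy()
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(time[mask], event[mask])
        curves[g] = kmf.survival_function_
        tables[g] = kmf.event_table
    if event.sum() == 0:
        if require_logrank:
            raise SurvivalError("log-rank test requires at least one event")
        return KaplanMeierResult(curves, tables, None, {})
    overall = multivariate_logrank_test(time, grouping, event)
    pairwise = {}
    for g1, g2 in combinations(sorted(grouping.unique()), 2):
        m1, m2 = (grouping == g1).to_numpy(), (grouping == g2).to_numpy()
        res = logrank_test(time[m1], time[m2], event[m1], event[m2])
        pairwise[(g1, g2)] = float(res.p_value)
    if adjust_pairwise and pairwise:
        k = len(pairwise)
        pairwise = {pair: min(1.0, p * k) for pair, p in pairwise.items()}
    return KaplanMeierResult(curves, tables, float(overall.p_value), pairwise)


def _cox_frame(clinical_table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Covariate coding: cluster 2/3 vs 1, FIGO III/IV vs I/II, age in years."""
    df = pd.DataFrame({
        "dss_time": clinical_table["dss_time"],
        "dss_event": clinical_table["dss_event"],
        "cluster_23_vs_1": (labels.loc[clinical_table.index] > 1).astype(int),
        "figo_34_vs_12": clinical_table["figo_stage"].astype(str)
        .str.startswith(_ADVANCED_FIGO).astype(int),
        "age": clinical_table["age"].astype(float),
    })
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        import logging
        logging.getLogger(__name__).warning(
            "Cox: excluded %d rows with missing covariates", n0 - len(df))
    return df


def cox_model(clinical_table: pd.DataFrame, labels: pd.Series,
              adjusted: bool = True,
              covariates: tuple[str, ...] = ("cluster_23_vs_1",
                                             "figo_34_vs_12", "age")) -> pd.DataFrame:
    """Cox proportional-hazards HRs with Wald 95% CIs.

    ``adjusted=True`` fits all covariates simultaneously; otherwise each
    covariate is fitted in its own univariate model.
    """
    df = _cox_frame(clinical_table, labels)
    if df["dss_event"].sum() == 0:
        raise SurvivalError("Cox model requires at least one event")
    rows = []
    cov_sets = [list(covariates)] if adjusted else [[c] for c in covariates]
    for covs in cov_sets:
        cph = CoxPHFitter()
        try:
            cph.fit(df[["dss_time", "dss_event"] + covs],
                    duration_col="dss_time", event_col="dss_event")
        except Exception as exc:  # monotone likelihood / separation
            raise SurvivalError(
                f"Cox fit failed for covariates {covs}: {exc}") from exc
        s = cph.summary
        for cov in covs:
            rows.append({
                "covariate": cov,
                "model": "adjusted" if adjusted else "unadjusted",
                "HR": float(s.loc[cov, "exp(coef)"]),
                "ci_lower": float(s.loc[cov, "exp(coef) lower 95%"]),
                "ci_upper": float(s.loc[cov, "exp(coef) upper 95%"]),
                "pvalue": float(s.loc[cov, "p"]),
            })
    return pd.DataFrame(rows).set_index("covariate")


def _categorical_test(table: pd.DataFrame, rng: np.random.Generator,
                      n_mc: int = 2000) -> tuple[str, float, float]:
    """Chi-square, or Fisher/Monte-Carlo when expected counts are small."""
    obs = table.to_numpy()
    chi2, p, _, expected = stats.chi2_contingency(obs)
    if (expected >= 5).all():
        return "chi-square", float(chi2), float(p)
    if obs.shape == (2, 2):
        _, p = stats.fisher_exact(obs)
        return "Fisher exact", float("nan"), float(p)
    # r x c with small expecteds: permutation null of the chi-square statistic
    rows = np.repeat(np.arange(obs.shape[0]), obs.sum(axis=1))
    cols = np.repeat(np.arange(obs.shape[1]), obs.sum(axis=0))
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        t = np.zeros_like(obs)
        np.add.at(t, (rows, perm), 1)
        c, _, _, _ = stats.chi2_contingency(t, correction=False)
        hits += c >= chi2 - 1e-12
    return "chi-square (Monte Carlo)", float(chi2), float((hits + 1) / (n_mc + 1))


@dataclass
class AssociationResult:
    variable: str
    test: str
    statistic: float
    pvalue: float
    summary: pd.DataFrame    # contingency counts or per-group summaries
    note: str = ""


def clinicopathological_table(clinical_table: pd.DataFrame, labels: pd.Series,
                              variables: dict | None = None,
                              seed: int = 0) -> list[AssociationResult]:
    """Compare clinical variables across clusters, one test per variable.

    ``variables`` maps column name to 'continuous' or 'categorical'; the
    default covers age, FIGO stage, histology and maximum tumor diameter.
    """
    if variables is None:
        variables = {"age": "continuous", "figo_stage": "categorical",
                     "histology": "categorical",
                     "max_tumor_diameter": "continuous"}
    rng = np.random.default_rng(seed)
    labels = labels.loc[clinical_table.index]
    results = []
    for var, kind in variables.items():
        x = clinical_table[var]
        if x.nunique() < 2:
            results.append(AssociationResult(var, "skipped", np.nan, np.nan,
                                             pd.DataFrame(),
                                             note="constant across cohort"))
            continue
        if kind == "continuous":
            groups = [x[labels == k].to_numpy(float)
                      for k in sorted(labels.unique())]
            if len(groups) == 2:
                stat, p = stats.mannwhitneyu(*groups, alternative="two-sided")
                test = "Mann-Whitney"
            else:
                stat, p = stats.kruskal(*groups)
                test = "Kruskal-Wallis"
            summary = x.groupby(labels).agg(["median", "min", "max"])
        else:
            table = pd.crosstab(x, labels)
            test, stat, p = _categorical_test(table, rng)
            pct = table.div(table.sum(axis=0), axis=1).mul(100).round(1)
            summary = pd.concat({"n": table, "pct": pct}, axis=1)
        results.append(AssociationResult(var, test, float(stat), float(p), summary))
    return results


def per_gene_mutation_test(mutation_matrix: pd.DataFrame, labels: pd.Series,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Cluster-vs-rest Fisher tests of per-gene mutation frequency.

    For every gene and every cluster a 2x2 Fisher exact test compares mutation
    frequency in that cluster against the other clusters combined; BH-FDR is
    applied across all gene/cluster tests. Genes mutated in zero patients are
    untestable (p = 1).
    """
    labels = labels.loc[mutation_matrix.index]
    clusters = sorted(labels.unique())
    rows = []
    for gene in mutation_matrix.columns:
        calls = mutation_matrix[gene]
        freqs = {f"freq_C{k}": float(calls[labels == k].mean()) for k in clusters}
        counts = {f"n_mut_C{k}": int(calls[labels == k].sum()) for k in clusters}
        if calls.sum() == 0:
            rows.append({"gene": gene, **freqs, **counts, "best_cluster": None,
                         "pvalue": 1.0, "untestable": True})
            continue
        best_p, best_k = 1.0, None
        for k in clusters:
            in_k = labels == k
            a, b = int(calls[in_k].sum()), int((1 - calls[in_k]).sum())
            c, d = int(calls[~in_k].sum()), int((1 - calls[~in_k]).sum())
            _, p = stats.fisher_exact([[a, b], [c, d]])
            if p < best_p:
                best_p, best_k = float(p), k
        rows.append({"gene": gene, **freqs, **counts, "best_cluster": best_k,
                     "pvalue": best_p, "untestable": False})
    report = pd.DataFrame(rows).set_index("gene")
    reject, qvals, _, _ = multipletests(report["pvalue"], alpha=alpha,
                                        method="fdr_bh")
    report["qvalue"] = qvals
    report["fdr_significant"] = reject & ~report["untestable"]
    return report


def pathway_aggregation(mutation_matrix: pd.DataFrame, labels: pd.Series,
                        pathways: dict | None = None) -> pd.DataFrame:
    """Per-cluster proportion of patients with >=1 mutation in each pathway.

    A chi-square test compares the mutated/unmutated split across clusters
    for every pathway.
    """
    pathways = pathways or DEFAULT_PATHWAYS
    labels = labels.loc[mutation_matrix.index]
    clusters = sorted(labels.unique())
    rows = []
    for pw, genes in pathways.items():
        genes = [g for g in genes if g in mutation_matrix.columns]
        if not genes:
            continue
        hit = (mutation_matrix[genes].sum(axis=1) > 0).astype(int)
        props = {f"prop_C{k}": float(hit[labels == k].mean()) for k in clusters}
        counts = {f"n_C{k}": int(hit[labels == k].sum()) for k in clusters}
        table = pd.crosstab(hit, labels)
        if table.shape[0] < 2:
            p = np.nan
        else:
            _, p, _, _ = stats.chi2_contingency(table)
        rows.append({"pathway": pw, **props, **counts, "pvalue": float(p)})
    return pd.DataFrame(rows).set_index("pathway")
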