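"""Cohort-level descriptive and comparative statistics.

Per-dataset and pooled gene mutation frequencies (random-effects
meta-analysis on the logit scale), per-patient mutational load with
stage/location group comparisons, pathway and druggable-gene burden,
pairwise co-occurrence / mutual exclusivity, clinical group comparisons,
and the age-trend test for rising mutation prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, logit
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .ingest import classify_nonsilent


def gene_frequencies(gene_matrix: pd.DataFrame, clinical: pd.DataFrame | None = None,
                     by: str = "overall") -> pd.DataFrame:
    """Mutation frequency per gene, overall or per dataset.

    Returns (gene, group, n_mut, n_total, freq, ci_low, ci_high) with
    Clopper-Pearson 95% intervals.
    """
    if gene_matrix.empty:
        raise ValueError("gene matrix is empty")
    if by == "overall":
        groups = {"overall": gene_matrix.index}
    elif by == "dataset":
        if clinical is None:
            raise ValueError("per-dataset frequencies need the clinical table")
        ds = clinical.set_index("sample_id")["dataset_id"]
        groups = {d: idx for d, idx in gene_matrix.index.to_series().groupby(
            gene_matrix.index.map(ds))}
    else:
        raise ValueError("by must be 'overall' or 'dataset'")
    rows = []
    for group, idx in groups.items():
        sub = gene_matrix.loc[idx]
        n = len(sub)
        for gene, n_mut in sub.sum(axis=0).items():
            lo, hi = proportion_confint(int(n_mut), n, alpha=0.05, method="beta")
            rows.append((gene, group, int(n_mut), n, n_mut / n, lo, hi))
    return pd.DataFrame(rows, columns=["gene", "group", "n_mut", "n_total",
                                       "freq", "ci_low", "ci_high"])


@dataclass
class MetaFrequency:
    gene: str
    per_dataset: pd.DataFrame          # group, n_mut, n_total, proportion, yi, vi
    pooled_proportion: float
    pooled_ci: tuple[float, float]
    tau2: float
    method: str = "DerSimonian-Laird (logit)"


def pooled_frequency(counts: pd.DataFrame, gene: str = "") -> MetaFrequency:
    """Random-effects pooled mutation frequency across datasets.

    `counts` needs columns n_mut and n_total (one row per dataset).
    Study proportions are pooled on the logit scale with inverse-variance
    weights and the DerSimonian-Laird between-study variance; boundary
    studies (0 or all mutated) get a 0.5 continuity correction.  The pooled
    value and CI are back-transformed to the proportion scale.
    """
    df = counts.copy()
    if (df["n_total"] < 1).any():
        raise ValueError("every dataset needs n_total >= 1")
    x = df["n_mut"].to_numpy(dtype=float)
    n = df["n_total"].to_numpy(dtype=float)
    boundary = (x == 0) | (x == n)
    xc = np.where(boundary, x + 0.5, x)
    nc = np.where(boundary, n + 1.0, n)
    p = xc / nc
    yi = logit(p)
    vi = 1.0 / xc + 1.0 / (nc - xc)
    df["proportion"] = p
    df["yi"], df["vi"] = yi, vi
    if len(df) < 2:
        warnings.warn("single dataset: pooled frequency equals its own proportion")
        se = float(np.sqrt(vi[0]))
        ci = (float(expit(yi[0] - 1.96 * se)), float(expit(yi[0] + 1.96 * se)))
        return MetaFrequency(gene=gene, per_dataset=df,
                             pooled_proportion=float(p[0]), pooled_ci=ci, tau2=0.0)
    w = 1.0 / vi
    y_fixed = np.sum(w * yi) / np.sum(w)
    Q = float(np.sum(w * (yi - y_fixed) ** 2))
    c = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (Q - (len(df) - 1)) / c) if c > 0 else 0.0
    wr = 1.0 / (vi + tau2)
    y_re = float(np.sum(wr * yi) / np.sum(wr))
    se = float(np.sqrt(1.0 / np.sum(wr)))
    return MetaFrequency(
        gene=gene, per_dataset=df, pooled_proportion=float(expit(y_re)),
        pooled_ci=(float(expit(y_re - 1.96 * se)), float(expit(y_re + 1.96 * se))),
        tau2=float(tau2))


def forest_table(gene_matrix: pd.DataFrame, clinical: pd.DataFrame,
                 genes: list[str]) -> pd.DataFrame:
    """Forest-plot-ready table: per-dataset rows plus a pooled row per gene."""
    per_ds = gene_frequencies(gene_matrix, clinical, by="dataset")
    rows = []
    for gene in genes:
        sub = per_ds[per_ds["gene"] == gene]
        rows.append(sub)
        meta = pooled_frequency(sub[["n_mut", "n_total"]], gene=gene)
        rows.append(pd.DataFrame([{
            "gene": gene, "group": "pooled", "n_mut": sub["n_mut"].sum(),
            "n_total": sub["n_total"].sum(), "freq": meta.pooled_proportion,
            "ci_low": meta.pooled_ci[0], "ci_high": meta.pooled_ci[1]}]))
    return pd.concat(rows, ignore_index=True)


def mutational_load(records: pd.DataFrame, clinical: pd.DataFrame,
                    group_col: str | None = None) -> tuple[pd.Series, dict | None]:
    """Per-patient nonsilent mutation count, with optional group comparison.

    Patients in the clinical table without records count 0.  When
    `group_col` is given, returns a Kruskal-Wallis test across its non-NA
    levels plus pairwise two-sided Wilcoxon rank-sum comparisons.
    """
    ns = records[records["variant_class"].map(classify_nonsilent)]
    load = ns.groupby("sample_id").size()
    load = load.reindex(clinical["sample_id"], fill_value=0).astype(int)
    load.name = "mutational_load"
    if group_col is None:
        return load, None
    grouping = clinical.set_index("sample_id")[group_col]
    mask = grouping.notna()
    levels = sorted(grouping[mask].unique())
    if len(levels) < 2:
        raise ValueError(f"grouping {group_col} has fewer than 2 non-NA levels")
    samples = [load[grouping == lv].to_numpy() for lv in levels]
    kw_stat, kw_p = sps.kruskal(*samples)
    pairwise = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            u, p = sps.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
            pairwise.append({"group_a": levels[i], "group_b": levels[j],
                             "statistic": float(u), "p": float(p)})
    return load, {"levels": levels, "kruskal_stat": float(kw_stat),
                  "kruskal_p": float(kw_p), "pairwise": pairwise}


def pathway_burden(gene_matrix: pd.DataFrame,
                   gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Fraction of patients with >=1 nonsilent mutation in each gene set."""
    rows = []
    for name, genes in gene_sets.items():
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        present = [g for g in genes if g in gene_matrix.columns]
        hit = gene_matrix[present].any(axis=1) if present else pd.Series(
            False, index=gene_matrix.index)
        rows.append({"set": name, "n_genes": len(genes),
                     "n_genes_present": len(present),
                     "n_patients_hit": int(hit.sum()),
                     "burden": float(hit.mean())})
    return pd.DataFrame(rows)


def cooccurrence(gene_matrix: pd.DataFrame,
                 genes: list[str] | None = None) -> pd.DataFrame:
    """Pairwise co-occurrence / exclusivity of gene mutations.

    For every gene pair: 2x2 contingency counts, odds ratio (Haldane 0.5
    correction when any cell is zero), two-sided Fisher exact p, and
    Benjamini-Hochberg adjusted p across all pairs.  Direction is
    'exclusive' iff OR < 1, else 'co-occurring'.
    """
    genes = list(genes) if genes is not None else list(gene_matrix.columns)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    M = gene_matrix[genes].to_numpy(dtype=bool)
    n = M.shape[0]
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = M[:, i], M[:, j]
            both = int(np.sum(a & b))
            a_only = int(np.sum(a & ~b))
            b_only = int(np.sum(~a & b))
            neither = n - both - a_only - b_only
            table = np.array([[both, a_only], [b_only, neither]])
            if (table == 0).any():
                ct = table + 0.5
            else:
                ct = table.astype(float)
            or_ = (ct[0, 0] * ct[1, 1]) / (ct[0, 1] * ct[1, 0])
            _, p = sps.fisher_exact(table, alternative="two-sided")
            rows.append({"gene_a": genes[i], "gene_b": genes[j], "both": both,
                         "a_only": a_only, "b_only": b_only, "neither": neither,
                         "odds_ratio": float(or_), "p_value": float(p),
                         "direction": "exclusive" if or_ < 1 else "co-occurring"})
    out = pd.DataFrame(rows)
    out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def compare_groups(gene_matrix: pd.DataFrame, grouping: pd.Series,
                   *, n_mc: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Per-gene mutation-frequency comparison across categorical groups.

    Patients with NA group are excluded.  Two levels: two-sided Fisher
    exact test on the 2x2 table.  More levels: Monte-Carlo permutation p
    for the chi-squared statistic of the 2xL table (fixed seed).  BH
    adjustment across genes.
    """
    grouping = grouping.reindex(gene_matrix.index)
    mask = grouping.notna()
    if mask.sum() == 0 or grouping[mask].nunique() < 2:
        raise ValueError("grouping needs >= 2 non-NA levels")
    sub = gene_matrix.loc[mask]
    grp = grouping[mask]
    levels = sorted(grp.unique())
    rng = np.random.default_rng(seed)
    codes = pd.Categorical(grp, categories=levels).codes
    rows = []
    for gene in sub.columns:
        x = sub[gene].to_numpy(dtype=int)
        counts = np.array([[int(x[codes == k].sum()),
                            int((codes == k).sum())] for k in range(len(levels))])
        freqs = {f"freq_{lv}": counts[k, 0] / counts[k, 1]
                 for k, lv in enumerate(levels)}
        table = np.column_stack([counts[:, 0], counts[:, 1] - counts[:, 0]])
        if len(levels) == 2:
            _, p = sps.fisher_exact(table, alternative="two-sided")
        else:
            p = _mc_chi2_p(x, codes, len(levels), n_mc, rng)
        rows.append({"gene": gene, "p_value": float(p), **freqs})
    out = pd.DataFrame(rows)
    out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def _chi2_stat(x: np.ndarray, codes: np.ndarray, L: int) -> float:
    tot_mut = x.sum()
    n = len(x)
    if tot_mut in (0, n):
        return 0.0
    stat = 0.0
    p_all = tot_mut / n
    for k in range(L):
        nk = int((codes == k).sum())
        if nk == 0:
            continue
        for obs, exp in ((x[codes == k].sum(), nk * p_all),
                         (nk - x[codes == k].sum(), nk * (1 - p_all))):
            if exp > 0:
                stat += (obs - exp) ** 2 / exp
    return stat


def _mc_chi2_p(x, codes, L, n_mc, rng) -> float:
    obs = _chi2_stat(x, codes, L)
    hits = 0
    perm = codes.copy()
    for _ in range(n_mc):
        rng.shuffle(perm)
        if _chi2_stat(x, perm, L) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def age_trend(gene_indicator: pd.Series, ages: pd.Series,
              bins: list[float]) -> tuple[pd.DataFrame, float]:
    """Per-age-bin mutation proportion and Cochran-Armitage trend test.

    `bins` are edges (left-inclusive, right-exclusive except the last);
    scores are equally spaced over the bins.  Requires >= 3 non-empty bins.
    Returns the per-bin table and the two-sided trend p-value.
    """
    ages = ages.reindex(gene_indicator.index)
    mask = ages.notna()
    cut = pd.cut(ages[mask], bins=bins, right=False, include_lowest=True)
    x = gene_indicator[mask]
    tab = pd.DataFrame({
        "bin": cut.cat.categories.astype(str),
        "n": [int((cut == c).sum()) for c in cut.cat.categories],
        "n_mut": [int(x[cut == c].sum()) for c in cut.cat.categories],
    })
    tab = tab[tab["n"] > 0].reset_index(drop=True)
    if len(tab) < 3:
        raise ValueError("age trend needs >= 3 non-empty bins")
    tab["proportion"] = tab["n_mut"] / tab["n"]
    s = np.arange(len(tab), dtype=float)          # equally spaced scores
    nk, xk = tab["n"].to_numpy(float), tab["n_mut"].to_numpy(float)
    N, X = nk.sum(), xk.sum()
    pbar = X / N
    num = np.sum(s * (xk - nk * pbar))
    den = pbar * (1 - pbar) * (np.sum(nk * s ** 2) - np.sum(nk * s) ** 2 / N)
    if den <= 0:
        return tab, 1.0
    z = num / np.sqrt(den)
    p = 2 * sps.norm.sf(abs(z))
    return tab, float(p)
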