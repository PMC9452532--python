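"""Survival analysis and the count-based prognostic mutational score.

Per-gene prognostic effects are estimated by multivariable Cox
proportional-hazards regression of overall survival on the gene's
nonsilent-mutation indicator, adjusted for age, sex, and tumor stage.  The
panel construction is deliberately simple to resist overfitting on a
heterogeneous meta-cohort: genes significantly associated with worse
survival overall (HR > 1, p < 0.05) whose direction of effect holds in
both the early-stage (I/II) and late-stage (III/IV) subgroups are ranked
by mutational frequency, and the top n (default 8) form the panel.  A
patient's mutational score is the count of mutated panel genes (each gene
contributes 0 or 1 regardless of how many times it is hit), banded as
0 / 1 / >=2 for reporting.

The Cox partial likelihood is maximized by an in-package vectorized
Newton-Raphson solver with the Efron approximation for tied event times;
panel selection runs one fit per candidate gene per stratum, so the solver
is built for throughput at small covariate counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps


# --- Cox partial-likelihood solver ----------------------------------------

@dataclass
class CoxFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool

    def hr(self, j: int = 0) -> float:
        return float(np.exp(self.beta[j]))

    def ci(self, j: int = 0, alpha: float = 0.05) -> tuple[float, float]:
        z = sps.norm.ppf(1 - alpha / 2)
        with np.errstate(over="ignore"):  # inf upper bound on degenerate fits
            return (float(np.exp(self.beta[j] - z * self.se[j])),
                    float(np.exp(self.beta[j] + z * self.se[j])))

    def p(self, j: int = 0) -> float:
        if self.se[j] == 0:
            return float("nan")
        return float(2 * sps.norm.sf(abs(self.beta[j] / self.se[j])))


def _rev_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def cox_ph(X: np.ndarray, time: np.ndarray, event: np.ndarray,
           max_iter: int = 60, tol: float = 1e-9) -> CoxFit:
    """Newton-Raphson Cox fit with the Efron approximation for ties.

    X is (n, p); returns coefficient estimates, standard errors from the
    inverse observed information, and the maximized partial log-likelihood.
    Raises LinAlgError for singular designs (e.g. constant columns).
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    t, d, Xs = time[order], event[order], X[order]
    first = np.searchsorted(t, t, side="left")      # risk sets respect ties
    ev = np.flatnonzero(d)
    n_ev = len(ev)
    if n_ev == 0:
        raise ValueError("no events")
    # tie groups among events (contiguous because ev is sorted by time)
    ev_first = first[ev]
    _, inv, m = np.unique(ev_first, return_inverse=True, return_counts=True)
    grp_start = np.concatenate(([0], np.cumsum(m)[:-1]))
    l_rank = np.arange(n_ev) - grp_start[inv]       # 0..m-1 within group
    frac = l_rank / m[inv]

    beta = np.zeros(p)
    loglik_prev = -np.inf
    converged = False
    H = np.eye(p)
    for _ in range(max_iter):
        eta = Xs @ beta
        eta -= eta.max()                            # overflow guard; cancels in ratios
        w = np.exp(eta)
        wX = w[:, None] * Xs
        wXX = np.einsum("i,ij,ik->ijk", w, Xs, Xs)
        S0 = _rev_cumsum(w)[first]
        S1 = _rev_cumsum(wX)[first]
        S2 = _rev_cumsum(wXX)[first]
        D0 = np.bincount(inv, weights=w[ev])
        D1 = np.stack([np.bincount(inv, weights=wX[ev, j]) for j in range(p)], axis=1)
        D2 = np.stack([np.bincount(inv, weights=wXX[ev, j, k])
                       for j in range(p) for k in range(p)], axis=1).reshape(len(m), p, p)
        phi0 = S0[ev] - frac * D0[inv]
        phi1 = S1[ev] - frac[:, None] * D1[inv]
        phi2 = S2[ev] - frac[:, None, None] * D2[inv]
        loglik = float(eta[ev].sum() - np.log(phi0).sum())
        r = phi1 / phi0[:, None]
        grad = Xs[ev].sum(axis=0) - r.sum(axis=0)
        H = (phi2 / phi0[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", r, r)
        if not np.isfinite(loglik):
            raise np.linalg.LinAlgError("partial likelihood diverged")
        step = np.linalg.solve(H, grad)
        if abs(loglik - loglik_prev) < tol * (abs(loglik) + 1.0):
            converged = True
            break
        # step-halving keeps the likelihood ascending
        shrink, new_beta = 1.0, beta + step
        for _ in range(12):
            eta_n = Xs @ new_beta
            eta_n -= eta_n.max()
            w_n = np.exp(eta_n)
            S0_n = _rev_cumsum(w_n)[first]
            D0_n = np.bincount(inv, weights=w_n[ev])
            phi0_n = S0_n[ev] - frac * D0_n[inv]
            ll_n = float(eta_n[ev].sum() - np.log(phi0_n).sum())
            if np.isfinite(ll_n) and ll_n >= loglik - 1e-12:
                break
            shrink *= 0.5
            new_beta = beta + shrink * step
        beta = new_beta
        loglik_prev = loglik
    cov = np.linalg.inv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return CoxFit(beta=beta, se=se, loglik=loglik_prev if np.isfinite(loglik_prev) else loglik,
                  n=n, n_events=n_ev, converged=converged)


# --- per-gene adjusted Cox -------------------------------------------------

@dataclass
class GeneSurvival:
    gene: str
    n_mut: int
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    reason: str | None = None   # set when the fit was not evaluable

    @property
    def ok(self) -> bool:
        return self.reason is None


def _design(clinical: pd.DataFrame, covariates) -> tuple[pd.DataFrame, list[str]]:
    """Complete-case covariate design aligned to clinical sample ids."""
    df = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    cols = {}
    for cov in covariates:
        if cov == "age":
            cols["age"] = pd.to_numeric(df["age"], errors="coerce")
        elif cov == "sex":
            s = df["sex"].astype(str).str.lower()
            cols["sex_male"] = s.map({"male": 1.0, "m": 1.0, "female": 0.0, "f": 0.0})
        elif cov == "stage":
            st = df["stage"].astype(str).str.upper()
            for lv in ("II", "III", "IV"):
                cols[f"stage_{lv}"] = (st == lv).astype(float)
            cols["stage_II"] = cols["stage_II"].where(st.isin(["I", "II", "III", "IV"]))
        elif cov == "stage_group":
            cols["stage_late"] = df["stage_group"].map({"early": 0.0, "late": 1.0})
        else:
            cols[cov] = pd.to_numeric(df[cov], errors="coerce")
    design = pd.DataFrame(cols, index=df.index)
    design["_os_time"] = pd.to_numeric(df["os_time"], errors="coerce")
    design["_os_event"] = pd.to_numeric(df["os_event"], errors="coerce")
    return design, list(cols)


def adjusted_cox(gene_matrix: pd.DataFrame, clinical: pd.DataFrame, gene: str,
                 covariates=("age", "sex", "stage"),
                 min_events: int = 10) -> GeneSurvival:
    """Adjusted HR of a gene's mutation indicator from a multivariable Cox fit.

    Complete-case analysis (rows with any NA covariate or survival field are
    dropped); stage enters as a categorical I-IV (dummies against I).  Not
    evaluable fits come back as an NA row with a reason code instead of
    raising.
    """
    design, covs = _design(clinical, covariates)
    design = design.dropna()
    ind = gene_matrix[gene].reindex(design.index)
    design = design[ind.notna()]
    ind = ind[ind.notna()].astype(float)
    n = len(design)
    n_ev = int(design["_os_event"].sum())
    n_mut = int(ind.sum())

    def na(reason):
        return GeneSurvival(gene=gene, n_mut=n_mut, hr=np.nan, ci_low=np.nan,
                            ci_high=np.nan, p=np.nan, n=n, n_events=n_ev, reason=reason)

    if n_ev == 0:
        return na("no events")
    if n_ev < min_events:
        return na("too few events")
    if ind.nunique() < 2:
        return na("constant mutation indicator")
    X = np.column_stack([ind.to_numpy()] + [design[c].to_numpy() for c in covs])
    try:
        fit = cox_ph(X, design["_os_time"].to_numpy(), design["_os_event"].to_numpy())
    except np.linalg.LinAlgError:
        return na("singular design")
    lo, hi = fit.ci(0)
    return GeneSurvival(gene=gene, n_mut=n_mut, hr=fit.hr(0), ci_low=lo,
                        ci_high=hi, p=fit.p(0), n=n, n_events=n_ev)


# --- KM / log-rank ---------------------------------------------------------

def km_logrank(groups: pd.Series, clinical: pd.DataFrame) -> dict:
    """Kaplan-Meier curves per group and the log-rank test across groups."""
    df = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    g = groups.reindex(df.index)
    mask = g.notna() & df["os_time"].notna() & df["os_event"].notna()
    g, sub = g[mask], df[mask]
    levels = sorted(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("log-rank needs >= 2 non-empty groups")
    curves = {}
    for lv in levels:
        kmf = KaplanMeierFitter()
        kmf.fit(sub.loc[g == lv, "os_time"], sub.loc[g == lv, "os_event"], label=str(lv))
        curves[lv] = kmf
    res = multivariate_logrank_test(sub["os_time"], g, sub["os_event"])
    return {"curves": curves, "p": float(res.p_value),
            "statistic": float(res.test_statistic), "levels": levels}


# --- panel construction and the mutational score ---------------------------

@dataclass
class ScorePanel:
    genes: list[str]                       # ordered by frequency descending
    audit: pd.DataFrame = field(repr=False, default=None)
    n_requested: int = 8
    exclusions: frozenset = frozenset()


def _cox_scan(gene_matrix: pd.DataFrame, clinical: pd.DataFrame, genes,
              covariates, min_events: int = 10) -> pd.DataFrame:
    """One adjusted Cox fit per gene sharing a precomputed covariate design."""
    design, covs = _design(clinical, covariates)
    design = design.dropna()
    gm = gene_matrix.reindex(design.index)
    time = design["_os_time"].to_numpy()
    event = design["_os_event"].to_numpy()
    base = np.column_stack([design[c].to_numpy() for c in covs]) if covs else \
        np.empty((len(design), 0))
    n_ev = int(event.sum())
    rows = []
    for gene in genes:
        ind = gm[gene].to_numpy(dtype=float)
        n_mut = int(ind.sum())
        row = {"gene": gene, "n_mut": n_mut, "hr": np.nan, "ci_low": np.nan,
               "ci_high": np.nan, "p": np.nan, "reason": None}
        if n_ev == 0:
            row["reason"] = "no events"
        elif n_ev < min_events:
            row["reason"] = "too few events"
        elif n_mut == 0 or n_mut == len(ind):
            row["reason"] = "constant mutation indicator"
        else:
            try:
                fit = cox_ph(np.column_stack([ind, base]), time, event)
                row["hr"] = fit.hr(0)
                row["ci_low"], row["ci_high"] = fit.ci(0)
                row["p"] = fit.p(0)
            except np.linalg.LinAlgError:
                row["reason"] = "singular design"
        rows.append(row)
    return pd.DataFrame(rows)


def build_score_panel(gene_matrix: pd.DataFrame, clinical: pd.DataFrame,
                      n: int = 8, exclusions=frozenset(),
                      alpha: float = 0.05) -> ScorePanel:
    """Four-step construction of the prognostic gene panel.

    1. adjusted Cox (age, sex, stage) per gene on all training patients;
    2. the same model within the early and late stage subgroups, with stage
       dropped from the covariates;
    3. candidates = genes with overall HR > 1 and p < alpha whose subgroup
       HRs are both > 1, minus the capture-incompleteness exclusions;
    4. rank candidates by mutational frequency descending (alphabetical
       tie-break) and keep the top n.

    Returns the panel plus a full audit table.  Fewer than n candidates are
    returned as-is with a warning, never padded.
    """
    clin = clinical.copy()
    if "stage_group" not in clin.columns:
        from .ingest import stage_group
        clin["stage_group"] = stage_group(clin["stage"])
    genes = [g for g in gene_matrix.columns]
    overall = _cox_scan(gene_matrix, clin, genes, ("age", "sex", "stage"))
    sub = {}
    for grp in ("early", "late"):
        ids = clin.loc[clin["stage_group"] == grp, "sample_id"]
        sub[grp] = _cox_scan(gene_matrix.loc[gene_matrix.index.isin(ids)],
                             clin[clin["sample_id"].isin(ids)],
                             genes, ("age", "sex"))
    audit = overall.rename(columns={c: f"{c}_overall" for c in
                                    ("hr", "ci_low", "ci_high", "p", "reason")})
    for grp in ("early", "late"):
        audit[f"hr_{grp}"] = sub[grp]["hr"].to_numpy()
        audit[f"p_{grp}"] = sub[grp]["p"].to_numpy()
    freq = gene_matrix.mean(axis=0)
    audit["frequency"] = audit["gene"].map(freq)
    audit["excluded_capture"] = audit["gene"].isin(set(exclusions))
    audit["pass_overall"] = (audit["hr_overall"] > 1) & (audit["p_overall"] < alpha)
    audit["pass_subgroups"] = (audit["hr_early"] > 1) & (audit["hr_late"] > 1)
    audit["candidate"] = (audit["pass_overall"] & audit["pass_subgroups"]
                          & ~audit["excluded_capture"])
    cands = audit[audit["candidate"]].sort_values(
        ["frequency", "gene"], ascending=[False, True], kind="stable")
    if len(cands) < n:
        warnings.warn(f"only {len(cands)} candidate genes for a panel of {n}")
    chosen = list(cands["gene"].head(n))
    audit["selected"] = audit["gene"].isin(chosen)
    return ScorePanel(genes=chosen, audit=audit, n_requested=n,
                      exclusions=frozenset(exclusions))


def mutational_score(gene_matrix: pd.DataFrame, panel: ScorePanel | list[str]) -> pd.Series:
    """Count of mutated panel genes per patient (each gene counts once)."""
    genes = panel.genes if isinstance(panel, ScorePanel) else list(panel)
    if not genes:
        raise ValueError("panel is empty")
    present = [g for g in genes if g in gene_matrix.columns]
    score = gene_matrix[present].gt(0).sum(axis=1).astype(int)
    score.name = "mutational_score"
    return score


def score_bands(score: pd.Series) -> pd.Series:
    """Band the score as '0' / '1' / '2+' for reporting."""
    return pd.cut(score, bins=[-0.5, 0.5, 1.5, np.inf],
                  labels=["0", "1", "2+"]).astype(str)


@dataclass
class ScoreResult:
    score: pd.Series
    bands: pd.Series
    strata: dict                 # stage_group -> {"logrank_p", "hr_band": {...}}
    per_dataset: pd.DataFrame | None
    evaluable: bool = True


def _band_hrs(bands: pd.Series, clinical: pd.DataFrame) -> dict:
    """HR of each positive score band against band 0 (Cox on band dummies)."""
    df = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    b = bands.reindex(df.index)
    mask = b.notna() & df["os_time"].notna() & df["os_event"].notna()
    b, sub = b[mask], df[mask]
    out = {}
    levels = [lv for lv in ("1", "2+") if (b == lv).any()]
    if not levels or not (b == "0").any():
        return out
    X = np.column_stack([(b == lv).to_numpy(float) for lv in levels])
    try:
        fit = cox_ph(X, sub["os_time"].to_numpy(), sub["os_event"].to_numpy())
    except (np.linalg.LinAlgError, ValueError):
        return out
    for j, lv in enumerate(levels):
        lo, hi = fit.ci(j)
        out[lv] = {"hr": fit.hr(j), "ci_low": lo, "ci_high": hi, "p": fit.p(j)}
    return out


def validate_panel(panel: ScorePanel | list[str], gene_matrix: pd.DataFrame,
                   clinical: pd.DataFrame, by_dataset: bool = True,
                   min_dataset_n: int = 30) -> ScoreResult:
    """Validate the score: banded KM/log-rank within stage strata, banded
    HRs against score 0, and per-dataset stage-adjusted Cox fits.

    Per-dataset fits use the positive-vs-zero score indicator adjusted for
    the early/late stage group and keep only datasets with at least
    `min_dataset_n` survival-informative patients.
    """
    clin = clinical.copy()
    if "stage_group" not in clin.columns:
        from .ingest import stage_group
        clin["stage_group"] = stage_group(clin["stage"])
    score = mutational_score(gene_matrix, panel)
    bands = score_bands(score)
    if bands.nunique() < 2:
        return ScoreResult(score=score, bands=bands, strata={}, per_dataset=None,
                           evaluable=False)
    clin_ix = clin.set_index("sample_id")
    strata = {}
    for grp in ("early", "late"):
        ids = clin_ix.index[clin_ix["stage_group"] == grp]
        b = bands.reindex(ids).dropna()
        sub = clin_ix.loc[b.index]
        entry = {"logrank_p": np.nan, "hr_band": {}}
        if b.nunique() >= 2 and sub["os_event"].sum() >= 1:
            entry["logrank_p"] = km_logrank(b, sub.reset_index())["p"]
            entry["hr_band"] = _band_hrs(b, sub.reset_index())
        strata[grp] = entry
    per_ds = None
    if by_dataset:
        rows = []
        pos = (score > 0).astype(float)
        for ds, grp in clin.groupby("dataset_id"):
            ok = grp.dropna(subset=["os_time", "os_event"])
            if len(ok) < min_dataset_n:
                continue
            design, _ = _design(ok, ("stage_group",))
            design = design.dropna()
            ind = pos.reindex(design.index)
            keep = ind.notna()
            design, ind = design[keep], ind[keep]
            row = {"dataset_id": ds, "n": len(design),
                   "n_positive": int(ind.sum()), "hr": np.nan,
                   "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}
            if 0 < ind.sum() < len(ind) and design["_os_event"].sum() > 0:
                try:
                    fit = cox_ph(np.column_stack([ind.to_numpy(),
                                                  design["stage_late"].to_numpy()]),
                                 design["_os_time"].to_numpy(),
                                 design["_os_event"].to_numpy())
                    row["hr"] = fit.hr(0)
                    row["ci_low"], row["ci_high"] = fit.ci(0)
                    row["p"] = fit.p(0)
                except (np.linalg.LinAlgError, ValueError):
                    pass
            rows.append(row)
        per_ds = pd.DataFrame(rows)
    return ScoreResult(score=score, bands=bands, strata=strata, per_dataset=per_ds)


def region_survival(records: pd.DataFrame, clinical: pd.DataFrame, gene: str,
                    region: tuple[int, int], cds: tuple[int, int] | None = None) -> dict:
    """Stratified survival by mutation locus: in-region vs out-of-region vs WT.

    `region` is a 1-based inclusive coding interval of the gene (e.g. a
    functional domain); patients with any nonsilent mutation inside it form
    the in-region stratum (priority over out-of-region).  Log-rank is run
    across the strata within each stage group.
    """
    from .ingest import classify_nonsilent, stage_group as _sg
    lo, hi = region
    if cds is not None and not (cds[0] <= lo and hi <= cds[1]):
        raise ValueError(f"region {region} outside gene CDS {cds}")
    if lo > hi:
        raise ValueError("region start must be <= end")
    rec = records[(records["gene"] == gene)
                  & records["variant_class"].map(classify_nonsilent)]
    in_ids = set(rec.loc[rec["pos"].between(lo, hi), "sample_id"])
    out_ids = set(rec["sample_id"]) - in_ids
    clin = clinical.copy()
    if "stage_group" not in clin.columns:
        clin["stage_group"] = _sg(clin["stage"])
    strata = pd.Series("WT", index=clin["sample_id"], name="stratum")
    strata[strata.index.isin(out_ids)] = "out_region"
    strata[strata.index.isin(in_ids)] = "in_region"
    results = {"strata": strata}
    clin_ix = clin.set_index("sample_id")
    for grp in ("early", "late"):
        ids = clin_ix.index[clin_ix["stage_group"] == grp]
        s = strata.reindex(ids)
        present = s[s.notna()]
        if present.nunique() >= 2:
            results[grp] = km_logrank(present, clin_ix.loc[present.index].reset_index())
        else:
            results[grp] = None
    return results
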