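"""Significantly-mutated-gene selection by combined criteria.

Per gene the pipeline computes the cohort mutational frequency, the
CDS-length-adjusted mutational density (mutations per patient per Mb of
CDS), and the raw nonsynonymous/synonymous count ratio (a positive-selection
heuristic, not the site-normalized evolutionary dN/dS).  External per-gene
scores from background-mutation-model tools (a Q value) and hotspot
clustering tools (a cluster score) are consumed as input columns.  A gene
is called significant only when all five criteria pass:

    1. mutational frequency >= 2%
    2. external Q value <= 0.01
    3. external cluster score >= 0.2
    4. mutational density >= 50
    5. dN/dS >= 5

Datasets that deposited only nonsilent records (no synonymous calls) are
excluded beforehand; they would inflate dN/dS and densities for everyone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import classify_nonsilent


@dataclass
class SelectionThresholds:
    min_frequency: float = 0.02
    max_q: float = 0.01
    min_cluster_score: float = 0.2
    min_density: float = 50.0
    min_dnds: float = 5.0

    def __post_init__(self):
        for name in ("min_frequency", "max_q", "min_cluster_score",
                     "min_density", "min_dnds"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or math.isnan(v):
                raise ValueError(f"threshold {name} must be numeric")


def mutational_density(n_mutations: int, n_patients: int, cds_length_bp: int) -> float:
    """Mutations per patient per megabase of CDS.

    density = (n_mutations / n_patients) / (cds_length_bp / 1e6).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if cds_length_bp < 1:
        raise ValueError("CDS length must be >= 1 bp")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    return (n_mutations / n_patients) / (cds_length_bp / 1e6)


def dnds(n_nonsilent: int, n_synonymous: int) -> float:
    """Raw nonsilent / synonymous count ratio.

    0/0 is undefined (NaN, fails any threshold); x/0 with x > 0 is +inf
    (passes any finite threshold).
    """
    if n_nonsilent < 0 or n_synonymous < 0:
        raise ValueError("counts must be >= 0")
    if n_synonymous == 0:
        return float("inf") if n_nonsilent > 0 else float("nan")
    return n_nonsilent / n_synonymous


def prefilter_datasets(records: pd.DataFrame, flagged: set[str] | None = None,
                       *, auto_detect: bool = True,
                       min_records_for_detection: int = 500) -> tuple[pd.DataFrame, set[str]]:
    """Remove datasets that carry no synonymous records.

    `flagged` datasets are always removed.  With `auto_detect`, any dataset
    contributing more than `min_records_for_detection` records but zero
    synonymous ones is flagged too (with a warning): such sources deposited
    nonsilent-only lists and would bias dN/dS and density upward.
    """
    flagged = set(flagged or ())
    if auto_detect and len(records):
        syn = records["variant_class"].isin(["Silent", "Synonymous"])
        per_ds = records.groupby("dataset_id").agg(
            n=("dataset_id", "size"))
        per_ds["n_syn"] = syn.groupby(records["dataset_id"]).sum()
        auto = per_ds[(per_ds["n"] > min_records_for_detection)
                      & (per_ds["n_syn"] == 0)].index
        if len(auto):
            warnings.warn("datasets without synonymous records excluded from "
                          f"driver statistics: {sorted(auto)}")
            flagged |= set(auto)
    out = records[~records["dataset_id"].isin(flagged)].reset_index(drop=True)
    return out, flagged


def modal_transcript(transcripts: pd.Series, cds_lengths: dict[str, int] | None = None):
    """Most common transcript among a gene's records; ties -> longest CDS."""
    counts = transcripts.dropna().value_counts()
    if counts.empty:
        return None
    top = counts[counts == counts.iloc[0]].index
    if len(top) > 1 and cds_lengths:
        return max(top, key=lambda t: cds_lengths.get(t, -1))
    return top[0]


@dataclass
class GeneStatsTable:
    table: pd.DataFrame
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)

    @property
    def selected(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "gene"])


def gene_stats(records: pd.DataFrame, cds_lengths: dict[str, int],
               n_patients: int | None = None, *,
               density_numerator: str = "nonsilent") -> pd.DataFrame:
    """Per-gene counts, frequency, mutational density and dN/dS.

    `density_numerator` selects which mutation count enters the density:
    'nonsilent' (default; the density threshold of 50 is calibrated to it)
    or 'synonymous'.  `n_patients` defaults to the number of distinct
    samples in `records` — pass the cohort size explicitly when patients
    without mutations exist.
    """
    if density_numerator not in ("nonsilent", "synonymous"):
        raise ValueError("density_numerator must be 'nonsilent' or 'synonymous'")
    if n_patients is None:
        n_patients = records["sample_id"].nunique()
    ns_mask = records["variant_class"].map(classify_nonsilent)
    syn_mask = records["variant_class"].isin(["Silent", "Synonymous"])
    rows = []
    for gene, grp in records.groupby("gene"):
        if gene not in cds_lengths:
            continue
        n_ns = int(ns_mask[grp.index].sum())
        n_syn = int(syn_mask[grp.index].sum())
        n_mut_patients = grp.loc[ns_mask[grp.index], "sample_id"].nunique()
        cds = cds_lengths[gene]
        num = n_ns if density_numerator == "nonsilent" else n_syn
        rows.append({
            "gene": gene,
            "transcript": modal_transcript(grp["transcript"]) if "transcript" in grp else None,
            "cds_length_bp": cds,
            "n_patients_cohort": n_patients,
            "n_mut_patients": n_mut_patients,
            "frequency": n_mut_patients / n_patients,
            "n_nonsilent_mutations": n_ns,
            "n_synonymous_mutations": n_syn,
            "mutational_density": mutational_density(num, n_patients, cds),
            "dnds_ratio": dnds(n_ns, n_syn),
        })
    return pd.DataFrame(rows)


def combine_selection(stats: pd.DataFrame,
                      external: pd.DataFrame | None = None,
                      thresholds: SelectionThresholds | None = None,
                      *, allow_missing_external: bool = False) -> GeneStatsTable:
    """Apply the five-criterion combined selection.

    `external` is a per-gene table with columns gene, q_value,
    cluster_score.  A gene is selected iff all five criteria pass; a null
    external value fails its criterion unless `allow_missing_external`
    relaxes it to "not evaluable" (the remaining four must then pass).
    The returned audit table records every criterion's boolean.
    """
    th = thresholds or SelectionThresholds()
    df = stats.copy()
    if external is not None:
        ext = external.set_index("gene")
        df["external_q"] = df["gene"].map(ext["q_value"])
        df["external_cluster_score"] = df["gene"].map(ext["cluster_score"])
    else:
        df["external_q"] = np.nan
        df["external_cluster_score"] = np.nan

    df["pass_frequency"] = df["frequency"] >= th.min_frequency
    df["pass_density"] = df["mutational_density"] >= th.min_density
    df["pass_dnds"] = df["dnds_ratio"] >= th.min_dnds  # NaN compares False
    q_known = df["external_q"].notna()
    c_known = df["external_cluster_score"].notna()
    if allow_missing_external:
        df["pass_q"] = np.where(q_known, df["external_q"] <= th.max_q, True)
        df["pass_cluster"] = np.where(
            c_known, df["external_cluster_score"] >= th.min_cluster_score, True)
    else:
        df["pass_q"] = q_known & (df["external_q"] <= th.max_q)
        df["pass_cluster"] = c_known & (df["external_cluster_score"] >= th.min_cluster_score)
    crit = ["pass_frequency", "pass_q", "pass_cluster", "pass_density", "pass_dnds"]
    df["selected"] = df[crit].all(axis=1)
    df = df.sort_values(["selected", "frequency"], ascending=[False, False]).reset_index(drop=True)
    return GeneStatsTable(table=df, thresholds=th)
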