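"""Read, verify, deduplicate, and harmonize mutation records and clinical data.

Mutation records arrive as MAF-like TSV (1-based inclusive coordinates);
sample identifiers are dataset-prefixed so multi-source cohorts cannot
collide.  Reference-base authenticity is checked against the genome build
the coordinates claim, duplicated samples are detected by pairwise Jaccard
comparison of site-allele profiles, and nonsilent classification gates the
gene-level indicator matrix used by all downstream frequency and survival
analyses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "Tumor_Sample_Barcode", "Dataset", "Chromosome", "Start_Position",
    "Reference_Allele", "Tumor_Seq_Allele2", "Hugo_Symbol",
    "Variant_Classification",
)

#: canonical column names used internally
_RENAME = {
    "Tumor_Sample_Barcode": "sample_id",
    "Dataset": "dataset_id",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Hugo_Symbol": "gene",
    "Transcript_ID": "transcript",
    "Variant_Classification": "variant_class",
    "Variant_Type": "variant_type",
}

NONSILENT = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation",
    "Translation_Start_Site", "Splice_Site",
    "Frame_Shift_Ins", "Frame_Shift_Del", "In_Frame_Ins", "In_Frame_Del",
})
SILENT = frozenset({
    "Silent", "Synonymous", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank",
    "IGR", "RNA", "Intergenic",
})


def classify_nonsilent(variant_class: str, *, strict: bool = False) -> bool:
    """True for protein-altering classes, False for silent/noncoding ones.

    Unknown classes raise in strict mode, otherwise warn and return False
    (protects frequency denominators from inflated noise).
    """
    if variant_class in NONSILENT:
        return True
    if variant_class in SILENT:
        return False
    if strict:
        raise ValueError(f"unknown variant classification: {variant_class!r}")
    warnings.warn(f"unknown variant classification {variant_class!r}; treated as silent")
    return False


def read_records(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a MAF-like TSV into the canonical record table.

    Returns (records, rejects); malformed rows land in the reject report
    with a reason, never silently dropped.  A missing required column is a
    hard error naming it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    df = df.rename(columns=_RENAME)
    if "transcript" not in df.columns:
        df["transcript"] = pd.NA
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    ref = df["ref"].astype(str)
    alt = df["alt"].astype(str)
    if "variant_type" not in df.columns:
        df["variant_type"] = np.where(
            (ref.str.len() == 1) & (alt.str.len() == 1) & (ref != "-") & (alt != "-"),
            "SNP", np.where(ref.str.len() > alt.str.len(), "DEL", "INS"))
    reason = pd.Series("", index=df.index)
    reason[df["pos"].isna() | (df["pos"] < 1)] = "invalid position"
    reason[(ref == alt) & (reason == "")] = "ref == alt"
    is_snv = df["variant_type"].isin(["SNP", "SNV"])
    bad_snv = is_snv & ((ref.str.len() != 1) | (alt.str.len() != 1))
    reason[bad_snv & (reason == "")] = "SNV alleles must be single bases"
    rejects = df[reason != ""].assign(reason=reason[reason != ""])
    records = df[reason == ""].copy()
    records["pos"] = records["pos"].astype(int)
    return records.reset_index(drop=True), rejects.reset_index(drop=True)


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical TSV and derive the early/late stage grouping.

    Stage I/II map to 'early', III/IV to 'late'; anything else is NA.
    """
    df = pd.read_csv(path, sep="\t")
    return prepare_clinical(df)


def prepare_clinical(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "stage" in df.columns:
        df["stage_group"] = stage_group(df["stage"])
    if "os_time" in df.columns and (pd.to_numeric(df["os_time"], errors="coerce") < 0).any():
        raise ValueError("negative overall-survival times")
    return df


def stage_group(stage: pd.Series) -> pd.Series:
    s = stage.astype(str).str.strip().str.upper()
    out = pd.Series(pd.NA, index=stage.index, dtype="object")
    out[s.isin(["I", "II"])] = "early"
    out[s.isin(["III", "IV"])] = "late"
    return out


def verify_reference(records: pd.DataFrame, genome) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Check each record's ref allele against the genome.

    A record is verified iff the genome base(s) at [pos, pos + |ref| - 1]
    (1-based, case-insensitive) equal the ref allele; pure insertions
    (ref '-') only need their anchor position to lie on the contig.
    Returns (verified, mismatches); an absent contig is a hard error.
    """
    contigs = set(records["chrom"].astype(str).unique())
    try:
        available = set(genome.keys())
    except AttributeError:
        available = {str(k) for k in genome}
    absent = contigs - {str(c) for c in available}
    if absent:
        raise ValueError(f"contig(s) absent from genome: {sorted(absent)}")
    seqs = {c: str(genome[c][:]).upper() for c in contigs}
    ok = np.ones(len(records), dtype=bool)
    for i, row in enumerate(records.itertuples(index=False)):
        seq = seqs[str(row.chrom)]
        p0 = int(row.pos) - 1
        ref = str(row.ref).upper()
        if ref == "-":  # insertion: anchored representation, check flank exists
            ok[i] = 0 <= p0 < len(seq)
            continue
        ok[i] = seq[p0:p0 + len(ref)] == ref
    return records[ok].reset_index(drop=True), records[~ok].reset_index(drop=True)


def detect_duplicates(records: pd.DataFrame, threshold: float = 0.5,
                      screen_floor: float = 0.0) -> pd.DataFrame:
    """Pairwise Jaccard of site-allele profiles to flag duplicated samples.

    Profiles are sets of chrom:pos:ref:alt keys.  Only pairs sharing at
    least one site are scored (inverted-index candidate screen), which makes
    the comparison scale with real overlap rather than all sample pairs.
    Returns a symmetric-by-construction table (sample_a < sample_b) with
    jaccard and a `flagged` column for jaccard >= threshold.
    """
    key = (records["chrom"].astype(str) + ":" + records["pos"].astype(str)
           + ":" + records["ref"].astype(str) + ":" + records["alt"].astype(str))
    profiles: dict[str, set] = {
        s: set(k) for s, k in key.groupby(records["sample_id"].to_numpy())
    }
    sizes = {s: len(v) for s, v in profiles.items()}
    inter: dict[tuple, int] = {}
    site_index: dict[str, list] = {}
    for s, sites in profiles.items():
        for site in sites:
            site_index.setdefault(site, []).append(s)
    for members in site_index.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = sorted((members[i], members[j]))
                inter[(a, b)] = inter.get((a, b), 0) + 1
    rows = []
    for (a, b), shared in inter.items():
        jac = shared / (sizes[a] + sizes[b] - shared)
        if jac >= screen_floor:
            rows.append((a, b, jac, jac >= threshold))
    out = pd.DataFrame(rows, columns=["sample_a", "sample_b", "jaccard", "flagged"])
    return out.sort_values("jaccard", ascending=False).reset_index(drop=True)


def resolve_duplicates(records: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Drop one member of each flagged duplicate pair.

    Keeps the member from the larger dataset (more records available there),
    breaking ties lexicographically by sample id.
    """
    if pairs.empty:
        return records
    ds_size = records.groupby("dataset_id")["sample_id"].nunique()
    sample_ds = records.drop_duplicates("sample_id").set_index("sample_id")["dataset_id"]
    drop = set()
    for row in pairs[pairs["flagged"]].itertuples(index=False):
        a, b = row.sample_a, row.sample_b
        na, nb = ds_size.get(sample_ds[a], 0), ds_size.get(sample_ds[b], 0)
        if na > nb:
            drop.add(b)
        elif nb > na:
            drop.add(a)
        else:
            drop.add(max(a, b))
    return records[~records["sample_id"].isin(drop)].reset_index(drop=True)


def keep_earliest_sample(records: pd.DataFrame, patient_col: str = "patient_id",
                         timepoint_col: str | None = None) -> pd.DataFrame:
    """Keep one tumor sample per patient: the earliest.

    Earliest means the smallest value in `timepoint_col` when present;
    otherwise the first sample by file order, with a warning.  Records
    without a patient column are returned unchanged.
    """
    if patient_col not in records.columns:
        return records
    if timepoint_col and timepoint_col in records.columns:
        order = records.sort_values(timepoint_col, kind="stable")
    else:
        warnings.warn("no timepoint column; keeping first sample per patient by file order")
        order = records
    keep = order.drop_duplicates(patient_col)["sample_id"].unique()
    return records[records["sample_id"].isin(keep)].reset_index(drop=True)


@dataclass
class GeneMatrix:
    """Patients x genes nonsilent-mutation indicator plus multiplicity."""

    indicator: pd.DataFrame
    multiplicity: pd.DataFrame

    def __post_init__(self):
        assert (self.multiplicity.to_numpy() >= self.indicator.to_numpy()).all()


def build_gene_matrix(records: pd.DataFrame, clinical: pd.DataFrame | None = None,
                      *, strict: bool = False) -> GeneMatrix:
    """Gene-level indicator (>=1 nonsilent record) and multiplicity counts.

    Patients present in `clinical` but without records get all-zero rows;
    record samples absent from clinical are kept with a warning.
    """
    ns = records[
        records["variant_class"].map(lambda c: classify_nonsilent(c, strict=strict))
    ] if len(records) else records
    counts = (ns.groupby(["sample_id", "gene"]).size().unstack(fill_value=0)
              if len(ns) else pd.DataFrame())
    patients = list(counts.index)
    if clinical is not None:
        clin_ids = list(clinical["sample_id"])
        extra = [p for p in patients if p not in set(clin_ids)]
        if extra:
            warnings.warn(f"{len(extra)} sample(s) missing from clinical table; kept")
        patients = clin_ids + extra
    mult = counts.reindex(index=patients, fill_value=0).fillna(0).astype(int)
    mult.index.name = "sample_id"
    return GeneMatrix(indicator=(mult > 0).astype(int), multiplicity=mult)


def qc_report(n_read: int, n_rejected: int, n_verified: int, n_mismatch: int,
              duplicates: pd.DataFrame) -> dict:
    return {
        "records_read": int(n_read),
        "records_rejected": int(n_rejected),
        "records_verified": int(n_verified),
        "reference_mismatches": int(n_mismatch),
        "duplicate_pairs_flagged": int(duplicates["flagged"].sum()) if len(duplicates) else 0,
    }


def write_qc_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
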