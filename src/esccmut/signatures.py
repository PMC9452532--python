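"""SBS96 mutational-signature extraction and refitting.

Single-base substitutions are classified into 96 channels: six
pyrimidine-centered substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 16 combinations of 5' and 3' flanking bases.  De novo
signatures are extracted from a sample x 96 count matrix by non-negative
matrix factorization (multiplicative updates, Frobenius objective) with a
rank survey over candidate factorization ranks; the chosen rank is where
the cophenetic correlation of the restart-consensus clustering drops most
sharply.  Fixed signatures can then be refit onto any cohort by per-sample
non-negative least squares, matched to a reference catalog by cosine
similarity, and used to group patients by their dominant mutational
process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Canonical channel order: substitution class major, then 5' base, then 3' base.
CHANNELS96 = tuple(
    f"{l}[{sub}]{r}" for sub in SUB_CLASSES for l in _BASES for r in _BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS96)}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_of(ref: str, alt: str, left: str, right: str) -> str | None:
    """Map a substitution with flanking bases to its SBS96 channel.

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand.  Returns None for non-ACGT bases or ref == alt.
    """
    ref, alt, left, right = ref.upper(), alt.upper(), left.upper(), right.upper()
    if any(b not in _BASES for b in (ref, alt, left, right)) or ref == alt:
        return None
    if ref in "AG":
        ref, alt = revcomp(ref), revcomp(alt)
        left, right = revcomp(right), revcomp(left)
    return f"{left}[{ref}>{alt}]{right}"


def build_sbs96(records: pd.DataFrame, genome) -> tuple[pd.DataFrame, dict]:
    """Tally SNVs into a sample x 96 count matrix.

    Parameters
    ----------
    records
        Mutation table with columns sample_id, chrom, pos (1-based), ref, alt.
        Non-SNV rows (allele length != 1) are dropped and reported.
    genome
        Mapping of contig name -> sequence (a `pyfaidx.Fasta` or plain dict
        of strings); used to fetch the flanking context.

    Returns
    -------
    (matrix, report)
        ``matrix`` is indexed by sample with the canonical 96 columns;
        ``report`` counts rows used / dropped by reason.
    """
    samples = pd.unique(records["sample_id"])
    mat = pd.DataFrame(
        0, index=pd.Index(samples, name="sample_id"), columns=list(CHANNELS96), dtype=int
    )
    report = {"n_input": len(records), "n_used": 0, "n_non_snv": 0,
              "n_bad_context": 0, "n_off_contig": 0}
    seqs: dict[str, str] = {}
    for row in records.itertuples(index=False):
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) != 1 or len(alt) != 1 or ref == "-" or alt == "-":
            report["n_non_snv"] += 1
            continue
        chrom = str(row.chrom)
        if chrom not in seqs:
            seqs[chrom] = str(genome[chrom][:])
        seq = seqs[chrom]
        pos = int(row.pos)  # 1-based
        if pos < 2 or pos > len(seq) - 1:
            report["n_off_contig"] += 1
            continue
        ch = channel_of(ref, alt, seq[pos - 2], seq[pos])
        if ch is None:
            report["n_bad_context"] += 1
            continue
        mat.loc[row.sample_id, ch] += 1
        report["n_used"] += 1
    return mat, report


@dataclass
class NMFResult:
    """One factorization V ~ exposures @ signatures."""

    signatures: pd.DataFrame    # k x 96, rows sum to 1
    exposures: pd.DataFrame     # samples x k, absolute counts scale
    rss: float
    objective_history: np.ndarray = field(repr=False, default=None)

    @property
    def exposure_fractions(self) -> pd.DataFrame:
        return _to_fractions(self.exposures)


def _to_fractions(expo: pd.DataFrame) -> pd.DataFrame:
    tot = expo.sum(axis=1)
    frac = expo.div(tot.where(tot > 0), axis=0).fillna(0.0)
    return frac


def _mu_nmf(V: np.ndarray, k: int, rng: np.random.Generator,
            max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF minimizing ||V - WH||_F^2.

    Returns (W, H, objective history).  The multiplicative updates make the
    objective non-increasing; the trajectory is kept so tests can assert it.
    """
    n, m = V.shape
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = rng.uniform(0.1, 1.1, size=(n, k)) * scale
    H = rng.uniform(0.1, 1.1, size=(k, m)) * scale
    eps = 1e-12
    hist = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        obj = float(np.linalg.norm(V - W @ H) ** 2)
        hist.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(prev, 1e-30):
            break
        prev = obj
    return W, H, np.asarray(hist)


def nmf_factorize(matrix: pd.DataFrame, k: int, seed: int = 0,
                  max_iter: int = 2000, tol: float = 1e-6) -> NMFResult:
    """Factorize a sample x 96 matrix into k signatures and exposures.

    All-zero sample rows are removed (with a warning) before fitting.
    Signature rows are scaled to probability vectors, with the compensating
    scale folded into the exposures, so exposures stay on the mutation-count
    scale.  Signatures are named sig1..sigk ordered by total contribution
    (descending).
    """
    if not 1 <= k < min(matrix.shape[0], matrix.shape[1]):
        raise ValueError(f"rank k={k} out of range for matrix {matrix.shape}")
    row_tot = matrix.sum(axis=1)
    if (row_tot == 0).any():
        warnings.warn(f"removing {(row_tot == 0).sum()} all-zero sample rows before NMF")
        matrix = matrix.loc[row_tot > 0]
    V = matrix.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    W, H, hist = _mu_nmf(V, k, rng, max_iter, tol)
    # scale H rows to probability vectors
    s = H.sum(axis=1)
    s[s == 0] = 1.0
    H = H / s[:, None]
    W = W * s[None, :]
    order = np.argsort(-W.sum(axis=0), kind="stable")
    W, H = W[:, order], H[order]
    names = [f"sig{i + 1}" for i in range(k)]
    sigs = pd.DataFrame(H, index=names, columns=matrix.columns)
    expo = pd.DataFrame(W, index=matrix.index, columns=names)
    return NMFResult(signatures=sigs, exposures=expo,
                     rss=float(np.linalg.norm(V - W @ H) ** 2),
                     objective_history=hist)


@dataclass
class RankSurvey:
    ks: list[int]
    cophenetic: dict[int, float]
    rss: dict[int, float]
    n_restarts: int
    selected_k: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.ks,
             "cophenetic": [self.cophenetic[k] for k in self.ks],
             "rss": [self.rss[k] for k in self.ks]}
        )


def _consensus_cophenetic(memberships: list[np.ndarray]) -> float:
    """Cophenetic correlation of the restart-consensus co-clustering matrix.

    Samples co-cluster in one restart when they share the argmax-exposure
    component.  The consensus (fraction of restarts co-clustered) is turned
    into a dissimilarity whose average-linkage dendrogram is compared with
    the dissimilarity itself.
    """
    n = memberships[0].shape[0]
    C = np.zeros((n, n))
    for m in memberships:
        C += (m[:, None] == m[None, :])
    C /= len(memberships)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    dvec = squareform(D, checks=False)
    if np.allclose(dvec, dvec[0]):
        return 1.0  # degenerate: perfectly stable (or perfectly uniform) consensus
    Z = average(dvec)
    c, _ = cophenet(Z, dvec)
    return float(c)


def rank_survey(matrix: pd.DataFrame, k_range, n_restarts: int = 30,
                seed: int = 0, max_iter: int = 500, tol: float = 1e-5) -> RankSurvey:
    """Survey factorization ranks: best-of-restarts RSS and consensus stability.

    Per rank, `n_restarts` seeded factorizations are run; the RSS reported is
    the best restart's, and the cophenetic correlation measures how stable the
    argmax-exposure co-clustering is across restarts.
    """
    ks = sorted(int(k) for k in k_range)
    if n_restarts < 2:
        warnings.warn("n_restarts < 2 makes the consensus matrix degenerate "
                      "(cophenetic correlation is trivially 1)")
    coph, rss = {}, {}
    for k in ks:
        members, best = [], np.inf
        for r in range(n_restarts):
            res = nmf_factorize(matrix, k, seed=seed + 1009 * k + r,
                                max_iter=max_iter, tol=tol)
            members.append(res.exposures.to_numpy().argmax(axis=1))
            best = min(best, res.rss)
        rss[k] = best
        coph[k] = _consensus_cophenetic(members)
    survey = RankSurvey(ks=ks, cophenetic=coph, rss=rss, n_restarts=n_restarts)
    survey.selected_k = select_rank(survey)
    return survey


def select_rank(survey: RankSurvey) -> int:
    """Pick the rank before the largest drop in cophenetic correlation.

    k* = argmax_k [coph(k) - coph(k+1)] over consecutive surveyed ranks;
    ties break toward the smaller k.  The RSS curve is reported alongside in
    the survey for manual override.
    """
    ks = survey.ks
    if len(ks) < 3:
        raise ValueError("rank survey needs at least 3 candidate ranks")
    drops = [survey.cophenetic[ks[i]] - survey.cophenetic[ks[i + 1]]
             for i in range(len(ks) - 1)]
    best = int(np.argmax(drops))
    if max(drops) <= 0:
        warnings.warn("cophenetic correlation never drops; selecting smallest rank")
        return ks[0]
    return ks[best]


def refit_exposures(matrix: pd.DataFrame, signatures: pd.DataFrame) -> pd.DataFrame:
    """Refit fixed signatures onto each sample by non-negative least squares.

    Returns absolute exposures (mutation-count scale); zero-count samples get
    all-zero rows.
    """
    S = signatures.to_numpy(dtype=float)
    if not np.allclose(S.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("signature rows must be normalized probability vectors")
    V = matrix[list(signatures.columns)].to_numpy(dtype=float)
    out = np.zeros((V.shape[0], S.shape[0]))
    A = S.T  # 96 x k
    for i, v in enumerate(V):
        if v.sum() == 0:
            continue
        out[i], _ = nnls(A, v)
    return pd.DataFrame(out, index=matrix.index, columns=signatures.index)


def cosine_match(signatures: pd.DataFrame,
                 reference: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cosine similarity of each extracted signature to a reference catalog.

    The reference is reordered to the extracted channel order by column label.
    Returns the full similarity matrix and a per-signature best-match table.
    """
    ref = reference[list(signatures.columns)]
    A = signatures.to_numpy(dtype=float)
    B = ref.to_numpy(dtype=float)
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-300)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-300)
    sim = pd.DataFrame(An @ Bn.T, index=signatures.index, columns=ref.index)
    best = pd.DataFrame({
        "best_match": sim.idxmax(axis=1),
        "similarity": sim.max(axis=1),
    })
    return sim, best


def read_catalog(path) -> pd.DataFrame:
    """Read a reference signature catalog TSV.

    Accepts either 'A[C>A]A'-style row labels in the first column, or the
    COSMIC v3 layout with Type ('C>A') and SubType ('ACA') columns; signatures
    are the remaining numeric columns.  Returns signatures x 96 with canonical
    channel order.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if {"Type", "SubType"} <= set(cols):
        labels = [f"{s[0]}[{t}]{s[2]}" for t, s in zip(df["Type"], df["SubType"])]
        data = df.drop(columns=["Type", "SubType"])
    else:
        labels = df.iloc[:, 0].astype(str).tolist()
        data = df.iloc[:, 1:]
    data.index = labels
    missing = set(CHANNELS96) - set(labels)
    if missing:
        raise ValueError(f"catalog missing {len(missing)} channels, e.g. {sorted(missing)[:3]}")
    return data.loc[list(CHANNELS96)].T


def dominant_cluster(exposures: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each sample to its highest-contribution signature.

    Ties break toward the lower signature index (argmax convention).  Returns
    per-sample labels and a cluster-size table with cohort fractions.
    """
    frac = _to_fractions(exposures)
    idx = frac.to_numpy().argmax(axis=1)
    labels = pd.Series([exposures.columns[i] for i in idx],
                       index=exposures.index, name="cluster")
    sizes = labels.value_counts().reindex(exposures.columns, fill_value=0)
    table = pd.DataFrame({"n": sizes, "fraction": sizes / len(labels)})
    return labels, table
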