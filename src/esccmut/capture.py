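"""Exome capture-platform bias estimation.

Exome kits capture slightly different region sets; variants discovered by
whole-genome sequencing can fall outside a given kit's capture range and
would be invisible to cohorts sequenced on it.  The estimator computes, for
each variant, the signed distance to the nearest capture boundary
(positive inside capture, negative outside), and reports the percentage of
test-set variants more than `threshold_bp` outside capture minus the same
percentage in a reference set sequenced on that very platform — the
background subtraction absorbs annotation drift and liftover loss.  Genes
whose CDS is not fully covered are listed so downstream analyses can
exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping/adjacent 0-based half-open intervals."""
    if intervals.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        g = grp.sort_values("start")
        starts = g["start"].to_numpy(dtype=np.int64)
        ends = g["end"].to_numpy(dtype=np.int64)
        if (starts >= ends).any():
            raise ValueError("intervals must satisfy start < end")
        cs, ce = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= ce:
                ce = max(ce, e)
            else:
                rows.append((chrom, cs, ce))
                cs, ce = s, e
        rows.append((chrom, cs, ce))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class CaptureRegions:
    """Sorted, merged capture intervals (0-based half-open) for one platform."""

    platform: str
    intervals: pd.DataFrame

    def __post_init__(self):
        self.intervals = merge_intervals(self.intervals)
        self._by_chrom = {
            str(c): (grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64))
            for c, grp in self.intervals.groupby("chrom")
        }

    @classmethod
    def from_bed(cls, path, platform: str | None = None) -> "CaptureRegions":
        bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                          usecols=[0, 1, 2], names=["chrom", "start", "end"],
                          dtype={"chrom": str})
        return cls(platform=platform or str(path), intervals=bed)

    def total_bp(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())


def boundary_distance(chrom: str, pos: int, regions: CaptureRegions) -> float:
    """Signed bp distance from a 1-based locus to the nearest capture boundary.

    Positive inside an interval (minimum 1 at an edge-adjacent base),
    negative outside (bp to the nearest interval); -inf when the contig has
    no capture intervals at all.
    """
    pair = regions._by_chrom.get(str(chrom))
    if pair is None:
        return float("-inf")
    starts, ends = pair
    g = int(pos) - 1  # to 0-based
    i = int(np.searchsorted(starts, g, side="right")) - 1
    if i >= 0 and g < ends[i]:
        return float(min(g - starts[i] + 1, ends[i] - g))
    gaps = []
    if i >= 0:
        gaps.append(g - ends[i] + 1)
    if i + 1 < len(starts):
        gaps.append(starts[i + 1] - g)
    return float(-min(gaps))


def boundary_distances(records: pd.DataFrame, regions: CaptureRegions) -> np.ndarray:
    """Vectorized signed boundary distance for a record table (chrom, pos)."""
    out = np.empty(len(records))
    chroms = records["chrom"].astype(str).to_numpy()
    poss = records["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        pair = regions._by_chrom.get(chrom)
        if pair is None:
            out[m] = -np.inf
            continue
        starts, ends = pair
        g = poss[m].astype(np.int64) - 1
        i = np.searchsorted(starts, g, side="right") - 1
        inside = (i >= 0) & (g < ends[np.clip(i, 0, None)])
        d = np.empty(g.shape, dtype=float)
        ii = np.clip(i, 0, None)
        d[inside] = np.minimum(g[inside] - starts[ii[inside]] + 1,
                               ends[ii[inside]] - g[inside])
        outside = ~inside
        left = np.where(i[outside] >= 0,
                        g[outside] - ends[np.clip(i[outside], 0, None)] + 1, np.inf)
        nxt = i[outside] + 1
        right = np.where(nxt < len(starts),
                         starts[np.clip(nxt, 0, len(starts) - 1)] - g[outside], np.inf)
        d[outside] = -np.minimum(left, right)
        out[m] = d
    return out


@dataclass
class BiasEstimate:
    platform: str
    pct_outside_test: float
    pct_outside_reference: float
    estimate: float            # test minus reference, percentage points; may be negative
    threshold_bp: int
    n_test: int
    n_reference: int


def uncaptured_fraction(test_records: pd.DataFrame, reference_records: pd.DataFrame,
                        regions: CaptureRegions, threshold_bp: int = 200) -> BiasEstimate:
    """Background-subtracted percentage of variants a platform would miss.

    pct = 100 x fraction of records with signed boundary distance below
    -threshold_bp, computed for the WGS-derived test set and for the
    reference set sequenced on this platform; the estimate is their
    difference (reported as-is, possibly negative).
    """
    for name, df in (("test", test_records), ("reference", reference_records)):
        if df.empty:
            raise ValueError(f"{name} record set is empty")
    d_test = boundary_distances(test_records, regions)
    d_ref = boundary_distances(reference_records, regions)
    pct_t = 100.0 * float(np.mean(d_test < -threshold_bp))
    pct_r = 100.0 * float(np.mean(d_ref < -threshold_bp))
    return BiasEstimate(platform=regions.platform, pct_outside_test=pct_t,
                        pct_outside_reference=pct_r, estimate=pct_t - pct_r,
                        threshold_bp=threshold_bp,
                        n_test=len(test_records), n_reference=len(reference_records))


def _intersect_bp(starts_a, ends_a, starts_b, ends_b) -> int:
    """Total overlap between two merged, sorted interval lists."""
    i = j = 0
    total = 0
    while i < len(starts_a) and j < len(starts_b):
        lo = max(starts_a[i], starts_b[j])
        hi = min(ends_a[i], ends_b[j])
        if hi > lo:
            total += hi - lo
        if ends_a[i] < ends_b[j]:
            i += 1
        else:
            j += 1
    return int(total)


def incomplete_genes(regions: CaptureRegions, cds_models: pd.DataFrame) -> pd.DataFrame:
    """Genes whose CDS is not fully inside the capture regions.

    `cds_models` has columns gene, chrom, start, end (0-based half-open CDS
    intervals, possibly several per gene).  Returns (gene, cds_bp,
    uncovered_bp, uncovered_fraction) for genes with any uncovered base,
    sorted by uncovered_fraction descending.
    """
    rows = []
    for gene, grp in cds_models.groupby("gene"):
        merged = merge_intervals(grp[["chrom", "start", "end"]])
        cds_bp = int((merged["end"] - merged["start"]).sum())
        covered = 0
        for chrom, sub in merged.groupby("chrom"):
            pair = regions._by_chrom.get(str(chrom))
            if pair is None:
                continue
            covered += _intersect_bp(sub["start"].to_numpy(), sub["end"].to_numpy(),
                                     pair[0], pair[1])
        unc = cds_bp - covered
        if unc > 0:
            rows.append((gene, cds_bp, unc, unc / cds_bp))
    out = pd.DataFrame(rows, columns=["gene", "cds_bp", "uncovered_bp",
                                      "uncovered_fraction"])
    return out.sort_values("uncovered_fraction", ascending=False).reset_index(drop=True)
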