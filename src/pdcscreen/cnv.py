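"""Tumor/normal read-depth CNV calling.

The chain is: per-bin tumor/normal ratio, median centering, GC correction by
per-decile median normalization, log2 transform, per-chromosome segmentation
by greedy bottom-up merging under a BIC penalty, threshold calls on segment
means (gain > +0.7, loss < -0.7 in log2), and gene-level calls by the
fraction of a gene's exons overlapping called segments (strictly > 75%).

Coordinates are 0-based half-open throughout; SEG output converts to
1-based inclusive.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

GAIN_THRESHOLD = 0.7
LOSS_THRESHOLD = -0.7
GENE_EXON_FRACTION = 0.75


@dataclass
class Segment:
    chrom: str
    start: int          # 0-based half-open, genomic coordinates
    end: int
    start_bin: int      # index range into the per-chromosome bin table
    end_bin: int        # exclusive
    n_bins: int
    log_ratio: float
    call: str = "neutral"


@dataclass
class GeneCNVCall:
    gene: str
    status: str                       # gain | loss | neutral
    fraction_exons_overlapping: float


def normalize_coverage(bins: pd.DataFrame, n_gc_strata: int = 10,
                       min_stratum_bins: int = 20) -> pd.DataFrame:
    """Per-bin log2 tumor/normal ratio with median centering and GC correction.

    Parameters
    ----------
    bins
        Table with columns chrom, start, end, gc, normal_count, tumor_count.
    n_gc_strata
        Number of equal-width GC strata for the median correction.
    min_stratum_bins
        Strata with fewer bins borrow the global median (avoids unstable
        correction from sparse GC tails).

    Returns a copy of ``bins`` with ``log2_ratio`` (float, NaN for masked
    bins) and ``masked`` (bool) columns.  Bins with ``normal_count == 0``
    are masked, never divided.
    """
    out = bins.copy()
    normal = out["normal_count"].to_numpy(float)
    tumor = out["tumor_count"].to_numpy(float)
    masked = normal <= 0
    ratio = np.full(len(out), np.nan)
    ratio[~masked] = tumor[~masked] / normal[~masked]

    med = np.nanmedian(ratio) if not np.all(masked) else np.nan
    if med and np.isfinite(med):
        ratio = ratio / med

    # GC correction: divide by a GC-stratified median of the centered ratio
    gc = out["gc"].to_numpy(float)
    strata = np.clip((gc * n_gc_strata).astype(int), 0, n_gc_strata - 1)
    global_med = np.nanmedian(ratio) if not np.all(masked) else 1.0
    for s in range(n_gc_strata):
        sel = (strata == s) & ~masked
        if sel.sum() >= min_stratum_bins:
            m = np.nanmedian(ratio[sel])
        else:
            m = global_med
        if m > 0 and np.isfinite(m):
            ratio[sel] = ratio[sel] / m

    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2_ratio"] = np.log2(ratio)
    out["masked"] = masked
    n_masked = int(masked.sum())
    if n_masked:
        warnings.warn(f"{n_masked} bins masked (normal_count == 0)")
    return out


def _merge_cost(n1: int, s1: float, n2: int, s2: float) -> float:
    # increase in RSS when merging two adjacent segments with means s1/n1, s2/n2
    m1, m2 = s1 / n1, s2 / n2
    return n1 * n2 / (n1 + n2) * (m1 - m2) ** 2


def _segment_one(values: np.ndarray, penalty: float, sigma2: float) -> list[tuple[int, int]]:
    """Greedy bottom-up merge of one chromosome's bin values.

    Adjacent segments are merged, cheapest first, while the RSS increase of
    the merge stays below the BIC penalty term ``penalty * sigma2 * log(n)``.
    Returns (start, end) bin-index ranges partitioning [0, len(values)).
    """
    n = len(values)
    if n == 1:
        return [(0, 1)]
    threshold = penalty * sigma2 * np.log(n)

    # doubly linked list of live segments: id -> [start, end, n, sum]
    segs = {i: [i, i + 1, 1, float(values[i])] for i in range(n)}
    prev = {i: i - 1 if i > 0 else None for i in range(n)}
    nxt = {i: i + 1 if i < n - 1 else None for i in range(n)}

    heap: list[tuple[float, int, int]] = []
    for i in range(n - 1):
        c = _merge_cost(1, float(values[i]), 1, float(values[i + 1]))
        heapq.heappush(heap, (c, i, i + 1))

    while heap:
        cost, a, b = heapq.heappop(heap)
        if a not in segs or b not in segs or nxt[a] != b:
            continue  # stale entry
        # recompute: segment contents may have changed since push
        cur = _merge_cost(segs[a][2], segs[a][3], segs[b][2], segs[b][3])
        if cur > cost + 1e-15:
            heapq.heappush(heap, (cur, a, b))
            continue
        if cur >= threshold:
            break  # heap is cost-ordered; no cheaper merge remains
        # merge b into a
        segs[a][1] = segs[b][1]
        segs[a][2] += segs[b][2]
        segs[a][3] += segs[b][3]
        after = nxt[b]
        nxt[a] = after
        if after is not None:
            prev[after] = a
        del segs[b]
        if prev[a] is not None:
            p = prev[a]
            heapq.heappush(
                heap, (_merge_cost(segs[p][2], segs[p][3], segs[a][2], segs[a][3]), p, a)
            )
        if after is not None:
            heapq.heappush(
                heap, (_merge_cost(segs[a][2], segs[a][3], segs[after][2], segs[after][3]), a, after)
            )
    return sorted((s[0], s[1]) for s in segs.values())


def segment_log_ratios(bins: pd.DataFrame, penalty: float = 2.0) -> list[Segment]:
    """Segment per-bin log2 ratios into piecewise-constant segments.

    ``bins`` must carry chrom, start, end, log2_ratio (from
    :func:`normalize_coverage`); masked/NaN bins are dropped before
    segmentation.  Segments partition the retained bins per chromosome and
    the segment log_ratio is the mean of its member bins.
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    usable = bins[np.isfinite(bins["log2_ratio"])].reset_index(drop=True)
    if len(usable) == 0:
        return []
    diffs = np.diff(usable["log2_ratio"].to_numpy())
    # robust per-bin noise from first differences: |d| ~ |N(0, 2 sigma^2)|
    # away from breakpoints, so sigma = MAD-style median(|d|) / 0.9539;
    # the floor keeps the noise-free case mergeable (zero-cost merges stay
    # below a positive threshold)
    if len(diffs):
        sigma2 = (float(np.median(np.abs(diffs))) / 0.9539) ** 2 / 2.0
    else:
        sigma2 = 0.0
    sigma2 = max(sigma2, 1e-12)

    segments: list[Segment] = []
    for chrom, grp in usable.groupby("chrom", sort=False):
        vals = grp["log2_ratio"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for i, j in _segment_one(vals, penalty, sigma2):
            segments.append(
                Segment(
                    chrom=str(chrom),
                    start=int(starts[i]),
                    end=int(ends[j - 1]),
                    start_bin=i,
                    end_bin=j,
                    n_bins=j - i,
                    log_ratio=float(vals[i:j].mean()),
                )
            )
    return segments


def call_segments(
    segments: list[Segment],
    gain_thr: float = GAIN_THRESHOLD,
    loss_thr: float = LOSS_THRESHOLD,
) -> list[Segment]:
    """Set gain/loss/neutral calls: gain iff log_ratio > gain_thr (strict),
    loss iff < loss_thr (strict), neutral otherwise."""
    if not (gain_thr > 0 > loss_thr):
        raise ValueError("require gain_thr > 0 > loss_thr")
    for seg in segments:
        if seg.log_ratio > gain_thr:
            seg.call = "gain"
        elif seg.log_ratio < loss_thr:
            seg.call = "loss"
        else:
            seg.call = "neutral"
    return segments


def call_gene_cnv(
    genes: pd.DataFrame,
    segments: list[Segment],
    min_fraction: float = GENE_EXON_FRACTION,
) -> list[GeneCNVCall]:
    """Gene-level CNV calls from called segments.

    ``genes`` is an exon table (gene, chrom, start, end; 0-based half-open).
    An exon overlaps a called segment when >= 1 bp intersects it.  Per gene
    the overlapping-exon fraction is computed separately for gain and loss;
    status is the direction whose fraction is strictly > ``min_fraction``
    (ties between two qualifying directions -> neutral with a warning).
    Genes with exons on multiple chromosomes are rejected with a warning.
    """
    by_dir: dict[str, list[Segment]] = {"gain": [], "loss": []}
    for seg in segments:
        if seg.call in by_dir:
            by_dir[seg.call].append(seg)

    calls: list[GeneCNVCall] = []
    for gene, grp in genes.groupby("gene", sort=True):
        if grp["chrom"].nunique() > 1:
            warnings.warn(f"gene {gene}: exons on multiple chromosomes, skipped")
            continue
        chrom = grp["chrom"].iloc[0]
        n_exons = len(grp)
        frac = {}
        for direction, segs in by_dir.items():
            segs_c = [s for s in segs if s.chrom == chrom]
            n_over = 0
            for _, exon in grp.iterrows():
                if any(s.start < exon["end"] and s.end > exon["start"] for s in segs_c):
                    n_over += 1
            frac[direction] = n_over / n_exons
        g, l = frac["gain"], frac["loss"]
        if g > min_fraction and l > min_fraction:
            if g == l:
                warnings.warn(f"gene {gene}: gain and loss fractions tie, neutral")
                calls.append(GeneCNVCall(gene, "neutral", g))
            else:
                status = "gain" if g > l else "loss"
                calls.append(GeneCNVCall(gene, status, max(g, l)))
        elif g > min_fraction:
            calls.append(GeneCNVCall(gene, "gain", g))
        elif l > min_fraction:
            calls.append(GeneCNVCall(gene, "loss", l))
        else:
            calls.append(GeneCNVCall(gene, "neutral", max(g, l)))
    return calls


def segments_to_frame(segments: list[Segment], sample: str = "sample") -> pd.DataFrame:
    """SEG-style table (1-based inclusive coordinates)."""
    return pd.DataFrame(
        {
            "sample": sample,
            "chrom": [s.chrom for s in segments],
            "start": [s.start + 1 for s in segments],
            "end": [s.end for s in segments],
            "n_bins": [s.n_bins for s in segments],
            "log2_ratio": [s.log_ratio for s in segments],
            "call": [s.call for s in segments],
        }
    )
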