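"""Copy-number alteration calling from tumour log R ratio.

Tumour LRR is smoothed per sample and chromosome with an exact
piecewise-constant fit (PCF): the segmentation minimising

    sum over segments of within-segment SSE  +  gamma * (number of breakpoints)

subject to a minimum segment length, solved by an O(n^2) dynamic program.
Smoothed values above +0.07 are called amplification, below -0.07 deletion,
and the closed interval [-0.07, 0.07] normal (2^0.07 ~ 1.05 on the
non-logarithmic copy-ratio scale). Joint disparity x CNA classes label each
blood-heterozygous cell by its shift direction and copy-number state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PairedArrayData, ValidationError

__all__ = [
    "Segment",
    "AMPLIFICATION", "NORMAL", "DELETION",
    "CNA_LABELS",
    "pcf_segment",
    "estimate_noise_sd",
    "smooth_lrr",
    "delog",
    "locus_mean_histogram",
    "call_cna",
    "call_cna_matrix",
    "joint_classify",
    "segments_table",
]

DEFAULT_GAMMA: float = 15.0
DEFAULT_KMIN: int = 5
DEFAULT_THRESHOLD: float = 0.07

# integer CNA state codes
DELETION: int = -1
NORMAL: int = 0
AMPLIFICATION: int = 1
CNA_LABELS: dict[int, str] = {DELETION: "deletion", NORMAL: "normal", AMPLIFICATION: "amplification"}


@dataclass(frozen=True)
class Segment:
    """One constant-mean segment (inclusive locus indices within a chromosome)."""

    chromosome: str
    start_index: int
    end_index: int
    mean_value: float

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1


def pcf_segment(
    values: np.ndarray,
    gamma: float,
    kmin: int = DEFAULT_KMIN,
    chromosome: str = "1",
) -> list[Segment]:
    """Exact penalised least-squares segmentation of one signal.

    Minimises total within-segment SSE plus ``gamma`` per breakpoint, with
    every segment at least ``kmin`` points long; segment means are the
    within-segment averages. Inputs shorter than ``kmin`` (or shorter than
    ``2 * kmin``, where no breakpoint is feasible) return a single segment.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(gamma) or gamma < 0:
        raise ValidationError(f"penalty must be finite and >= 0, got {gamma}")
    if kmin < 1:
        raise ValidationError(f"kmin must be >= 1, got {kmin}")
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("pcf_segment needs a non-empty 1-D signal")
    if not np.isfinite(x).all():
        raise ValidationError("pcf_segment input must be finite (drop missing first)")
    n = x.size
    if n < 2 * kmin:
        return [Segment(chromosome, 0, n - 1, float(x.mean()))]

    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    dp = np.full(n + 1, np.inf)
    back = np.zeros(n + 1, dtype=int)
    dp[0] = -gamma  # first segment pays no breakpoint penalty
    for j in range(kmin, n + 1):
        # candidate split points: 0 or any i >= kmin with j - i >= kmin
        i = np.arange(0, j - kmin + 1)
        length = j - i
        sse = (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / length
        cand = dp[i] + gamma + sse
        k = int(np.argmin(cand))
        dp[j] = cand[k]
        back[j] = i[k]

    bounds = []
    j = n
    while j > 0:
        i = back[j]
        bounds.append((i, j))
        j = i
    segments = []
    for i, j in reversed(bounds):
        mean = (s1[j] - s1[i]) / (j - i)
        segments.append(Segment(chromosome, i, j - 1, float(mean)))
    return _merge_equal_means(segments)


def _merge_equal_means(segments: list[Segment]) -> list[Segment]:
    """Merge adjacent segments with identical means (possible at gamma = 0)."""
    out = [segments[0]]
    for seg in segments[1:]:
        prev = out[-1]
        if seg.mean_value == prev.mean_value:
            n1, n2 = prev.length, seg.length
            out[-1] = Segment(
                prev.chromosome,
                prev.start_index,
                seg.end_index,
                (prev.mean_value * n1 + seg.mean_value * n2) / (n1 + n2),
            )
        else:
            out.append(seg)
    return out


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust residual SD from first differences (MAD / 0.6745 / sqrt(2))."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return 0.0
    d = np.diff(x)
    return float(np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0))


def smooth_lrr(
    lrr: pd.DataFrame,
    loci: pd.DataFrame,
    gamma: float = DEFAULT_GAMMA,
    kmin: int = DEFAULT_KMIN,
    scale_penalty: bool = True,
) -> tuple[pd.DataFrame, dict[str, list[Segment]]]:
    """PCF-smooth an LRR matrix per sample and chromosome.

    ``gamma`` is expressed on the standardised signal: the effective penalty
    is ``gamma * sigma_hat**2`` with a per-sample robust noise estimate
    (set ``scale_penalty=False`` to use ``gamma`` directly). Missing values
    are dropped before fitting and receive the smoothed value of the
    segment enclosing their position. Returns the smoothed matrix and
    per-sample segment lists (indices are within-chromosome positions).
    """
    chroms = loci["chromosome"].to_numpy()
    smoothed = pd.DataFrame(np.nan, index=lrr.index, columns=lrr.columns)
    segment_map: dict[str, list[Segment]] = {}
    chrom_blocks = [(c, np.flatnonzero(chroms == c)) for c in pd.unique(chroms)]
    for sample in lrr.columns:
        col = lrr[sample].to_numpy(float)
        sd = estimate_noise_sd(col) if scale_penalty else 1.0
        penalty = gamma * sd * sd if scale_penalty else gamma
        if penalty == 0.0 and scale_penalty:
            penalty = gamma  # flat/degenerate signal: fall back to raw penalty
        sample_segments: list[Segment] = []
        out = np.full(col.shape, np.nan)
        for chrom, block in chrom_blocks:
            y = col[block]
            present = np.flatnonzero(np.isfinite(y))
            if present.size == 0:
                continue
            segs = pcf_segment(y[present], gamma=penalty, kmin=kmin, chromosome=str(chrom))
            # map fit indices (over present loci) back to chromosome indices,
            # propagating each segment's mean to enclosed missing loci
            starts = np.array([s.start_index for s in segs])
            means = np.array([s.mean_value for s in segs])
            for s in segs:
                sample_segments.append(
                    Segment(str(chrom), int(present[s.start_index]), int(present[s.end_index]), s.mean_value)
                )
            nearest = np.searchsorted(present, np.arange(block.size), side="right") - 1
            seg_of = np.clip(np.searchsorted(starts, nearest, side="right") - 1, 0, len(segs) - 1)
            out[block] = means[seg_of]
        smoothed[sample] = out
        segment_map[sample] = sample_segments
    return smoothed, segment_map


def delog(smoothed_lrr):
    """Transform log2 ratio to the non-logarithmic copy-ratio scale (2**x)."""
    return np.power(2.0, smoothed_lrr)


def locus_mean_histogram(
    delogged: pd.DataFrame | np.ndarray,
    bin_width: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus mean copy ratio and histogram modes (threshold diagnostics).

    Returns ``(locus_means, counts, bin_edges, peak_locations)`` where
    peaks are bin centres at local maxima of the binned histogram, ordered
    by decreasing height.
    """
    values = np.asarray(delogged, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    with np.errstate(invalid="ignore"):
        n_present = np.isfinite(values).sum(axis=1)
        means = np.where(
            n_present > 0,
            np.nansum(np.where(np.isfinite(values), values, 0.0), axis=1) / np.maximum(n_present, 1),
            np.nan,
        )
    finite = means[np.isfinite(means)]
    if finite.size == 0:
        return means, np.array([]), np.array([]), np.array([])
    lo = np.floor(finite.min() / bin_width) * bin_width
    hi = np.ceil(finite.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(finite, bins=edges)
    centres = (edges[:-1] + edges[1:]) / 2
    padded = np.concatenate(([-1], counts, [-1]))
    is_peak = (padded[1:-1] > padded[:-2]) & (padded[1:-1] >= padded[2:]) & (counts > 0)
    peaks = centres[is_peak]
    order = np.argsort(counts[is_peak])[::-1]
    return means, counts, edges, peaks[order]


def call_cna(smoothed_lrr: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Classify one smoothed LRR value; the closed band [-t, t] is normal."""
    if smoothed_lrr > threshold:
        return CNA_LABELS[AMPLIFICATION]
    if smoothed_lrr < -threshold:
        return CNA_LABELS[DELETION]
    return CNA_LABELS[NORMAL]


def call_cna_matrix(
    smoothed: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Vectorised CNA states as int8 codes (-1 deletion, 0 normal, +1 amplification).

    Missing smoothed values stay 0 (no call is interpreted as normal).
    """
    v = smoothed.to_numpy(float)
    out = np.zeros(v.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        out[v > threshold] = AMPLIFICATION
        out[v < -threshold] = DELETION
    return pd.DataFrame(out, index=smoothed.index, columns=smoothed.columns)


def joint_classify(shift_direction: str, cna_call: str) -> str:
    """Combine a disparity direction with a CNA state (Cartesian labelling).

    ``shift_direction`` in {"toward-A", "toward-B", "none"}; unshifted
    samples are labelled "unshifted" regardless of CNA state.
    """
    if shift_direction == "none":
        return "unshifted"
    side = {"toward-A": "AA", "toward-B": "BB"}[shift_direction]
    return f"{side}-{cna_call}"


def segments_table(segment_map: dict[str, list[Segment]], loci: pd.DataFrame,
                   threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Flatten per-sample segments to a BED-like table with CNA states.

    Start/end are the genomic positions (1-based, inclusive) of the first
    and last locus of each segment.
    """
    chroms = loci["chromosome"].to_numpy()
    pos = loci["position"].to_numpy()
    pos_by_chrom = {str(c): pos[chroms == c] for c in pd.unique(chroms)}
    rows = []
    for sample, segs in segment_map.items():
        for s in segs:
            chrom_pos = pos_by_chrom[s.chromosome]
            rows.append(
                {
                    "sample_id": sample,
                    "chromosome": s.chromosome,
                    "start": int(chrom_pos[s.start_index]),
                    "end": int(chrom_pos[s.end_index]),
                    "n_loci": s.length,
                    "mean_lrr": s.mean_value,
                    "state": call_cna(s.mean_value, threshold),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "chromosome", "start", "end", "n_loci", "mean_lrr", "state"])
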