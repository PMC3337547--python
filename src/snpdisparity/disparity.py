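"""Directional allelic disparity: 2-SD shift detection and score statistics.

For each retained locus the blood-heterozygous samples define a reference
cluster with mean ``mu`` and sample standard deviation ``sigma`` (n-1
denominator) of their blood BAF. A blood-AB sample is counted as shifted
toward AA if its tumour BAF falls below ``mu - k*sigma`` and toward BB if it
exceeds ``mu + k*sigma`` (k defaults to 2). Per-locus summary statistics:

* score  S = (1 - min(nAA, nBB) / max(nAA, nBB)) * 100   (0 when equal)
* r_BB = nBB / (nAA + nBB) * 100      (shifted toward the B allele)
* r_AA = nAA / (nAA + nBB) * 100
* r_AB = (nAA + nBB) / n_het * 100    (heterozygotes showing disparity)
* delta = r_BB - r_AA

plus a Hardy-Weinberg chi-square on the blood genotype counts, flagged
in-HWE when the statistic is at or below the 0.95 chi-square quantile at
1 df (3.841).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PairedArrayData, ValidationError
from .preprocess import AA, AB, BB

__all__ = [
    "HWE_CHI2_THRESHOLD",
    "HetStats",
    "DisparityRecord",
    "het_stats",
    "detect_shifts",
    "disparity_score",
    "disparity_rates",
    "hwe_test",
    "compute_disparity",
    "shift_directions",
    "select_loci",
]

log = logging.getLogger(__name__)

#: 0.95 quantile of the chi-square distribution with 1 df, to 3 decimals.
HWE_CHI2_THRESHOLD: float = 3.841


@dataclass(frozen=True)
class HetStats:
    """Blood heterozygote cluster location at one locus."""

    locus_id: str
    mu: float
    sigma: float
    n_het: int


@dataclass(frozen=True)
class DisparityRecord:
    """Per-locus disparity summary (one row of the report table)."""

    locus_id: str
    n_het: int
    n_shift_AA: int
    n_shift_BB: int
    score: float
    r_AA: float
    r_BB: float
    r_AB: float
    delta: float
    preferential_allele: str
    hwe_chi2: float
    in_hwe: bool


def het_stats(
    blood_baf_row: np.ndarray | pd.Series,
    genotype_calls: np.ndarray | pd.Series,
    locus_id: str = "",
) -> HetStats:
    """Mean/SD of blood BAF over AB-called samples (missing excluded)."""
    baf = np.asarray(blood_baf_row, dtype=float)
    calls = np.asarray(genotype_calls)
    het = (calls == AB) & np.isfinite(baf)
    n = int(het.sum())
    if n == 0:
        raise ValidationError(f"locus {locus_id}: no heterozygous blood samples")
    vals = baf[het]
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=1)) if n > 1 else float("nan")
    return HetStats(locus_id=locus_id, mu=mu, sigma=sigma, n_het=n)


def detect_shifts(
    tumour_baf_row: np.ndarray | pd.Series,
    het_sample_indices: np.ndarray,
    stats: HetStats,
    sd_multiplier: float = 2.0,
) -> tuple[int, int, dict[int, str]]:
    """Count blood-AB samples whose tumour BAF leaves the mu +/- k*sigma band.

    Returns (n_shift_AA, n_shift_BB, {sample index -> "AA"|"BB"}). Samples
    with missing tumour BAF are skipped.
    """
    t = np.asarray(tumour_baf_row, dtype=float)
    lo = stats.mu - sd_multiplier * stats.sigma
    hi = stats.mu + sd_multiplier * stats.sigma
    labels: dict[int, str] = {}
    for j in np.asarray(het_sample_indices, dtype=int):
        v = t[j]
        if not np.isfinite(v):
            continue
        if v < lo:
            labels[j] = "AA"
        elif v > hi:
            labels[j] = "BB"
    n_aa = sum(1 for d in labels.values() if d == "AA")
    n_bb = len(labels) - n_aa
    return n_aa, n_bb, labels


def disparity_score(n_shift_AA: int, n_shift_BB: int) -> float:
    """Asymmetry score S in [0, 100]; 0 for equal counts (including 0, 0)."""
    if n_shift_AA < 0 or n_shift_BB < 0:
        raise ValidationError("shift counts must be non-negative")
    if n_shift_AA == n_shift_BB:
        return 0.0
    lo, hi = sorted((n_shift_AA, n_shift_BB))
    return (1.0 - lo / hi) * 100.0


def disparity_rates(
    n_shift_AA: int, n_shift_BB: int, n_het: int
) -> tuple[float, float, float, float]:
    """Directional shift percentages (r_AA, r_BB, r_AB, delta).

    All zero when no sample shifted.
    """
    if n_het < 1:
        raise ValidationError("n_het must be >= 1")
    total = n_shift_AA + n_shift_BB
    if total > n_het:
        raise ValidationError(f"shift counts ({total}) exceed heterozygote count ({n_het})")
    if total == 0:
        return 0.0, 0.0, 0.0, 0.0
    r_aa = n_shift_AA / total * 100.0
    r_bb = n_shift_BB / total * 100.0
    r_ab = total / n_het * 100.0
    return r_aa, r_bb, r_ab, r_bb - r_aa


def hwe_test(n_AA: int, n_AB: int, n_BB: int) -> tuple[float, bool]:
    """Hardy-Weinberg chi-square on genotype counts.

    Expected counts are N*p^2, 2*N*p*q, N*q^2 with p the A-allele
    frequency; the flag is True when the statistic is <= 3.841 (0.95
    quantile at 1 df). Monomorphic input (p in {0, 1}) returns (0, True).
    """
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValidationError("HWE test needs at least one genotyped sample")
    p = (2 * n_AA + n_AB) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or p == 1.0:
        return 0.0, True
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_AB, n_BB], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, chi2 <= HWE_CHI2_THRESHOLD


_DIRECTION_LABELS = {-1: "toward-A", 0: "none", 1: "toward-B"}


def shift_directions(
    data: PairedArrayData,
    calls: pd.DataFrame,
    sd_multiplier: float = 2.0,
) -> pd.DataFrame:
    """Per-cell shift direction matrix (int8): -1 toward AA, +1 toward BB, 0 otherwise.

    Non-heterozygous cells, missing tumour BAF, and loci with fewer than two
    usable heterozygotes are all 0.
    """
    blood = data.blood_baf.to_numpy(float)
    tumour = data.tumour_baf.to_numpy(float)
    c = calls.to_numpy()
    het = (c == AB) & np.isfinite(blood)

    n_het = het.sum(axis=1)
    b = np.where(het, blood, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(n_het > 0, b.sum(axis=1) / np.maximum(n_het, 1), np.nan)
        dev2 = np.where(het, (blood - mu[:, None]) ** 2, 0.0).sum(axis=1)
        sigma = np.where(n_het > 1, np.sqrt(dev2 / np.maximum(n_het - 1, 1)), np.nan)
    usable = n_het >= 2

    lo = (mu - sd_multiplier * sigma)[:, None]
    hi = (mu + sd_multiplier * sigma)[:, None]
    valid = het & np.isfinite(tumour) & usable[:, None]
    out = np.zeros(blood.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        out[valid & (tumour < lo)] = -1
        out[valid & (tumour > hi)] = 1
    return pd.DataFrame(out, index=data.loci.index, columns=data.sample_ids)


def compute_disparity(
    data: PairedArrayData,
    calls: pd.DataFrame,
    sd_multiplier: float = 2.0,
) -> pd.DataFrame:
    """Per-locus disparity table for all loci with >= 2 usable heterozygotes.

    Columns: annotation (gene, chromosome, position, cytoband), blood
    genotype counts and derived quantities (pct_het, maf, HWE), the
    heterozygote cluster (mu, sigma, n_het), shift counts and the score and
    rate statistics. Loci with fewer than two heterozygotes are skipped
    with a logged reason (the 2-SD band is undefined).
    """
    blood = data.blood_baf.to_numpy(float)
    c = calls.to_numpy()

    n_aa = (c == AA).sum(axis=1)
    n_ab = (c == AB).sum(axis=1)
    n_bb = (c == BB).sum(axis=1)
    n_typed = n_aa + n_ab + n_bb

    het = (c == AB) & np.isfinite(blood)
    n_het = het.sum(axis=1)
    b = np.where(het, blood, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(n_het > 0, b.sum(axis=1) / np.maximum(n_het, 1), np.nan)
        dev2 = np.where(het, (blood - mu[:, None]) ** 2, 0.0).sum(axis=1)
        sigma = np.where(n_het > 1, np.sqrt(dev2 / np.maximum(n_het - 1, 1)), np.nan)

    skipped = int((n_het < 2).sum())
    if skipped:
        log.info("skipping %d loci with fewer than 2 usable heterozygotes", skipped)

    dirs = shift_directions(data, calls, sd_multiplier=sd_multiplier).to_numpy()
    n_shift_aa = (dirs == -1).sum(axis=1)
    n_shift_bb = (dirs == 1).sum(axis=1)

    keep = n_het >= 2
    idx = data.loci.index[keep]
    n_aa, n_ab, n_bb, n_typed = (a[keep] for a in (n_aa, n_ab, n_bb, n_typed))
    n_het_k = n_het[keep]
    mu, sigma = mu[keep], sigma[keep]
    n_shift_aa, n_shift_bb = n_shift_aa[keep], n_shift_bb[keep]

    total = n_shift_aa + n_shift_bb
    with np.errstate(divide="ignore", invalid="ignore"):
        r_aa = np.where(total > 0, n_shift_aa / np.maximum(total, 1) * 100.0, 0.0)
        r_bb = np.where(total > 0, n_shift_bb / np.maximum(total, 1) * 100.0, 0.0)
        r_ab = np.where(total > 0, total / n_het_k * 100.0, 0.0)
    delta = r_bb - r_aa
    hi = np.maximum(n_shift_aa, n_shift_bb)
    lo_c = np.minimum(n_shift_aa, n_shift_bb)
    score = np.where(hi > lo_c, (1.0 - lo_c / np.maximum(hi, 1)) * 100.0, 0.0)
    pref = np.where(
        n_shift_aa > n_shift_bb, "toward-A", np.where(n_shift_bb > n_shift_aa, "toward-B", "none")
    )

    # HWE from blood genotype counts; vectorised version of hwe_test
    N = n_typed.astype(float)
    p = (2 * n_aa + n_ab) / (2 * N)
    q = 1.0 - p
    mono = (p == 0.0) | (p == 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        exp_aa, exp_ab, exp_bb = N * p * p, 2 * N * p * q, N * q * q
        chi2 = (
            (n_aa - exp_aa) ** 2 / exp_aa
            + (n_ab - exp_ab) ** 2 / exp_ab
            + (n_bb - exp_bb) ** 2 / exp_bb
        )
    chi2 = np.where(mono, 0.0, chi2)
    maf = np.minimum(p, q)

    ann = data.loci.loc[idx]
    return pd.DataFrame(
        {
            "gene": ann["gene"].to_numpy(),
            "chromosome": ann["chromosome"].to_numpy(),
            "position": ann["position"].to_numpy(),
            "cytoband": ann["cytoband"].to_numpy(),
            "n_AA": n_aa,
            "n_AB": n_ab,
            "n_BB": n_bb,
            "pct_het": n_ab / N * 100.0,
            "maf": maf,
            "hwe_chi2": chi2,
            "in_hwe": chi2 <= HWE_CHI2_THRESHOLD,
            "n_het": n_het_k,
            "mu": mu,
            "sigma": sigma,
            "n_shift_AA": n_shift_aa,
            "n_shift_BB": n_shift_bb,
            "r_AA": r_aa,
            "r_BB": r_bb,
            "r_AB": r_ab,
            "delta": delta,
            "score": score,
            "preferential_allele": pref,
        },
        index=pd.Index(idx, name="locus_id"),
    )


def select_loci(
    records: pd.DataFrame,
    min_score: float = 75.0,
    min_het_shift_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """High-disparity locus selection.

    Returns ``(selected, strict)``: loci with score >= ``min_score`` (and at
    least one shifted sample), and the stricter subset additionally
    requiring that at least ``min_het_shift_fraction`` of the heterozygotes
    shifted.
    """
    shifted = records["n_shift_AA"] + records["n_shift_BB"]
    selected = records[(records["score"] >= min_score) & (shifted > 0)]
    frac = (selected["n_shift_AA"] + selected["n_shift_BB"]) / selected["n_het"]
    strict = selected[frac >= min_het_shift_fraction]
    return selected, strict
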