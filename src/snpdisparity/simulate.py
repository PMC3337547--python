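"""Synthetic paired blood-tumour BAF/LRR cohorts with known planted events.

The generator emulates the data model of a paired SNP-array experiment:
per-locus blood genotypes drawn under Hardy-Weinberg equilibrium at a
locus-specific minor-allele frequency, BAF clustered around the canonical
centres 0 / 0.5 / 1 with truncated Gaussian noise (clipped to [0, 1]),
missing values, tumour BAF equal to blood BAF except at planted disparity
loci (where a chosen fraction of heterozygotes moves beyond the 2-SD band
toward a biased direction), and tumour LRR built from planted constant
segments plus Gaussian noise. Every draw flows from a single seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, PairedArrayData, ValidationError

__all__ = [
    "CnaSegmentSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate",
    "truth_recovery_report",
]


@dataclass(frozen=True)
class CnaSegmentSpec:
    """A planted copy-number segment: within-chromosome locus span + LRR shift."""

    chromosome: str
    start_index: int  # inclusive, within-chromosome locus index
    end_index: int    # inclusive
    lrr_shift: float

    @property
    def state(self) -> str:
        return "amplification" if self.lrr_shift > 0 else "deletion"


def _default_cna_segments() -> list[CnaSegmentSpec]:
    return [
        CnaSegmentSpec("1", 40, 89, 0.3),
        CnaSegmentSpec("2", 100, 149, -0.3),
        CnaSegmentSpec("3", 20, 59, 0.3),
        CnaSegmentSpec("4", 60, 109, -0.3),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the paired breast-cancer array setting the package
    targets: 112 sample pairs, BAF cluster noise SD 0.03, occasional
    missing cells, 2% of loci carrying directional disparity in 80% of
    their heterozygotes, and a handful of 40-50-locus CNA segments of
    |shift| 0.3 on an LRR noise SD of 0.15.
    """

    n_loci: int = 5000
    n_samples: int = 112
    n_chromosomes: int = 22
    maf_range: tuple[float, float] = (0.05, 0.5)
    baf_noise_sd: float = 0.03
    missing_rate: float = 0.01
    disparity_fraction: float = 0.02
    shift_fraction: float = 0.8
    shift_direction_bias: float = 0.5
    cna_segments: list[CnaSegmentSpec] = field(default_factory=_default_cna_segments)
    lrr_noise_sd: float = 0.15
    clinical_odds: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "disparity_fraction", "shift_fraction", "shift_direction_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.baf_noise_sd <= 0 or self.lrr_noise_sd <= 0:
            raise ValidationError("noise SDs must be positive")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValidationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.clinical_odds <= 0:
            raise ValidationError("clinical_odds must be positive")
        # a shift has to clear the 2-SD band around 0.5 to be detectable
        if 0.5 - 2.0 * self.baf_noise_sd <= 2.0 * self.baf_noise_sd:
            warnings.warn(
                "baf_noise_sd so large that planted shifts cannot clear the "
                f"2-SD band (limit: sd < 0.125, got {self.baf_noise_sd})",
                stacklevel=2,
            )


@dataclass
class SyntheticTruth:
    """Planted events: per-locus disparity directions and CNA segments."""

    #: locus_id -> ("toward-A"|"toward-B", list of shifted sample ids)
    disparity: pd.DataFrame
    #: planted segments with resolved locus-id spans
    segments: pd.DataFrame

    def disparity_locus_ids(self) -> list[str]:
        return list(self.disparity.index)

    def cna_state_by_locus(self, locus_ids: pd.Index) -> pd.Series:
        """Truth CNA state per locus ("normal" outside planted segments)."""
        out = pd.Series("normal", index=locus_ids, dtype=object)
        for _, seg in self.segments.iterrows():
            ids = [l for l in seg["locus_ids"] if l in out.index]
            out.loc[ids] = seg["state"]
        return out


_CLUSTER_CENTRE = np.array([0.0, 0.5, 1.0])  # BAF centre per B-allele count


def simulate(config: SimulationConfig) -> tuple[PairedArrayData, ClinicalTable, SyntheticTruth]:
    """Draw one cohort; bit-identical for identical configs (same seed)."""
    rng = np.random.default_rng(config.seed)
    r, c = config.n_loci, config.n_samples

    # locus scaffold: even split over chromosomes, monotone synthetic positions
    chrom_of = np.repeat(
        np.arange(config.n_chromosomes), -(-r // config.n_chromosomes)
    )[:r]
    chroms = np.array([str(i + 1) for i in chrom_of])
    within = np.concatenate([np.arange((chrom_of == k).sum()) for k in range(config.n_chromosomes)])
    positions = (within + 1) * 10_000
    locus_ids = np.array([f"snp{i:06d}" for i in range(r)])
    sample_ids = [f"sample{j:03d}" for j in range(c)]
    genes = np.array([f"GENE{i // 5:05d}" if (i // 5) % 7 else "" for i in range(r)], dtype=object)
    bands = np.array(
        [f"{ch}p1" if w < (chrom_of == k).sum() / 2 else f"{ch}q1"
         for ch, k, w in zip(chroms, chrom_of, within)],
        dtype=object,
    )
    alleles = rng.choice(list("ACGT"), size=(r, 2))
    swap = alleles[:, 0] == alleles[:, 1]
    alleles[swap, 1] = np.where(alleles[swap, 0] == "A", "G", "A")

    loci = pd.DataFrame(
        {
            "chromosome": chroms,
            "position": positions,
            "allele_a": alleles[:, 0],
            "allele_b": alleles[:, 1],
            "gene": [g if g else None for g in genes],
            "cytoband": bands,
        },
        index=pd.Index(locus_ids, name="locus_id"),
    )

    # blood genotypes under HWE at a per-locus MAF; B allele minor half the time
    maf = rng.uniform(*config.maf_range, size=r)
    q = np.where(rng.random(r) < 0.5, maf, 1.0 - maf)  # B-allele frequency
    probs = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=1)
    u = rng.random((r, c))
    cum = probs.cumsum(axis=1)
    genotype = (u[:, :, None] > cum[:, None, :]).sum(axis=2)  # 0, 1, 2 B alleles

    blood_baf = np.clip(
        _CLUSTER_CENTRE[genotype] + rng.normal(0.0, config.baf_noise_sd, size=(r, c)),
        0.0,
        1.0,
    )
    tumour_baf = blood_baf.copy()

    # plant directional disparity on informative loci only
    het = genotype == 1
    n_het = het.sum(axis=1)
    informative = (genotype == 0).any(axis=1) & (genotype == 2).any(axis=1) & (n_het >= 2)
    n_plant = int(round(config.disparity_fraction * r))
    candidates = np.flatnonzero(informative)
    n_plant = min(n_plant, candidates.size)
    planted = rng.choice(candidates, size=n_plant, replace=False) if n_plant else np.array([], int)

    # clinical covariates, optionally coupled to shifted-sample selection
    clinical = _simulate_clinical(rng, sample_ids)
    risk = (clinical.table["tp53"] == "mutate").to_numpy(int) + (
        clinical.table["grade"].to_numpy(float) - 1
    ) / 2.0
    weights = np.power(config.clinical_odds, risk)

    band_lo = 0.5 - 2.0 * config.baf_noise_sd
    band_hi = 0.5 + 2.0 * config.baf_noise_sd
    truth_rows = []
    for i in planted:
        hets = np.flatnonzero(het[i])
        k = max(1, int(np.ceil(config.shift_fraction * hets.size)))
        w = weights[hets] / weights[hets].sum()
        chosen = rng.choice(hets, size=k, replace=False, p=w)
        toward_b = rng.random() < config.shift_direction_bias
        if toward_b:
            tumour_baf[i, chosen] = rng.uniform(band_hi, 1.0, size=k)
        else:
            tumour_baf[i, chosen] = rng.uniform(0.0, band_lo, size=k)
        truth_rows.append(
            {
                "locus_id": locus_ids[i],
                "direction": "toward-B" if toward_b else "toward-A",
                "n_het": int(hets.size),
                "shifted_samples": [sample_ids[j] for j in chosen],
            }
        )

    # LRR: blood diploid baseline, tumour with planted constant segments
    blood_lrr = rng.normal(0.0, config.lrr_noise_sd, size=(r, c))
    tumour_mean = np.zeros((r, c))
    seg_rows = []
    for seg in config.cna_segments:
        on_chrom = np.flatnonzero(chroms == str(seg.chromosome))
        span = on_chrom[(within[on_chrom] >= seg.start_index) & (within[on_chrom] <= seg.end_index)]
        if span.size == 0:
            continue
        tumour_mean[span, :] += seg.lrr_shift
        seg_rows.append(
            {
                "chromosome": str(seg.chromosome),
                "start_index": int(within[span].min()),
                "end_index": int(within[span].max()),
                "lrr_shift": seg.lrr_shift,
                "state": seg.state,
                "locus_ids": list(locus_ids[span]),
            }
        )
    tumour_lrr = tumour_mean + rng.normal(0.0, config.lrr_noise_sd, size=(r, c))

    # missingness, independent per matrix
    mats = {}
    for name, m in (
        ("blood_baf", blood_baf),
        ("tumour_baf", tumour_baf),
        ("blood_lrr", blood_lrr),
        ("tumour_lrr", tumour_lrr),
    ):
        m = m.astype(float)
        if config.missing_rate > 0:
            m[rng.random((r, c)) < config.missing_rate] = np.nan
        mats[name] = pd.DataFrame(m, index=loci.index, columns=sample_ids)

    data = PairedArrayData(loci=loci, **mats).sorted()
    data.validate()
    truth = SyntheticTruth(
        disparity=pd.DataFrame(
            truth_rows, columns=["locus_id", "direction", "n_het", "shifted_samples"]
        ).set_index("locus_id"),
        segments=pd.DataFrame(
            seg_rows,
            columns=["chromosome", "start_index", "end_index", "lrr_shift", "state", "locus_ids"],
        ),
    )
    return data, clinical, truth


def _simulate_clinical(rng: np.random.Generator, sample_ids: list[str]) -> ClinicalTable:
    n = len(sample_ids)
    table = pd.DataFrame(
        {
            "grade": rng.choice([1, 2, 3], size=n, p=[0.2, 0.45, 0.35]),
            "er": rng.choice(["neg", "pos"], size=n, p=[0.35, 0.65]),
            "pr": rng.choice(["neg", "pos"], size=n, p=[0.45, 0.55]),
            "her2": rng.choice(["neg", "pos"], size=n, p=[0.8, 0.2]),
            "tp53": rng.choice(["wildtype", "mutate"], size=n, p=[0.7, 0.3]),
            "tumour_size": rng.choice(["T1", "T2", "T3+4"], size=n, p=[0.4, 0.45, 0.15]),
            "lymph_node": rng.choice(["neg", "pos"], size=n, p=[0.55, 0.45]),
            "subtype": rng.choice(["luminalA", "basal", "other"], size=n, p=[0.45, 0.2, 0.35]),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ClinicalTable(table)


def truth_recovery_report(
    truth: SyntheticTruth,
    records: pd.DataFrame,
    strict_locus_ids,
    cna_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sensitivity/specificity of the pipeline against the planted truth.

    * ``directional_shift``: planted disparity loci recovered in the strict
      high-disparity subset, with direction accuracy among those recovered.
    * ``amplification`` / ``deletion``: per locus x sample CNA calls inside
      planted segments (sensitivity) and, for specificity, the fraction of
      cells outside any planted segment called normal.
    """
    rows = []
    planted = [l for l in truth.disparity_locus_ids() if l in records.index]
    strict = set(strict_locus_ids)
    if planted:
        recovered = [l for l in planted if l in strict]
        sens = len(recovered) / len(planted)
        correct_dir = sum(
            records.loc[l, "preferential_allele"] == truth.disparity.loc[l, "direction"]
            for l in recovered
        )
        dir_acc = correct_dir / len(recovered) if recovered else np.nan
    else:
        sens, dir_acc = np.nan, np.nan
    unplanted = records.index.difference(truth.disparity.index)
    spec = float((~unplanted.isin(strict)).mean()) if len(unplanted) else np.nan
    rows.append(
        {"event": "directional_shift", "n_true": len(planted),
         "sensitivity": sens, "specificity": spec, "direction_accuracy": dir_acc}
    )

    if cna_calls is not None:
        state_by_locus = truth.cna_state_by_locus(cna_calls.index)
        calls = cna_calls.to_numpy()
        for state, code in (("amplification", 1), ("deletion", -1)):
            in_state = (state_by_locus == state).to_numpy()
            n_cells = int(in_state.sum()) * calls.shape[1]
            sens = float((calls[in_state] == code).mean()) if n_cells else np.nan
            rows.append(
                {"event": state, "n_true": n_cells,
                 "sensitivity": sens, "specificity": np.nan, "direction_accuracy": np.nan}
            )
        normal = (state_by_locus == "normal").to_numpy()
        spec = float((calls[normal] == 0).mean()) if normal.any() else np.nan
        rows[-2]["specificity"] = spec
        rows[-1]["specificity"] = spec
    return pd.DataFrame(rows).set_index("event")
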