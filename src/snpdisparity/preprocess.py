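"""Genotype-region classification from blood BAF and non-informative filtering.

Blood BAF is divided into three genotype regions by fixed thresholds
(defaults 0.2 / 0.8): AA for BAF <= 0.2, AB for 0.2 < BAF <= 0.8, BB above.
Chromosome-Y loci are removed, then any locus whose non-missing blood calls
do not cover all three genotype groups (monomorphs included) is dropped as
non-informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PairedArrayData, ValidationError

__all__ = [
    "AA", "AB", "BB", "MISSING",
    "GENOTYPE_LABELS",
    "FilterSummary",
    "classify_genotype",
    "classify_genotype_matrix",
    "filter_informative",
]

# integer genotype codes used throughout the pipeline
AA: int = 0
AB: int = 1
BB: int = 2
MISSING: int = -1

GENOTYPE_LABELS: dict[int, str] = {AA: "AA", AB: "AB", BB: "BB", MISSING: "missing"}

DEFAULT_THRESHOLDS: tuple[float, float] = (0.2, 0.8)


@dataclass(frozen=True)
class FilterSummary:
    """Locus bookkeeping for the non-informative filter."""

    n_input_loci: int
    n_removed_chrY: int
    n_removed_noninformative: int
    n_retained: int

    def __post_init__(self) -> None:
        total = self.n_removed_chrY + self.n_removed_noninformative + self.n_retained
        if total != self.n_input_loci:
            raise ValidationError(
                f"filter counts do not partition the input: {self.n_input_loci} != "
                f"{self.n_removed_chrY} + {self.n_removed_noninformative} + {self.n_retained}"
            )


def _check_thresholds(thresholds: tuple[float, float]) -> tuple[float, float]:
    t_low, t_high = thresholds
    if not (0.0 < t_low < t_high < 1.0):
        raise ValidationError(f"need 0 < t_low < t_high < 1, got {thresholds}")
    return t_low, t_high


def classify_genotype(
    baf: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Classify one BAF value into {AA, AB, BB, missing}.

    Boundary inclusivity: AA covers [0, t_low], AB covers (t_low, t_high],
    BB covers (t_high, 1].
    """
    t_low, t_high = _check_thresholds(thresholds)
    if baf is None or (isinstance(baf, float) and np.isnan(baf)):
        return GENOTYPE_LABELS[MISSING]
    if not 0.0 <= baf <= 1.0:
        raise ValidationError(f"BAF outside [0, 1]: {baf}")
    if baf <= t_low:
        return GENOTYPE_LABELS[AA]
    if baf <= t_high:
        return GENOTYPE_LABELS[AB]
    return GENOTYPE_LABELS[BB]


def classify_genotype_matrix(
    baf: pd.DataFrame, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Vectorised genotype calls; returns an int8 DataFrame of codes."""
    t_low, t_high = _check_thresholds(thresholds)
    values = baf.to_numpy(float)
    finite = np.isfinite(values)
    if ((values[finite] < 0) | (values[finite] > 1)).any():
        i, j = np.argwhere(finite & ((values < 0) | (values > 1)))[0]
        raise ValidationError(
            f"BAF outside [0, 1] at locus {baf.index[i]}, sample {baf.columns[j]}"
        )
    calls = np.full(values.shape, MISSING, dtype=np.int8)
    calls[finite & (values <= t_low)] = AA
    calls[finite & (values > t_low) & (values <= t_high)] = AB
    calls[finite & (values > t_high)] = BB
    return pd.DataFrame(calls, index=baf.index, columns=baf.columns)


def filter_informative(
    data: PairedArrayData,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> tuple[PairedArrayData, FilterSummary, pd.DataFrame]:
    """Drop chromosome-Y loci and loci lacking all three blood genotype groups.

    Returns the filtered data, a :class:`FilterSummary`, and the cached
    blood genotype calls (int8 codes) for the retained loci. Missing calls
    are ignored when counting genotype groups, so an all-missing locus is
    removed as non-informative.
    """
    n_input = data.n_loci
    on_y = data.loci["chromosome"] == "Y"
    autox = data.subset_loci(data.loci.index[~on_y])

    calls = classify_genotype_matrix(autox.blood_baf, thresholds)
    c = calls.to_numpy()
    has_all_three = (
        (c == AA).any(axis=1) & (c == AB).any(axis=1) & (c == BB).any(axis=1)
    )
    retained_ids = autox.loci.index[has_all_three]
    retained = autox.subset_loci(retained_ids)
    summary = FilterSummary(
        n_input_loci=n_input,
        n_removed_chrY=int(on_y.sum()),
        n_removed_noninformative=int((~has_all_three).sum()),
        n_retained=len(retained_ids),
    )
    return retained, summary, calls.loc[retained_ids]
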