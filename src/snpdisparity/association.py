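"""Association of disparity status with clinical covariates.

Two test statistics are used on 2 x k contingency tables: the Pearson
chi-square (uncorrected by default; a Yates flag exists for 2 x 2) for
nominal covariates, and the Cochran-Armitage trend test for ordered ones
(grade, tumour size). The trend statistic follows the score-test form used
by R's ``prop.trend.test``:

    X^2 = [sum_i s_i x_i - pbar * sum_i s_i n_i]^2
          / [pbar (1 - pbar) (sum_i s_i^2 n_i - (sum_i s_i n_i)^2 / N)]

with x_i the event counts, n_i the column totals, s_i the column scores
and pbar the pooled event proportion; it is chi-square with 1 df under the
null and invariant to affine changes of the scores.

The global test pools all locus x sample cells into one table; because
cells within a sample are correlated this is descriptive rather than
strictly inferential (see docs). The per-locus scan treats samples as
units and applies Benjamini-Hochberg adjustment across loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ClinicalTable, ValidationError

__all__ = [
    "ContingencyResult",
    "ORDERED_COVARIATES",
    "pearson_chi2",
    "cochran_armitage",
    "global_association",
    "per_locus_scan",
    "bh_adjust",
]

#: Ordered covariates and their level order (used for trend tests).
ORDERED_COVARIATES: dict[str, tuple] = {
    "grade": (1, 2, 3),
    "tumour_size": ("T1", "T2", "T3+4"),
}


class DegenerateTableError(ValueError):
    """A margin of the contingency table is zero; the test is undefined."""


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    statistic: float
    df: int
    p_value: float
    test_name: str


def _as_2xk(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValidationError(f"expected a 2 x k table with k >= 2, got shape {t.shape}")
    if (t < 0).any():
        raise ValidationError("contingency counts must be non-negative")
    return t


def pearson_chi2(table, continuity_correction: bool = False) -> ContingencyResult:
    """Pearson chi-square on a 2 x k table (df = k - 1).

    Uncorrected by default; ``continuity_correction=True`` applies the
    Yates correction (2 x 2 only).
    """
    t = _as_2xk(table)
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=continuity_correction)
    return ContingencyResult(
        table=t, statistic=float(chi2), df=int(dof), p_value=float(p), test_name="pearson"
    )


def cochran_armitage(table, scores=None) -> ContingencyResult:
    """Cochran-Armitage trend test on a 2 x k table of ordered columns (df = 1).

    Row 0 holds the event counts. ``scores`` default to 0, 1, ..., k-1 and
    must be strictly increasing.
    """
    t = _as_2xk(table)
    k = t.shape[1]
    s = np.arange(k, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    if s.shape != (k,) or (np.diff(s) <= 0).any():
        raise ValidationError("scores must be strictly increasing, one per column")
    x = t[0]
    n = t.sum(axis=0)
    N = n.sum()
    if (n == 0).any() or t[0].sum() == 0 or t[1].sum() == 0:
        raise DegenerateTableError("zero margin in trend-test table")
    pbar = x.sum() / N
    num = (s * x).sum() - pbar * (s * n).sum()
    den = pbar * (1 - pbar) * ((s * s * n).sum() - (s * n).sum() ** 2 / N)
    if den <= 0:
        raise DegenerateTableError("zero variance in trend-test table")
    chi2 = num * num / den
    return ContingencyResult(
        table=t,
        statistic=float(chi2),
        df=1,
        p_value=float(stats.chi2.sf(chi2, 1)),
        test_name="cochran_armitage",
    )


def _covariate_levels(clinical: ClinicalTable, covariate: str):
    values = clinical.covariate(covariate)
    if covariate in ORDERED_COVARIATES:
        levels = [l for l in ORDERED_COVARIATES[covariate] if (values == l).any()]
    else:
        declared = clinical.LEVELS.get(covariate)
        observed = values.dropna().unique()
        if declared is not None:
            levels = [l for l in declared if l in set(observed)]
        else:
            levels = sorted(observed)
    if len(levels) < 2:
        raise ValidationError(
            f"covariate {covariate!r} has fewer than 2 observed levels"
        )
    return values, levels


def global_association(
    disparity_indicator: pd.DataFrame,
    clinical: ClinicalTable,
    covariate: str,
    test: str = "auto",
) -> ContingencyResult:
    """Pool all locus x sample cells into a 2 x k table and test it.

    Row 1 counts disparity cells, row 2 the remaining cells, columns the
    covariate levels; samples with a missing covariate are excluded. With
    ``test="auto"`` ordered covariates get the trend test, others Pearson.
    """
    values, levels = _covariate_levels(clinical, covariate)
    ind = disparity_indicator
    cols = [s for s in ind.columns if s in values.index]
    table = np.zeros((2, len(levels)))
    n_loci = len(ind.index)
    for j, level in enumerate(levels):
        samples = [s for s in cols if pd.notna(values.get(s)) and values.get(s) == level]
        if samples:
            disp = int(ind[samples].to_numpy().sum())
            table[0, j] = disp
            table[1, j] = n_loci * len(samples) - disp
    if test == "auto":
        test = "cochran_armitage" if covariate in ORDERED_COVARIATES else "pearson"
    if test == "cochran_armitage":
        return cochran_armitage(table)
    if test == "pearson":
        return pearson_chi2(table)
    raise ValidationError(f"unknown test {test!r}")


def per_locus_scan(
    disparity_indicator: pd.DataFrame,
    clinical: ClinicalTable,
    covariate: str,
    test: str = "auto",
) -> pd.DataFrame:
    """Per-locus association with BH adjustment across the scanned loci.

    ``disparity_indicator`` should be restricted to the selected loci
    (e.g. the strict high-disparity subset); each locus contributes a
    2 x k table with samples as units. Degenerate tables are reported with
    ``testable=False`` and NaN statistics rather than dropped.
    """
    if disparity_indicator.shape[0] == 0:
        raise ValidationError("per-locus scan needs at least one locus")
    values, levels = _covariate_levels(clinical, covariate)
    cols = [s for s in disparity_indicator.columns if s in values.index]
    level_of = values.loc[cols]
    if test == "auto":
        test = "cochran_armitage" if covariate in ORDERED_COVARIATES else "pearson"

    rows = []
    for locus, row in disparity_indicator[cols].iterrows():
        table = np.zeros((2, len(levels)))
        for j, level in enumerate(levels):
            in_level = (level_of == level).fillna(False).to_numpy(bool)
            table[0, j] = int(row.to_numpy()[in_level].sum())
            table[1, j] = int(in_level.sum()) - table[0, j]
        try:
            res = (
                cochran_armitage(table) if test == "cochran_armitage" else pearson_chi2(table)
            )
            rows.append(
                dict(locus_id=locus, statistic=res.statistic, df=res.df,
                     p_value=res.p_value, testable=True,
                     **{f"n_level{j}": int(table[:, j].sum()) for j in range(len(levels))})
            )
        except DegenerateTableError:
            rows.append(
                dict(locus_id=locus, statistic=np.nan, df=np.nan, p_value=np.nan,
                     testable=False,
                     **{f"n_level{j}": int(table[:, j].sum()) for j in range(len(levels))})
            )
    out = pd.DataFrame(rows).set_index("locus_id")
    out["p_adjusted"] = np.nan
    testable = out["testable"].to_numpy()
    if testable.any():
        out.loc[testable, "p_adjusted"] = bh_adjust(out.loc[testable, "p_value"].to_numpy())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
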