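"""Normalization and seasonal differential-abundance calling.

The statistical path mirrors standard TMT workflows: "total peptide amount"
normalization, log2 transform, a per-protein one-way ANOVA on season with a
Tukey HSD season contrast (exact for the two-season design via the
studentized-range distribution), optional additive adjustment for batch and
year, Benjamini-Hochberg FDR over the tested proteins of each species, and
the differential-abundance call |log2FC| >= 1 with adjusted p < 0.05.

Fold changes are winter minus summer on the log2 scale (log2 Winter/Summer).
Zero intensities denote non-detection and are treated as missing; missing
values are dropped per protein (pairwise deletion), never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AbundanceMatrix, ValidationError

__all__ = [
    "normalize_total",
    "filter_both_seasons",
    "seasonal_test",
    "call_daps",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = ["protein_id", "log2fc", "p_value", "p_adj", "call",
                  "n_winter", "n_summer"]


def normalize_total(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample column by one factor so all column sums (over
    non-missing entries) equal the mean of the input column sums."""
    sums = matrix.data.sum(axis=0, skipna=True)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero total intensity")
    target = sums.mean()
    scaled = matrix.data * (target / sums)
    return AbundanceMatrix(data=scaled, species=matrix.species)


def filter_both_seasons(matrix: AbundanceMatrix, meta: pd.DataFrame,
                        min_per_season: int = 2) -> AbundanceMatrix:
    """Keep proteins quantified in both seasons: at least ``min_per_season``
    non-missing values in winter and in summer."""
    meta = meta.set_index("sample_id")
    season = meta.loc[matrix.sample_ids, "season"]
    keep = np.ones(matrix.shape[0], dtype=bool)
    for s in ("winter", "summer"):
        cols = season.index[season == s]
        keep &= matrix.data[cols].notna().sum(axis=1).to_numpy() >= min_per_season
    return AbundanceMatrix(data=matrix.data.loc[keep], species=matrix.species)


def _two_group_stats(w: np.ndarray, s: np.ndarray, k_groups: int = 2,
                     p_source: str = "contrast") -> tuple[float, float]:
    """log2fc and p-value for one protein from winter/summer log2 values.

    The season contrast is the Tukey HSD comparison; with k = 2 groups the
    studentized-range tail probability at q = sqrt(2)|t| equals the
    two-sided pooled t-test p-value, which is used directly.  For k > 2 the
    studentized-range distribution is evaluated explicitly.
    ``p_source='omnibus'`` returns the one-way ANOVA F-test p instead.
    """
    nw, ns = len(w), len(s)
    diff = w.mean() - s.mean()
    df = nw + ns - 2
    ssw = ((w - w.mean()) ** 2).sum() + ((s - s.mean()) ** 2).sum()
    if ssw == 0.0:
        return diff, (1.0 if diff == 0.0 else 0.0)
    mse = ssw / df
    t = diff / np.sqrt(mse * (1.0 / nw + 1.0 / ns))
    if p_source == "omnibus":
        p = float(stats.f.sf(t * t, 1, df))
    elif k_groups == 2:
        p = float(2.0 * stats.t.sf(abs(t), df))
    else:
        q = np.sqrt(2.0) * abs(t)
        p = float(stats.studentized_range.sf(q, k_groups, df))
    return float(diff), p


def _adjusted_stats(x: np.ndarray, winter: np.ndarray,
                    factors: list[np.ndarray]) -> tuple[float, float]:
    """Season effect and p from an additive fixed-effects linear model
    (season + factors, no interactions), tested on residual df."""
    n = len(x)
    cols = [np.ones(n), winter.astype(float)]
    for f in factors:
        levels = pd.unique(f)
        for lev in levels[1:]:  # first level is the reference
            cols.append((f == lev).astype(float))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    beta, _, _, _ = np.linalg.lstsq(X, x, rcond=None)
    resid = x - X @ beta
    dof = n - rank
    if dof <= 0:
        return float("nan"), float("nan")
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    est = float(beta[1])
    if se == 0.0:
        return est, (1.0 if est == 0.0 else 0.0)
    t = est / se
    return est, float(2.0 * stats.t.sf(abs(t), dof))


def _check_confounding(winter: np.ndarray, factors: dict[str, np.ndarray]) -> None:
    """Raise if the season indicator lies in the span of intercept + one
    factor's dummies (season effect then unidentifiable)."""
    y = winter.astype(float)
    for name, f in factors.items():
        levels = pd.unique(f)
        D = np.column_stack([np.ones(len(f))] + [(f == lev).astype(float) for lev in levels[1:]])
        proj, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
        if np.allclose(D @ proj, y, atol=1e-10):
            raise ValidationError(
                f"season is confounded with factor {name!r}: the seasonal "
                "contrast cannot be estimated"
            )


def seasonal_test(matrix: AbundanceMatrix, meta: pd.DataFrame,
                  adjust_for: tuple[str, ...] = (),
                  p_source: str = "contrast") -> pd.DataFrame:
    """Per-protein seasonal test on log2 intensities.

    Returns a DataFrame with columns ``protein_id, log2fc, p_value, p_adj,
    call, n_winter, n_summer``; ``call`` is ``untested`` for proteins with
    fewer than 2 usable values in either season (their p-values are NaN and
    they do not enter the BH correction).  ``call`` is otherwise
    ``not_significant`` until :func:`call_daps` applies thresholds.

    ``adjust_for`` may list ``batch`` and/or ``year``; the model is then an
    additive fixed-effects fit (season + factors) and ``log2fc`` is the
    factor-adjusted season coefficient.
    """
    bad = set(adjust_for) - {"batch", "year"}
    if bad:
        raise ValueError(f"adjust_for accepts 'batch' and 'year'; got {sorted(bad)}")
    meta_idx = meta.set_index("sample_id").loc[matrix.sample_ids]
    winter_all = (meta_idx["season"] == "winter").to_numpy()
    factor_all = {f: meta_idx[f].astype(str).to_numpy() for f in adjust_for}

    values = matrix.data.to_numpy(dtype=float)
    values = np.where(values > 0, values, np.nan)  # zeros are non-detections
    logv = np.log2(values)

    if adjust_for:
        _check_confounding(winter_all, factor_all)

    rows = []
    for i, pid in enumerate(matrix.protein_ids):
        x = logv[i]
        ok = ~np.isnan(x)
        w_mask = ok & winter_all
        s_mask = ok & ~winter_all
        nw, ns = int(w_mask.sum()), int(s_mask.sum())
        if nw < 2 or ns < 2:
            rows.append((pid, np.nan, np.nan, np.nan, "untested", nw, ns))
            continue
        if adjust_for:
            useful = [f[ok] for f in factor_all.values() if len(pd.unique(f[ok])) > 1]
            lfc, p = _adjusted_stats(x[ok], winter_all[ok], useful)
        else:
            lfc, p = _two_group_stats(x[w_mask], x[s_mask], p_source=p_source)
        rows.append((pid, lfc, p, np.nan, "not_significant", nw, ns))

    res = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    tested = res["p_value"].notna()
    if tested.any():
        res.loc[tested, "p_adj"] = multipletests(
            res.loc[tested, "p_value"].to_numpy(), method="fdr_bh")[1]
    return res


def call_daps(results: pd.DataFrame, lfc_min: float = 1.0,
              alpha: float = 0.05) -> pd.DataFrame:
    """Populate ``call``: up if log2fc >= lfc_min and p_adj < alpha, down if
    log2fc <= -lfc_min and p_adj < alpha, untested rows untouched."""
    out = results.copy()
    tested = out["p_adj"].notna()
    sig = tested & (out["p_adj"] < alpha)
    out.loc[tested, "call"] = "not_significant"
    out.loc[sig & (out["log2fc"] >= lfc_min), "call"] = "up"
    out.loc[sig & (out["log2fc"] <= -lfc_min), "call"] = "down"
    return out
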