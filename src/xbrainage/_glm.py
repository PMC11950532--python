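"""General-linear-model ANCOVA core shared by the BrainAGE and ROI stages.

One between-subject factor (clinical condition) plus continuous and/or
two-level covariates, no interactions.  Sums of squares are Type II,
computed by the drop-one (extra-sum-of-squares) construction: for each
term, SS = RSS(model without the term) - RSS(full model).  With no
interactions in the model this coincides with Type III.

The dependent variable may be a matrix (observations x regions); every
region is then tested against the same design in one vectorized pass,
which is what makes per-ROI testing and calibration simulations cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _dummy(col: np.ndarray, name: str) -> tuple[np.ndarray, list]:
    """Treatment-code a categorical column (first level = reference)."""
    levels = sorted(pd.unique(col).tolist())
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} needs >= 2 levels, got {levels}")
    mat = np.column_stack([(col == lv).astype(float) for lv in levels[1:]])
    return mat, levels


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.einsum("ij,ij->j", resid, resid)


def ancova(Y: np.ndarray, group: np.ndarray,
           covariates: dict[str, np.ndarray]) -> pd.DataFrame:
    """ANCOVA of each column of ``Y`` on a group factor plus covariates.

    ``covariates`` maps name -> column; numeric dtype columns enter as
    continuous covariates, object/str columns as two-level factors.

    Returns a tidy frame with one row per (column, factor):
    ``column, factor, SS, df, F, p, np2``.  Partial eta squared is
    SS_effect / (SS_effect + SS_residual).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    group = np.asarray(group)
    if len(group) != n:
        raise ValueError("group length must match observations")
    counts = pd.Series(group).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 subjects each, got "
                         f"{counts.to_dict()}")

    blocks: list[tuple[str, np.ndarray]] = []
    gmat, _ = _dummy(group, "condition")
    blocks.append(("condition", gmat))
    for name, col in covariates.items():
        col = np.asarray(col)
        if col.dtype.kind in "ifu":
            blocks.append((name, col.astype(float)[:, None]))
        else:
            cmat, _ = _dummy(col, name)
            blocks.append((name, cmat))

    X_full = np.column_stack([np.ones(n)] + [b for _, b in blocks])
    df_resid = n - X_full.shape[1]
    if df_resid < 1:
        raise ValueError("not enough observations for the design")
    rss_full = _rss(X_full, Y)

    rows = []
    for name, block in blocks:
        X_red = np.column_stack(
            [np.ones(n)] + [b for nm, b in blocks if nm != name])
        ss = np.maximum(_rss(X_red, Y) - rss_full, 0.0)
        df_t = block.shape[1]
        ms_resid = rss_full / df_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(ms_resid > 0, (ss / df_t) / ms_resid, np.inf)
        p = stats.f.sf(F, df_t, df_resid)
        np2 = np.where(ss + rss_full > 0, ss / (ss + rss_full), 0.0)
        for j in range(Y.shape[1]):
            rows.append({"column": j, "factor": name, "SS": ss[j],
                         "df": df_t, "F": float(F[j]), "p": float(p[j]),
                         "np2": float(np2[j])})
    out = pd.DataFrame(rows)
    out.attrs["df_resid"] = df_resid
    return out
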