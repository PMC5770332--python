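"""Group-level factorial mixed-effects tests and post-hoc statistics.

Balanced 2^k within-subject designs with a random subject intercept are
fitted in closed form: effect-coded factorial fixed effects plus subject
means, with F tests using containment denominator degrees of freedom
``df_den = N - n_subjects - p_within`` where ``p_within`` is the number of
non-intercept fixed-effect parameters (2^k - 1 for a full two-level
factorial).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["mixed_anova", "wilcoxon_posthoc", "volume_learning_correlation"]


def _effect_columns(df: pd.DataFrame, factors: list[str]) -> dict[str, np.ndarray]:
    """Effect-coded (+1/-1) columns for all main effects and interactions."""
    coded = {}
    for f in factors:
        levels = sorted(df[f].astype(str).unique())
        if len(levels) != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels, "
                             f"got {levels}")
        coded[f] = np.where(df[f].astype(str) == levels[0], 1.0, -1.0)
    cols = {}
    for order in range(1, len(factors) + 1):
        for combo in combinations(factors, order):
            col = np.ones(len(df))
            for f in combo:
                col = col * coded[f]
            cols[" x ".join(combo)] = col
    return cols


def mixed_anova(tbl: pd.DataFrame, factors: list[str],
                subject: str = "subject",
                response: str = "value") -> pd.DataFrame:
    """F table for a balanced full-factorial within-subject design.

    Returns one row per effect with columns ``effect, F, df_num, df_den, p``.
    Unbalanced tables are rejected with a per-cell count report.
    """
    df = tbl.reset_index(drop=True)
    for col in factors + [subject, response]:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    y = df[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")

    counts = df.groupby([subject] + factors, sort=True).size()
    n_expected_cells = df[subject].nunique() * 2 ** len(factors)
    if counts.nunique() > 1 or len(counts) != n_expected_cells:
        raise ValueError("unbalanced design; cell counts:\n"
                         + counts.to_string())

    n_obs = len(df)
    subjects = df[subject].unique()
    n_subj = len(subjects)
    cols = _effect_columns(df, factors)
    p_within = len(cols)
    df_den = n_obs - n_subj - p_within
    if df_den < 1:
        raise ValueError("no residual degrees of freedom")

    # subject fixed-block dummies plus effect columns; balanced design makes
    # effect columns orthogonal to each other and to the subject space
    subj_dummies = pd.get_dummies(df[subject]).to_numpy(dtype=float)
    X = np.column_stack([subj_dummies] + list(cols.values()))
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_resid = float(resid @ resid)
    ms_resid = ss_resid / df_den

    rows = []
    for name, col in cols.items():
        ss_effect = float((col @ y) ** 2 / (col @ col))
        F = ss_effect / ms_resid if ms_resid > 0 else np.inf
        p = float(stats.f.sf(F, 1, df_den))
        rows.append({"effect": name, "F": F, "df_num": 1, "df_den": df_den,
                     "p": p})
    return pd.DataFrame(rows)


def wilcoxon_posthoc(paired_a: np.ndarray, paired_b: np.ndarray,
                     alternative: str = "two-sided") -> float:
    """Wilcoxon signed-rank p for paired samples.

    Exact distribution for n <= 25 without ties; normal approximation with
    tie correction otherwise.  All-zero differences are an error.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if np.all(d == 0):
        raise ValueError("all paired differences are zero; statistic undefined")
    nonzero = d[d != 0]
    ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


def volume_learning_correlation(records: pd.DataFrame,
                                learning_columns: list[str] | None = None
                                ) -> dict[str, tuple[float, float]]:
    """Volume-corrected correlation of region size with learning strength.

    Region voxel counts are residualized on total gray-matter voxel counts
    (least squares with intercept); the residuals are then Pearson-correlated
    with each learning-index column.  Returns ``{column: (r, p)}`` with
    two-sided p values.
    """
    required = {"hg_voxels", "total_gm_voxels"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if learning_columns is None:
        learning_columns = [c for c in records.columns
                            if c.startswith("learning_")]
    if len(records) < 4:
        raise ValueError("need at least 4 subjects")
    hg = records["hg_voxels"].to_numpy(dtype=float)
    gm = records["total_gm_voxels"].to_numpy(dtype=float)
    if np.ptp(gm) == 0:
        raise ValueError("total gray-matter volume is constant")
    X = np.column_stack([np.ones_like(gm), gm])
    beta, *_ = np.linalg.lstsq(X, hg, rcond=None)
    resid = hg - X @ beta
    if resid.std() < 1e-12 * max(1.0, hg.std()):
        raise ValueError("region volume is collinear with total volume; "
                         "residual variance is zero")
    out = {}
    for col in learning_columns:
        r, p = stats.pearsonr(resid, records[col].to_numpy(dtype=float))
        out[col] = (float(r), float(p))
    return out
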