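"""Stepwise regression of an external phenotype on module eigenvalues.

Mixed forward/backward selection on partial-F p-values (default entry p 0.05,
stay p 0.10), followed by a partial (Type-III) sum-of-squares ANOVA table with
signed t-ratios, adjusted R-squared and the overall model F against the
corrected total.  Every candidate is a single-degree-of-freedom term, so for
each term t^2 = F and partial SS = t^2 * MSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StepwiseModel",
    "AnovaTable",
    "stepwise_select",
    "partial_anova",
    "adjusted_r2",
    "model_f",
]


@dataclass
class StepwiseModel:
    """Outcome of mixed stepwise selection over candidate eigentraits."""

    selected: list[str]
    coefficients: pd.Series
    p_enter: float
    p_leave: float
    history: pd.DataFrame  # step, term, action, p


@dataclass
class AnovaTable:
    """Partial-SS ANOVA of the selected model, mirroring a fit report table."""

    terms: pd.DataFrame  # source, df, ss, f_ratio, p_value, t_ratio
    ss_err: float
    df_err: int
    ss_tot: float
    df_tot: int
    adj_r2: float = field(init=False)
    model_f: float = field(init=False)
    model_p: float = field(init=False)

    def __post_init__(self) -> None:
        self.adj_r2 = adjusted_r2(self.ss_err, self.df_err, self.ss_tot, self.df_tot)
        self.model_f = model_f(self.ss_err, self.df_err, self.ss_tot, self.df_tot)
        df_model = self.df_tot - self.df_err
        self.model_p = float(stats.f.sf(self.model_f, df_model, self.df_err)) \
            if np.isfinite(self.model_f) and df_model > 0 else np.nan

    def to_frame(self) -> pd.DataFrame:
        """Full table with Error and Model(corrected-total) rows appended."""
        rows = self.terms.copy()
        extra = pd.DataFrame([
            {"source": "Error", "df": self.df_err, "ss": self.ss_err,
             "f_ratio": np.nan, "p_value": np.nan, "t_ratio": np.nan},
            {"source": "Model", "df": self.df_tot, "ss": self.ss_tot,
             "f_ratio": self.model_f, "p_value": self.model_p, "t_ratio": np.nan},
        ])
        return pd.concat([rows, extra], ignore_index=True)


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with (beta, rss, XtX_inv)."""
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    return beta, float(resid @ resid), XtX_inv


def _partial_p(y, Xbase, x_new) -> float:
    """Partial-F p-value for adding one column to the current design."""
    n = y.size
    _, rss0, _ = _ols(y, Xbase)
    X = np.column_stack([Xbase, x_new])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return 1.0
    _, rss1, _ = _ols(y, X)
    df2 = n - X.shape[1]
    if df2 <= 0:
        return 1.0
    if rss1 <= 0:
        return 0.0
    f = (rss0 - rss1) / (rss1 / df2)
    return float(stats.f.sf(f, 1, df2))


def stepwise_select(y, me: pd.DataFrame, p_enter: float = 0.05,
                    p_leave: float = 0.10) -> StepwiseModel:
    """Mixed forward/backward stepwise selection on partial-F p-values.

    Rows with missing phenotype are dropped.  At each forward step the
    candidate with the smallest partial p enters if p <= p_enter (ties break
    on lexicographic term id); backward steps then remove the worst retained
    term while its partial p exceeds p_leave.  An empty selection
    (intercept-only model) is a valid result.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=me.index)
    keep = y.notna()
    y = y[keep]
    me = me.loc[keep]
    n = len(y)
    yv = y.to_numpy()
    cols = {c: me[c].to_numpy(dtype=float) for c in me.columns}
    selected: list[str] = []
    hist = []
    step = 0
    while True:
        step += 1
        Xbase = np.column_stack([np.ones(n)] + [cols[c] for c in selected])
        if n <= Xbase.shape[1] + 1:
            break
        candidates = sorted(c for c in me.columns if c not in selected)
        entry = [(_partial_p(yv, Xbase, cols[c]), c) for c in candidates]
        entry.sort(key=lambda t: (t[0], t[1]))
        moved = False
        if entry and entry[0][0] <= p_enter:
            p_in, term = entry[0]
            selected.append(term)
            hist.append({"step": step, "term": term, "action": "enter", "p": p_in})
            moved = True
        # backward passes on the current model
        while len(selected) > 0:
            worst = _worst_term(yv, cols, selected, n)
            if worst is None or worst[0] <= p_leave:
                break
            p_out, term = worst
            selected.remove(term)
            hist.append({"step": step, "term": term, "action": "drop", "p": p_out})
            moved = True
        if not moved:
            break
    X = np.column_stack([np.ones(n)] + [cols[c] for c in selected])
    beta, _, _ = _ols(yv, X)
    coef = pd.Series(beta, index=["intercept"] + selected)
    history = pd.DataFrame(hist, columns=["step", "term", "action", "p"])
    return StepwiseModel(selected, coef, p_enter, p_leave, history)


def _worst_term(yv, cols, selected, n):
    """(p, term) for the retained term with the largest partial p."""
    worst = None
    for term in sorted(selected):
        others = [c for c in selected if c != term]
        Xbase = np.column_stack([np.ones(n)] + [cols[c] for c in others])
        p = _partial_p(yv, Xbase, cols[term])
        if worst is None or (p, term) > worst:
            worst = (p, term)
    return worst


def partial_anova(model: StepwiseModel, y, me: pd.DataFrame) -> AnovaTable:
    """Type-III (partial) SS ANOVA of the selected model.

    Per 1-DF term: t is the coefficient over its standard error, F = t^2, and
    partial SS = F * MSE.  Error and corrected-total rows carry the residual
    and total sums of squares; adjusted R-squared and the model F derive from
    them.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=me.index)
    keep = y.notna()
    y = y[keep]
    me = me.loc[keep]
    n = len(y)
    yv = y.to_numpy()
    X = np.column_stack([np.ones(n)] + [me[c].to_numpy(dtype=float)
                                        for c in model.selected])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    beta, rss, XtX_inv = _ols(yv, X)
    df_err = n - X.shape[1]
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = rss / df_err
    rows = []
    for j, term in enumerate(model.selected, start=1):
        se = np.sqrt(mse * XtX_inv[j, j])
        t = beta[j] / se
        f = t * t
        rows.append({"source": term, "df": 1, "ss": f * mse, "f_ratio": f,
                     "p_value": float(2.0 * stats.t.sf(abs(t), df_err)),
                     "t_ratio": float(t)})
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    terms = pd.DataFrame(rows, columns=["source", "df", "ss", "f_ratio",
                                        "p_value", "t_ratio"])
    return AnovaTable(terms, rss, df_err, ss_tot, n - 1)


def adjusted_r2(ss_err: float, df_err: int, ss_tot: float, df_tot: int) -> float:
    """Adjusted R-squared: 1 - (SS_err/DF_err) / (SS_tot/DF_tot)."""
    if df_err <= 0 or df_tot <= 0:
        raise ValueError("degrees of freedom must be positive")
    if ss_err < 0 or ss_tot < 0:
        raise ValueError("sums of squares must be non-negative")
    return 1.0 - (ss_err / df_err) / (ss_tot / df_tot)


def model_f(ss_err: float, df_err: int, ss_tot: float, df_tot: int) -> float:
    """Overall model F: ((SS_tot-SS_err)/(DF_tot-DF_err)) / (SS_err/DF_err).

    ``SS_err = 0`` returns +inf (a perfectly fitting model).
    """
    if df_tot <= df_err:
        raise ValueError("total DF must exceed error DF")
    if ss_err == 0:
        return float("inf")
    return ((ss_tot - ss_err) / (df_tot - df_err)) / (ss_err / df_err)
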