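"""Group-comparison and correlation layer.

Factorial (2- or 3-way) ANOVA with Type-III sums of squares under
sum-to-zero effects coding — the appropriate choice for the unbalanced cell
counts typical of animal cohorts — via statsmodels OLS.  Post-hoc pairwise
comparisons use the two-tailed pooled-variance Student's t-test.  Sleep and
cognitive measures are related by Pearson correlation with Bonferroni
correction over the family of pairs tested.
"""
from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats as scs

from .errors import ConfigurationError


def factorial_anova(data: pd.DataFrame, response: str,
                    factors: list[str]) -> pd.DataFrame:
    """Full-factorial Type-III ANOVA (sum-to-zero coding).

    Returns a tidy table: term, sum_sq, df, F, p (Residual row has NaN F/p).
    Every cell of the full factorial must be occupied; an empty cell is an
    error naming the cell.  A zero residual mean square yields infinite F,
    flagged with a warning.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if not 1 <= len(factors) <= 3:
        raise ConfigurationError("supported designs have 1-3 factors")
    for f in factors + [response]:
        if f not in data.columns:
            raise ConfigurationError(f"column {f!r} not in data")
    levels = [sorted(data[f].astype(str).unique()) for f in factors]
    for f, lv in zip(factors, levels):
        if len(lv) < 2:
            raise ConfigurationError(f"factor {f!r} has < 2 levels")
    counts = data.groupby([data[f].astype(str) for f in factors]).size()
    for cell in itertools.product(*levels):
        key = cell if len(cell) > 1 else cell[0]
        if key not in counts.index:
            raise ConfigurationError(
                f"empty cell {dict(zip(factors, cell))} in full-factorial design")
    n_params = int(np.prod([len(lv) for lv in levels]))
    if len(data) - n_params < 1:
        raise ConfigurationError(
            f"residual degrees of freedom {len(data) - n_params} < 1 "
            f"({len(data)} observations, {n_params} cells)")

    clean = data[[response] + factors].rename(columns={response: "_y"})
    formula = "_y ~ " + " * ".join(f"C({f}, Sum)" for f in factors)
    fit = ols(formula, data=clean).fit()
    table = sm.stats.anova_lm(fit, typ=3)

    def tidy_term(term: str) -> str:
        return ":".join(
            part.split("C(")[1].split(",")[0] for part in term.split(":")
        ) if "C(" in term else term

    table = table.rename(index=tidy_term).drop(index="Intercept")
    resid_ss = float(table.loc["Residual", "sum_sq"])
    total_ss = float(table["sum_sq"].sum())
    tol = 1e-12 * max(total_ss, 1.0)
    if resid_ss <= tol:
        warnings.warn("zero residual mean square: F ratios are infinite "
                      "where the effect SS is nonzero")
        table["F"] = np.where(table["sum_sq"] > tol, np.inf, 0.0)
        table.loc["Residual", "F"] = np.nan
        table["PR(>F)"] = np.where(table["F"] == np.inf, 0.0, 1.0)
        table.loc["Residual", "PR(>F)"] = np.nan
    out = table.reset_index().rename(columns={"index": "term",
                                              "PR(>F)": "p"})
    return out[["term", "sum_sq", "df", "F", "p"]]


def pairwise_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed two-sample Student's t (pooled variance).

    Degenerate zero-variance input: equal means give (0, 1) by convention,
    unequal means an infinite t with p = 0; both are flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("each group needs n >= 2")
    sp2 = (((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
           / (len(a) + len(b) - 2))
    if sp2 == 0.0:
        if np.mean(a) == np.mean(b):
            warnings.warn("zero pooled variance with equal means: p = 1")
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means: infinite t")
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), 0.0
    t, p = scs.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def pairwise_t_table(data: pd.DataFrame, response: str, group: str,
                     pairs: list[tuple[str, str]] | None = None
                     ) -> pd.DataFrame:
    """Pairwise pooled t-tests between group levels (all pairs by default)."""
    levels = sorted(data[group].astype(str).unique())
    pairs = pairs or list(itertools.combinations(levels, 2))
    rows = []
    for ga, gb in pairs:
        a = data.loc[data[group].astype(str) == ga, response].to_numpy()
        b = data.loc[data[group].astype(str) == gb, response].to_numpy()
        t, p = pairwise_t(a, b)
        rows.append({"contrast": f"{ga} vs {gb}", "t": t, "p": p,
                     "n_a": len(a), "n_b": len(b)})
    return pd.DataFrame(rows)


def correlation_matrix(sleep: pd.DataFrame,
                       cognitive: pd.DataFrame) -> pd.DataFrame:
    """Pearson r for every (sleep, cognitive) column pair, Bonferroni-adjusted.

    The two frames are aligned on their index (animal).  m = number of pairs
    actually tested; adjusted p = min(1, m * p).  Zero-variance columns are
    skipped with a warning, and pairs with fewer than 3 complete
    observations are skipped.
    """
    sleep, cognitive = sleep.align(cognitive, join="inner", axis=0)
    rows = []
    for sc in sleep.columns:
        for cc in cognitive.columns:
            x = sleep[sc].to_numpy(dtype=float)
            y = cognitive[cc].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                warnings.warn(f"pair ({sc}, {cc}): < 3 paired observations; skipped")
                continue
            if np.var(x[ok]) == 0 or np.var(y[ok]) == 0:
                warnings.warn(f"pair ({sc}, {cc}): zero variance; skipped")
                continue
            r, p = scs.pearsonr(x[ok], y[ok])
            rows.append({"pair": f"{sc} ~ {cc}", "sleep_metric": sc,
                         "cognitive_metric": cc, "n": int(ok.sum()),
                         "r": float(r), "p_raw": float(p)})
    out = pd.DataFrame(rows, columns=["pair", "sleep_metric",
                                      "cognitive_metric", "n", "r", "p_raw"])
    m = len(out)
    out["p_adj"] = np.minimum(1.0, out["p_raw"] * m) if m else []
    return out
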