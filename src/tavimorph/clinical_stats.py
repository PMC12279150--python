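"""Cohort-level tabular statistics.

Pairwise association screening across mixed-type clinical variables,
multiplicity thresholds, paravalvular-leakage (PVL) grade encodings and
summaries, and the device-choice logistic model.  Complete cases only:
each pairwise cell drops subjects with a missing value in either
variable; nothing is imputed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pairwise_associations", "bonferroni_threshold", "encode_pvl",
    "grade_summary", "device_choice_model", "device_type_share",
    "PVL_GRADES", "PVL_CONTINUOUS",
]

PVL_GRADES = ("none", "trivial", "mild", "moderate", "severe")
PVL_CONTINUOUS = {"none": 0.0, "trivial": 0.5, "mild": 1.0,
                  "moderate": 2.0, "severe": 3.0}


def _is_binary(series: pd.Series) -> bool:
    vals = series.dropna().unique()
    return len(vals) == 2


def pairwise_associations(table: pd.DataFrame,
                          yates: bool = True) -> pd.DataFrame:
    """All-pairs association screen over a covariate table.

    binary x binary -> chi-squared (Yates continuity correction by
    default); binary x continuous -> Welch two-sample t-test;
    continuous x continuous -> Pearson correlation test.  Returns a long
    DataFrame with one row per unordered pair (test, statistic, p, n).
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two variables")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sub = table[[a, b]].dropna()
            n = len(sub)
            if n == 0:
                rows.append({"var_a": a, "var_b": b, "test": "absent",
                             "statistic": np.nan, "p": np.nan, "n": 0})
                continue
            bin_a, bin_b = _is_binary(sub[a]), _is_binary(sub[b])
            try:
                if bin_a and bin_b:
                    ct = pd.crosstab(sub[a], sub[b]).to_numpy()
                    res = stats.chi2_contingency(ct, correction=yates)
                    rows.append({"var_a": a, "var_b": b, "test": "chi2",
                                 "statistic": res.statistic,
                                 "p": res.pvalue, "n": n})
                elif bin_a or bin_b:
                    g, x = (a, b) if bin_a else (b, a)
                    levels = sub[g].unique()
                    x0 = sub.loc[sub[g] == levels[0], x].astype(float)
                    x1 = sub.loc[sub[g] == levels[1], x].astype(float)
                    t, p = stats.ttest_ind(x0, x1, equal_var=False)
                    rows.append({"var_a": a, "var_b": b, "test": "welch_t",
                                 "statistic": t, "p": p, "n": n})
                else:
                    r, p = stats.pearsonr(sub[a].astype(float),
                                          sub[b].astype(float))
                    rows.append({"var_a": a, "var_b": b, "test": "pearson",
                                 "statistic": r, "p": p, "n": n})
            except Exception:
                rows.append({"var_a": a, "var_b": b, "test": "failed",
                             "statistic": np.nan, "p": np.nan, "n": n})
    return pd.DataFrame(rows)


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-pair significance threshold ``alpha / (m (m-1) / 2)``."""
    if m < 2:
        raise ValueError("need at least two variables")
    return alpha / (m * (m - 1) / 2)


def encode_pvl(grades, scheme: str = "binary_b"):
    """Encode PVL grades under one of four schemes.

    ``binary_a``: none+trivial (0) vs mild+ (1).
    ``binary_b``: none (0) vs mild+ (1), trivial dropped (NaN).
    ``continuous``: none 0, trivial 0.5, mild 1, moderate 2, severe 3.
    ``categorical``: grade labels kept as an ordered categorical.
    """
    s = pd.Series(grades)
    unknown = set(s.dropna().unique()) - set(PVL_GRADES)
    if unknown:
        raise ValueError(f"unknown PVL grade(s): {sorted(unknown)}")
    if scheme == "binary_a":
        return s.map({"none": 0, "trivial": 0, "mild": 1,
                      "moderate": 1, "severe": 1})
    if scheme == "binary_b":
        return s.map({"none": 0, "mild": 1, "moderate": 1, "severe": 1})
    if scheme == "continuous":
        return s.map(PVL_CONTINUOUS)
    if scheme == "categorical":
        return pd.Series(pd.Categorical(s, categories=PVL_GRADES,
                                        ordered=True))
    raise ValueError(f"unknown scheme '{scheme}'")


def grade_summary(counts) -> dict:
    """Percentages per grade and the mild-to-severe incidence.

    ``counts`` are the per-grade counts in the order none, trivial,
    mild, moderate, severe.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("zero total count")
    pct = 100.0 * c / total
    incidence = 100.0 * c[2:].sum() / total
    return {"percent": dict(zip(PVL_GRADES, pct)),
            "incidence_mild_plus_pct": float(incidence), "n": int(total)}


def device_type_share(n_self_expanding: int, n_balloon: int) -> float:
    """Self-expanding count relative to balloon-expandable count (%).

    Note the convention: the ratio of the two counts, not the share of
    all implanted devices.
    """
    if n_balloon <= 0:
        raise ValueError("balloon-expandable count must be positive")
    return 100.0 * n_self_expanding / n_balloon


def device_choice_model(table: pd.DataFrame, response: str,
                        predictors: list[str]):
    """Logistic model of a binary device choice.

    Maximum-likelihood fit via statsmodels; on (quasi-)separation the
    fit falls back to an L2-penalised fit with a notice.  Returns the
    fitted result plus a tidy coefficient table (sign, Wald z, p).
    """
    import statsmodels.api as sm

    data = table[[response] + predictors].dropna()
    y = data[response].astype(float)
    if y.nunique() < 2:
        raise ValueError("response has a single level")
    X = sm.add_constant(data[predictors].astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, X).fit(disp=0)
    except Exception:
        warnings.warn("separation detected; using L2-penalised logistic fit")
        res = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
    coefs = pd.DataFrame({"coef": res.params,
                          "sign": np.sign(res.params)})
    if getattr(res, "bse", None) is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            coefs["wald_z"] = res.params / res.bse
            coefs["p"] = 2 * stats.norm.sf(np.abs(coefs["wald_z"]))
    return res, coefs
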