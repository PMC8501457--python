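"""Experiment-level statistics over field-of-view summaries.

The statistical unit is the field of view.  Designs cross cell line,
HER2-inhibition treatment and metabolic treatment; the data are first fit to
a linear model with all interactions, and the ANOVA uses type II sums of
squares when no interaction term is significant and type III (with
sum-to-zero contrasts) otherwise.  Every pairwise group comparison is then
tested with Tukey-adjusted post hoc mean separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AnovaResult",
    "factorial_anova",
    "tukey_pairwise",
    "experiment_sem",
    "significance_stars",
]

STAR_TIERS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Conventional star annotation: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for threshold, stars in STAR_TIERS:
        if p < threshold:
            return stars
    return "ns"


@dataclass
class AnovaResult:
    """Per-term ANOVA table plus which sums-of-squares type was used."""

    table: pd.DataFrame  # index: term; columns: sum_sq, df, F, PR(>F)
    ss_type: str  # "II" or "III"
    interaction_significant: bool


def _clean_term(term: str) -> str:
    """Strip patsy decoration: C(Q('a'), Sum):C(Q('b')) -> a:b."""
    import re

    return re.sub(r"C\(Q\('([^']+)'\)(?:,\s*Sum)?\)", r"\1", term)


def _formula(response: str, factors: Sequence[str], sum_contrasts: bool) -> str:
    if sum_contrasts:
        terms = [f"C(Q('{f}'), Sum)" for f in factors]
    else:
        terms = [f"C(Q('{f}'))" for f in factors]
    return f"Q('{response}') ~ " + " * ".join(terms)


def anova_table(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    ss_type: str,
) -> pd.DataFrame:
    """Factorial ANOVA table with the requested sums-of-squares type.

    Type III uses sum-to-zero contrasts, as required for its terms to be
    interpretable; the intercept row is dropped.
    """
    if ss_type not in ("II", "III"):
        raise ValueError("ss_type must be 'II' or 'III'")
    sum_contrasts = ss_type == "III"
    model = smf.ols(_formula(response, factors, sum_contrasts), data=table).fit()
    resp_scale = float(np.square(table[response].astype(float)).sum())
    if model.ssr <= 1e-12 * max(resp_scale, 1e-30):
        raise ValueError("zero residual sum of squares; F statistics undefined")
    tab = sm.stats.anova_lm(model, typ=2 if ss_type == "II" else 3)
    tab = tab.drop(index=[ix for ix in tab.index if ix == "Intercept"])
    tab = tab.rename(columns={"PR(>F)": "p"})
    tab.index = [_clean_term(str(ix)) for ix in tab.index]
    return tab


def factorial_anova(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    alpha: float = 0.05,
) -> AnovaResult:
    """Interaction-gated factorial ANOVA.

    Fits the full-interaction linear model; if any interaction term is
    significant at ``alpha`` (judged on the type II table of the full
    model), reports type III sums of squares with sum-to-zero contrasts,
    otherwise type II.  Raises a ValueError naming the term when empty
    design cells make a term inestimable.
    """
    if len(factors) < 1:
        raise ValueError("need at least one factor")
    for f in list(factors) + [response]:
        if f not in table.columns:
            raise ValueError(f"column {f!r} missing from table")
    counts = table.groupby(list(factors), observed=True).size()
    full = 1
    for f in factors:
        full *= table[f].nunique()
    if len(counts) < full:
        raise ValueError("empty design cells: full interaction model inestimable")

    typ2 = anova_table(table, response, factors, "II")
    interaction_rows = [ix for ix in typ2.index if ":" in str(ix)]
    interaction_significant = bool(
        (typ2.loc[interaction_rows, "p"] < alpha).any()
    ) if interaction_rows else False

    if interaction_significant:
        tab, ss_type = anova_table(table, response, factors, "III"), "III"
    else:
        tab, ss_type = typ2, "II"
    return AnovaResult(table=tab, ss_type=ss_type,
                       interaction_significant=interaction_significant)


def tukey_pairwise(
    table: pd.DataFrame,
    response: str,
    group_cols: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey-HSD adjusted comparisons between every pair of factor groups.

    Groups are the observed combinations of ``group_cols``.  Returns a tidy
    frame with the mean difference, studentized-range adjusted p, a
    significance flag at ``alpha`` and the conventional star annotation.
    """
    groups = table[list(group_cols)].astype(str).agg(":".join, axis=1)
    sizes = groups.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with <2 observations: {small}")
    if sizes.size < 2:
        raise ValueError("need at least two groups")
    res = pairwise_tukeyhsd(endog=table[response].to_numpy(dtype=float),
                            groups=groups.to_numpy(), alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:],
                         columns=res.summary().data[0])
    out = pd.DataFrame({
        "group1": frame["group1"],
        "group2": frame["group2"],
        "mean_diff": frame["meandiff"].astype(float),
        "p_adj": np.asarray(res.pvalues, dtype=float),
        "significant": np.asarray(res.reject, dtype=bool),
    })
    out["stars"] = [significance_stars(p) for p in out["p_adj"]]
    return out


def experiment_sem(
    table: pd.DataFrame,
    response: str,
    group_cols: Sequence[str],
) -> pd.DataFrame:
    """Per-group mean and SEM over fields of view (sd / sqrt(n), n >= 2)."""
    def agg(v: pd.Series) -> pd.Series:
        v = v.astype(float)
        if len(v) < 2:
            raise ValueError("need at least two fields per group for a SEM")
        return pd.Series({
            "mean": v.mean(),
            "sem": v.std(ddof=1) / np.sqrt(len(v)),
            "n_fields": len(v),
        })

    out = (table.groupby(list(group_cols), observed=True)[response]
           .apply(agg).unstack().reset_index())
    out["n_fields"] = out["n_fields"].astype(int)
    return out
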