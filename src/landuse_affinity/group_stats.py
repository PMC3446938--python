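"""Order x frequency group analysis of the relative land-use indexes.

The unit of analysis is the taxon-occurrence: one row per (taxon,
collection) pair, carrying that collection's three relative land-use
indexes.  Because the three indexes are compositionally dependent (a
collection cannot be locally richer than its region in all three land-use
types at once) they are first analysed jointly with a type-III MANOVA
(Pillai's trace) on order, frequency class and their interaction, then
separately with three type-III ANOVAs under sum-to-zero contrasts.  Each
univariate model is reduced to its minimum adequate model by backward
elimination (interaction first, a main effect only once its interaction is
gone), and order-level differences are resolved with Tukey HSD tests on the
fitted model's residual variance, summarised as a compact letter display.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range
from statsmodels.multivariate.manova import MANOVA

__all__ = [
    "TermTestResult",
    "build_occurrence_table",
    "manova_type3",
    "anova_type3_backward",
    "tukey_letters",
    "order_affinity_summary",
    "RESPONSES",
]

logger = logging.getLogger(__name__)

RESPONSES = ("M_urban", "M_agri", "M_natural")
_FACTORS = ("order", "frequency_class")


@dataclass(frozen=True)
class TermTestResult:
    """One model term's type-III test."""

    term: str
    df_num: float
    df_den: float
    F: float
    p: float
    retained: bool


# ---------------------------------------------------------------------------
# Occurrence table

def build_occurrence_table(
    observations: pd.DataFrame,
    index_table: pd.DataFrame,
    taxa: pd.DataFrame,
    discarded_ids: set[str] | None = None,
) -> pd.DataFrame:
    """One row per taxon-occurrence with the collection's M values attached.

    Occurrences in discarded collections are dropped (their count is
    logged); an occurrence referencing a collection or taxon unknown to
    either table is an error.  Duplicate (taxon, collection) rows — e.g.
    several pictures of the same taxon in one collection — collapse to one
    occurrence.
    """
    discarded_ids = discarded_ids or set()
    retained_ids = set(index_table["collection_id"].astype(str))
    obs = observations.copy()
    obs["collection_id"] = obs["collection_id"].astype(str)
    if obs.empty:
        logger.warning("empty observations table: occurrence table is empty")
    unknown_c = set(obs["collection_id"]) - retained_ids - set(discarded_ids)
    if unknown_c:
        raise ValueError(f"unknown collection id(s) in observations: {sorted(unknown_c)[:5]}")
    unknown_t = set(obs["taxon_id"]) - set(taxa["taxon_id"])
    if unknown_t:
        raise ValueError(f"unknown taxon id(s) in observations: {sorted(unknown_t)[:5]}")
    n_before = len(obs)
    obs = obs[obs["collection_id"].isin(retained_ids)]
    dropped = n_before - len(obs)
    if dropped:
        logger.info("dropped %d occurrence(s) in discarded collections", dropped)
    occ = obs[["taxon_id", "collection_id"]].drop_duplicates()
    occ = occ.merge(taxa[["taxon_id", "order", "frequency_class"]], on="taxon_id")
    occ = occ.merge(
        index_table[["collection_id", *RESPONSES]], on="collection_id"
    )
    return occ.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Type-III models

def _sum_formula(response: str, terms: list[str]) -> str:
    rhs = (
        " + ".join(
            ":".join(f"C({f}, Sum)" for f in t.split(":")) for t in terms
        )
        or "1"
    )
    return f"{response} ~ {rhs}"


def _check_design(table: pd.DataFrame, terms: list[str], response: str) -> None:
    for f in _FACTORS:
        if any(f in t.split(":") for t in terms) and table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    y, X = patsy.dmatrices(
        _sum_formula(response, terms), table, return_type="dataframe"
    )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(
            "rank-deficient design (an empty factor cell with the interaction "
            "present?); consider dropping the interaction term"
        )
    if len(table) <= X.shape[1]:
        raise ValueError("fewer rows than model parameters")


def _pretty_term(term: str) -> str:
    return term.replace("C(", "").replace(", Sum)", "")


def manova_type3(
    table: pd.DataFrame,
    responses: tuple[str, ...] = RESPONSES,
    terms: list[str] | None = None,
) -> list[TermTestResult]:
    """Joint type-III multivariate test of the model terms.

    Pillai's trace for each term (under sum-to-zero contrasts each term's
    test is marginal, i.e. type III), converted to its approximate F.  With
    a single response the multivariate test reduces exactly to the
    univariate type-III ANOVA F, which is what is computed then.
    """
    terms = list(terms) if terms is not None else ["order", "frequency_class", "order:frequency_class"]
    _check_design(table, terms, responses[0])
    if len(responses) == 1:
        return _anova_type3(table, responses[0], terms)
    if all(table[r].nunique() == 1 for r in responses):
        return _degenerate_results(table, terms)
    lhs = " + ".join(responses)
    formula = _sum_formula(lhs, terms)
    mv = MANOVA.from_formula(formula, data=table).mv_test()
    out = []
    for term in terms:
        key = ":".join(f"C({f}, Sum)" for f in term.split(":"))
        stat = mv.results[key]["stat"]
        row = stat.loc["Pillai's trace"]
        out.append(
            TermTestResult(
                term=term,
                df_num=float(row["Num DF"]),
                df_den=float(row["Den DF"]),
                F=float(row["F Value"]),
                p=float(row["Pr > F"]),
                retained=True,
            )
        )
    return out


def _degenerate_results(table: pd.DataFrame, terms: list[str]) -> list[TermTestResult]:
    # constant response: no between-group variance, nothing to test
    df_den = float(len(table) - 1)
    return [TermTestResult(t, float("nan"), df_den, 0.0, 1.0, True) for t in terms]


def _anova_type3(
    table: pd.DataFrame, response: str, terms: list[str]
) -> list[TermTestResult]:
    if table[response].nunique() == 1:
        return _degenerate_results(table, terms)
    model = smf.ols(_sum_formula(response, terms), data=table).fit()
    aov = sm.stats.anova_lm(model, typ=3)
    out = []
    for term in terms:
        key = ":".join(f"C({f}, Sum)" for f in term.split(":"))
        row = aov.loc[key]
        out.append(
            TermTestResult(
                term=term,
                df_num=float(row["df"]),
                df_den=float(aov.loc["Residual", "df"]),
                F=float(row["F"]),
                p=float(row["PR(>F)"]),
                retained=True,
            )
        )
    return out


def anova_type3_backward(
    table: pd.DataFrame,
    response: str,
    alpha: float = 0.05,
):
    """Backward simplification of ``response ~ order * frequency_class``.

    Starting from the full factorial model, iteratively remove the least
    significant *removable* term whose type-III p exceeds ``alpha`` — the
    interaction is removable first, a main effect only once the interaction
    is gone — until every remaining term is significant (a term at exactly
    ``p == alpha`` is kept) or only the intercept remains.

    Returns ``(fitted minimum model, results)`` where ``results`` lists
    every term with its test at the step it was evaluated last and whether
    it survived into the minimum adequate model.
    """
    terms = ["order", "frequency_class", "order:frequency_class"]
    _check_design(table, terms, response)
    removed: dict[str, TermTestResult] = {}
    while terms:
        tests = {t.term: t for t in _anova_type3(table, response, terms)}
        removable = (
            ["order:frequency_class"]
            if "order:frequency_class" in terms
            else list(terms)
        )
        candidates = [tests[t] for t in removable if tests[t].p > alpha]
        if not candidates:
            break
        worst = max(candidates, key=lambda t: t.p)
        removed[worst.term] = TermTestResult(
            worst.term, worst.df_num, worst.df_den, worst.F, worst.p, False
        )
        terms.remove(worst.term)
    model = smf.ols(_sum_formula(response, terms), data=table).fit()
    final = _anova_type3(table, response, terms) if terms else []
    results = final + list(removed.values())
    return model, results


# ---------------------------------------------------------------------------
# Tukey HSD with compact letter display

def _compact_letters(
    levels: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Levels sharing a letter are not significantly different.  ``levels``
    should be sorted by descending mean so letters read conventionally;
    the display itself is invariant to level ordering.
    """
    groups: list[set[str]] = [set(levels)]
    for a, b in significant:
        for g in list(groups):
            if a in g and b in g:
                groups.remove(g)
                for new in (g - {a}, g - {b}):
                    if not any(new <= other for other in groups):
                        groups = [o for o in groups if not o <= new] + [new]
    pos = {lv: i for i, lv in enumerate(levels)}
    groups.sort(key=lambda g: min(pos[lv] for lv in g))
    letters = {lv: "" for lv in levels}
    for i, g in enumerate(groups):
        ch = chr(ord("a") + i)
        for lv in g:
            letters[lv] += ch
    return {lv: "".join(sorted(s)) for lv, s in letters.items()}


def tukey_letters(
    table: pd.DataFrame,
    response: str,
    factor: str = "order",
    alpha: float = 0.05,
    model=None,
) -> pd.DataFrame:
    """Tukey HSD comparisons among factor levels, with letter codes.

    All pairwise level differences are tested with the studentized-range
    distribution on the residual variance of ``model`` (the fitted minimum
    adequate model; when ``None``, a one-factor model is fitted here),
    using the Tukey-Kramer standard error for unbalanced groups.  Returns
    one row per level: mean, standard error of the mean, n and letter code,
    where levels sharing a letter do not differ at ``alpha``.
    """
    counts = table.groupby(factor, observed=True)[response].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"factor level(s) with fewer than 2 rows: {bad}")
    if counts.size < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    if model is None:
        model = smf.ols(_sum_formula(response, [factor]), data=table).fit()
    mse = float(model.mse_resid)
    df_resid = float(model.df_resid)
    means = table.groupby(factor, observed=True)[response].mean()
    sds = table.groupby(factor, observed=True)[response].std(ddof=1)
    k = means.size
    significant: set[tuple[str, str]] = set()
    for a, b in itertools.combinations(means.index, 2):
        se = np.sqrt(mse / 2.0 * (1.0 / counts[a] + 1.0 / counts[b]))
        q = abs(means[a] - means[b]) / se if se > 0 else 0.0
        p = float(studentized_range.sf(q, k, df_resid)) if se > 0 else 1.0
        if p < alpha:
            significant.add((str(a), str(b)))
    order_desc = [str(lv) for lv in means.sort_values(ascending=False).index]
    letters = _compact_letters(order_desc, significant)
    out = pd.DataFrame(
        {
            "level": [str(lv) for lv in means.index],
            "mean": means.to_numpy(),
            "se": (sds / np.sqrt(counts)).to_numpy(),
            "n": counts.to_numpy(),
        }
    )
    out["letters"] = out["level"].map(letters)
    return out.sort_values("mean", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Group-level affinity summary

def order_affinity_summary(occurrence_table: pd.DataFrame) -> pd.DataFrame:
    """Mean relative index and its standard error per order x frequency x land-use.

    The group mean over occurrence rows is the group's affinity; the
    standard error is sd/sqrt(n) with the n-1 denominator.  Singleton groups
    report SE 0 with ``se_undefined`` set; empty groups are simply absent
    (a warning is logged).
    """
    if occurrence_table.empty:
        logger.warning("empty occurrence table: no group summaries")
    rows = []
    grouped = occurrence_table.groupby(["order", "frequency_class"], observed=True)
    for (order, freq), grp in grouped:
        for resp, lu in zip(RESPONSES, ("urban", "agri", "natural")):
            v = grp[resp].to_numpy(dtype=float)
            n = v.size
            se = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append(
                {
                    "order": order,
                    "frequency_class": freq,
                    "landuse": lu,
                    "mean": float(v.mean()),
                    "se": se,
                    "n": n,
                    "se_undefined": n < 2,
                }
            )
    return pd.DataFrame(rows)
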