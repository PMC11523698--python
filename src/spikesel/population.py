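"""Population-level inference across recorded neurons.

Per-area counts of selective neurons are compared against the fraction
expected by chance with an exact upper-tail binomial test, with
Benjamini-Hochberg control of the false discovery rate across the tests of
one analysis batch.  Also provides the per-neuron one-way ANOVA for a
stimulus-category effect, Fisher's exact comparison of selective fractions
between subject groups, and the tuning-breadth histogram (how many neurons
code 0..4 categories).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CATEGORIES


def binomial_vs_chance(n_significant: int, n_total: int, chance: float = 0.05) -> float:
    """Exact upper-tail binomial probability P(X >= n_significant).

    ``chance`` is the per-test significance level: under the global null each
    neuron is declared selective with probability alpha, so the expected
    fraction of significant neurons is alpha.
    """
    if not 0 < chance < 1:
        raise ValueError("chance must be in (0, 1)")
    if not 0 <= n_significant <= n_total:
        raise ValueError("need 0 <= n_significant <= n_total")
    return float(stats.binom.sf(n_significant - 1, n_total, chance))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} (m / j) p_(j), capped at 1, for the ascending
    order statistics p_(1) <= ... <= p_(m).
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def anova_race_effect(counts: pd.DataFrame) -> tuple[float, bool]:
    """One-way fixed-effects ANOVA of response counts across the four
    categories.

    Returns ``(p_value, degenerate)``; ``degenerate`` is True (with NaN p)
    when F is undefined (zero between- and within-group variance, i.e. all
    observations identical).  Zero within-group variance with differing means
    gives an infinite F and p = 0.
    """
    import warnings

    groups = []
    for c in CATEGORIES:
        g = counts.loc[counts["category"] == c, "response_count"].to_numpy(float)
        if g.size < 2:
            raise ValueError(f"need at least 2 trials per category (got {g.size} for {c!r})")
        groups.append(g)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*groups)
    p = float(res.pvalue)
    return p, bool(np.isnan(p))


def fisher_fraction_compare(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p comparing fractions k1/n1 and k2/n2."""
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n in each group")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def round_half_up_percent(k: int, n: int) -> int:
    """Integer percentage with .5 rounded up, as in the summary tables."""
    if n <= 0:
        raise ValueError("n must be positive")
    return int(np.floor(100.0 * k / n + 0.5))


def area_category_summary(
    selectivity: pd.DataFrame,
    alpha: float = 0.05,
    fdr_family: str = "categories",
) -> pd.DataFrame:
    """Table-1-style summary: per area x category counts of selective neurons.

    ``selectivity`` is the long per-neuron x category frame from the
    regression stage.  Non-converged neurons (NaN p) count in denominators
    but never in numerators.  ``fdr_family`` selects the Benjamini-Hochberg
    family: ``"categories"`` corrects across all area x category tests in
    the batch; ``"areas"`` corrects within each category across areas.
    """
    if fdr_family not in ("categories", "areas", "all"):
        raise ValueError("fdr_family must be 'categories', 'areas' or 'all'")
    rows = []
    for area, grp in selectivity.groupby("area", sort=False):
        for cat in CATEGORIES:
            sub = grp[grp["category"] == cat]
            n = sub["neuron_id"].nunique()
            k = int(sub["significant"].eq(True).sum())  # NaN counts as False
            rows.append(
                {
                    "area": area,
                    "category": cat,
                    "n_total": n,
                    "n_significant": k,
                    "percent": round_half_up_percent(k, n),
                    "binomial_p": binomial_vs_chance(k, n, chance=alpha),
                }
            )
    out = pd.DataFrame(rows)
    if fdr_family == "areas":
        adj = np.empty(len(out))
        for cat in CATEGORIES:
            m = out["category"] == cat
            adj[m.to_numpy()] = benjamini_hochberg(out.loc[m, "binomial_p"].to_numpy())
        out["adjusted_p"] = adj
    else:
        out["adjusted_p"] = benjamini_hochberg(out["binomial_p"].to_numpy())
    out["significant_after_fdr"] = out["adjusted_p"] < alpha
    return out


def tuning_breadth(selectivity: pd.DataFrame) -> pd.DataFrame:
    """Histogram of the number of categories coded per neuron, by area.

    Returns one row per area x breadth (0..4) with counts and percentages of
    the area total; percentages per area sum to 100 up to rounding.
    """
    per_neuron = selectivity.drop_duplicates("neuron_id")[
        ["neuron_id", "area", "n_categories_coded"]
    ]
    rows = []
    for area, grp in per_neuron.groupby("area", sort=False):
        n = len(grp)
        for b in range(5):
            k = int((grp["n_categories_coded"] == b).sum())
            rows.append(
                {
                    "area": area,
                    "n_categories": b,
                    "n_neurons": k,
                    "n_total": n,
                    "percent": round_half_up_percent(k, n),
                }
            )
    return pd.DataFrame(rows)
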