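"""Per-neuron multinomial logistic regression for category selectivity.

Each trial contributes two observations: one labeled by its stimulus category
with the response-window spike count as the sole predictor, and one labeled
"background" with the background-window count.  A 5-level multinomial logit
(intercept + one slope per category, background as the reference level) is
fit by maximum likelihood; a two-sided Wald z-test of slope = 0 per category
decides whether the neuron's firing predicts that category versus background
firing.

No per-neuron correction is applied across the four category tests: multiple
comparisons are handled at the population stage (binomial tests against
chance with Benjamini-Hochberg FDR across areas/categories).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import BACKGROUND_LABEL, CATEGORIES

logger = logging.getLogger(__name__)

#: |log-odds slope| beyond which the fit is treated as separated/degenerate.
SEPARATION_COEF_LIMIT = 15.0
MAX_ITER = 100
CONVERGENCE_TOL = 1e-8


@dataclass
class SelectivityResult:
    """Per-category selectivity test results for one neuron.

    ``table`` has one row per category (fixed order) with columns
    ``coef, se, stat, p, significant``.  ``n_categories_coded`` counts the
    significant categories; non-converged or separated fits carry NaN
    p-values and code zero categories.
    """

    neuron_id: str
    area: str
    table: pd.DataFrame
    alpha: float = 0.05
    converged: bool = True
    separation_flag: bool = False
    llf: float = np.nan
    llnull: float = np.nan
    predictor: str = "count"

    @property
    def n_categories_coded(self) -> int:
        return int(self.table["significant"].sum())

    def to_rows(self) -> pd.DataFrame:
        out = self.table.reset_index(names="category")
        out.insert(0, "neuron_id", self.neuron_id)
        out.insert(1, "area", self.area)
        out["n_categories_coded"] = self.n_categories_coded
        out["converged"] = self.converged
        out["separation_flag"] = self.separation_flag
        return out


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "coef": np.nan,
            "se": np.nan,
            "stat": np.nan,
            "p": np.nan,
            "significant": False,
        },
        index=pd.Index(CATEGORIES, name="category"),
    )


def _degenerate(counts: pd.DataFrame, alpha: float, predictor: str) -> SelectivityResult:
    return SelectivityResult(
        neuron_id=str(counts["neuron_id"].iloc[0]),
        area=str(counts["area"].iloc[0]),
        table=_empty_table(),
        alpha=alpha,
        converged=False,
        separation_flag=True,
        predictor=predictor,
    )


def fit_selectivity(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    predictor: str = "count",
) -> SelectivityResult:
    """Fit the category-selectivity model to one neuron's trial counts.

    ``counts`` is a trial count matrix (one row per trial with
    ``category, response_count, background_count``).  With
    ``predictor="count"`` (default) the model is the 5-level multinomial
    logit on raw window counts described in the module docstring.
    ``predictor="ratio"`` is a sensitivity variant: one observation per trial
    labeled by category, with the shrunk response/background rate ratio
    ``(response+0.5)/(background+0.5)`` as predictor and the first category
    as reference; its per-category tests compare categories to each other
    rather than to background.

    Separation or non-convergence is reported via flags with NaN p-values;
    such neurons make no significance claims but stay in population
    denominators.
    """
    if predictor not in ("count", "ratio"):
        raise ValueError("predictor must be 'count' or 'ratio'")
    cats = counts["category"].to_numpy()
    if any((cats == c).sum() < 2 for c in CATEGORIES):
        raise ValueError("need at least 2 trials per category")

    resp = counts["response_count"].to_numpy(float)
    bg = counts["background_count"].to_numpy(float)
    if (resp == 0).all() and (bg == 0).all():
        logger.warning(
            "neuron %s: all counts zero; degenerate", counts["neuron_id"].iloc[0]
        )
        return _degenerate(counts, alpha, predictor)

    levels = (BACKGROUND_LABEL,) + CATEGORIES
    code = {lvl: i for i, lvl in enumerate(levels)}

    if predictor == "count":
        y = np.concatenate([[code[c] for c in cats], np.zeros(len(cats), int)])
        x = np.concatenate([resp, bg])
        test_levels = CATEGORIES  # slopes vs background reference
    else:
        y = np.array([code[c] for c in cats]) - 1  # categories only, 0-based
        x = (resp + 0.5) / (bg + 0.5)
        test_levels = CATEGORIES[1:]  # first category is the reference

    X = sm.add_constant(x.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.MNLogit(y, X).fit(
                method="newton", maxiter=MAX_ITER, tol=CONVERGENCE_TOL, disp=0
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning(
                "neuron %s: fit failed (%s)", counts["neuron_id"].iloc[0], exc
            )
            return _degenerate(counts, alpha, predictor)

    params = np.asarray(fit.params)  # (2, n_levels-1): rows const, slope
    bses = np.asarray(fit.bse)
    converged = bool(fit.mle_retvals.get("converged", False))
    # Separation shows as a diverging slope; intercepts may be legitimately
    # large-negative when a category never produces small counts.
    separated = bool(np.abs(params[1]).max() > SEPARATION_COEF_LIMIT)

    table = _empty_table()
    if converged and not separated:
        slopes = params[1]
        ses = bses[1]
        z = slopes / ses
        from scipy import stats as sps

        pvals = 2.0 * sps.norm.sf(np.abs(z))
        for j, lvl in enumerate(test_levels):
            table.loc[lvl, ["coef", "se", "stat", "p"]] = (
                slopes[j],
                ses[j],
                z[j],
                pvals[j],
            )
        table["significant"] = table["p"] < alpha
        table["significant"] = table["significant"].fillna(False).astype(bool)

    # Intercept-only log-likelihood in closed form (multinomial proportions);
    # statsmodels' llnull would refit a whole model.
    _, n_per_level = np.unique(y, return_counts=True)
    llnull = float((n_per_level * np.log(n_per_level / y.size)).sum())

    return SelectivityResult(
        neuron_id=str(counts["neuron_id"].iloc[0]),
        area=str(counts["area"].iloc[0]),
        table=table,
        alpha=alpha,
        converged=converged,
        separation_flag=separated,
        llf=float(fit.llf),
        llnull=llnull,
        predictor=predictor,
    )


def selectivity_frame(results: list[SelectivityResult]) -> pd.DataFrame:
    """Stack per-neuron results into one long DataFrame (one row per
    neuron x category)."""
    if not results:
        return pd.DataFrame(
            columns=[
                "neuron_id",
                "area",
                "category",
                "coef",
                "se",
                "stat",
                "p",
                "significant",
                "n_categories_coded",
                "converged",
                "separation_flag",
            ]
        )
    return pd.concat([r.to_rows() for r in results], ignore_index=True)
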