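"""Changes-from-background test (CBT).

A resampling test of the combined null hypothesis that firing rates are
equivalent across all stimulus categories *and* equal to background firing.
The test statistic is the sum over the four categories of the squared
deviation of the category's mean response count from the grand mean
background count; because response and background windows have identical
length, counts are proportional to rates and the statistic can be computed
on counts directly.

The null distribution is built by pooled resampling: all response and
background counts are pooled into one bag, and each resample draws (with
replacement) pseudo-groups of the original sizes — four category groups plus
one background group — and recomputes the statistic.  A label-permutation
variant (resampling without replacement, i.e. shuffling window/category
labels) is available via ``scheme="permute"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import benjamini_hochberg, binomial_vs_chance
from .types import CATEGORIES

DEFAULT_N_RESAMPLES = 10_000
MIN_RESAMPLES = 100
#: Resamples per vectorized batch; bounds peak memory at ~batch x 2n floats.
_BATCH = 2_000


@dataclass
class CBTResult:
    """Outcome of the CBT for one neuron."""

    neuron_id: str
    area: str
    observed_T: float
    p_value: float
    n_resamples: int
    seed: int


def cbt_statistic(counts: pd.DataFrame) -> float:
    """Sum of squared deviations of per-category mean response counts from
    the grand mean background count."""
    cats = counts["category"].to_numpy()
    resp = counts["response_count"].to_numpy(float)
    bg_mean = counts["background_count"].to_numpy(float).mean()
    t = 0.0
    for c in CATEGORIES:
        mask = cats == c
        if not mask.any():
            raise ValueError(f"no trials for category {c!r}")
        t += (resp[mask].mean() - bg_mean) ** 2
    return float(t)


def _stat_from_groups(group_means: np.ndarray, bg_means: np.ndarray) -> np.ndarray:
    """Vectorized statistic: group_means (R, 4), bg_means (R,)."""
    return ((group_means - bg_means[:, None]) ** 2).sum(axis=1)


def cbt_test(
    counts: pd.DataFrame,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    scheme: str = "pooled",
) -> CBTResult:
    """Run the CBT for one neuron's trial count matrix.

    The p-value uses the add-one rule
    ``p = (1 + #{T* >= T_obs}) / (n_resamples + 1)``, which avoids zero
    p-values from finite resampling.  Identical seeds give identical p.
    """
    if n_resamples < MIN_RESAMPLES:
        raise ValueError(f"n_resamples must be >= {MIN_RESAMPLES} for a stable p")
    if scheme not in ("pooled", "permute"):
        raise ValueError("scheme must be 'pooled' or 'permute'")

    observed = cbt_statistic(counts)

    cats = counts["category"].to_numpy()
    resp = counts["response_count"].to_numpy(float)
    bg = counts["background_count"].to_numpy(float)
    sizes = [int((cats == c).sum()) for c in CATEGORIES]
    n_bg = bg.size
    bag = np.concatenate([resp, bg])
    total = sum(sizes) + n_bg
    edges = np.cumsum([0] + sizes + [n_bg])

    rng = np.random.default_rng(seed)
    n_extreme = 0
    done = 0
    while done < n_resamples:
        r = min(_BATCH, n_resamples - done)
        if scheme == "pooled":
            draws = bag[rng.integers(0, bag.size, size=(r, total))]
        else:
            # Permutation: shuffle the pooled bag rows independently.
            draws = np.take_along_axis(
                np.broadcast_to(bag, (r, bag.size)).copy(),
                rng.permuted(
                    np.broadcast_to(np.arange(bag.size), (r, bag.size)).copy(), axis=1
                ),
                axis=1,
            )
        group_means = np.stack(
            [draws[:, edges[i] : edges[i + 1]].mean(axis=1) for i in range(4)], axis=1
        )
        bg_means = draws[:, edges[4] : edges[5]].mean(axis=1)
        t_star = _stat_from_groups(group_means, bg_means)
        n_extreme += int((t_star >= observed).sum())
        done += r

    p = (1 + n_extreme) / (n_resamples + 1)
    return CBTResult(
        neuron_id=str(counts["neuron_id"].iloc[0]),
        area=str(counts["area"].iloc[0]),
        observed_T=observed,
        p_value=float(p),
        n_resamples=n_resamples,
        seed=seed,
    )


def cbt_frame(results: list[CBTResult]) -> pd.DataFrame:
    """Stack CBT results into one DataFrame."""
    return pd.DataFrame(
        [
            {
                "neuron_id": r.neuron_id,
                "area": r.area,
                "observed_T": r.observed_T,
                "p": r.p_value,
                "n_resamples": r.n_resamples,
                "seed": r.seed,
            }
            for r in results
        ],
        columns=["neuron_id", "area", "observed_T", "p", "n_resamples", "seed"],
    )


def cbt_population(results: list[CBTResult], alpha: float = 0.05) -> pd.DataFrame:
    """Per-area summary of CBT outcomes (Table-2-style).

    For each area: number of neurons, number significant at ``alpha``,
    rounded percentage, upper-tail binomial p-value against chance ``alpha``,
    and Benjamini-Hochberg adjusted p across areas.
    """
    df = cbt_frame(results)
    if df.empty:
        raise ValueError("need at least one CBT result")
    rows = []
    for area, grp in df.groupby("area", sort=False):
        n = len(grp)
        k = int((grp["p"] < alpha).sum())
        rows.append(
            {
                "area": area,
                "n_total": n,
                "n_significant": k,
                "percent": int(np.floor(100 * k / n + 0.5)),
                "binomial_p": binomial_vs_chance(k, n, chance=alpha),
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = benjamini_hochberg(out["binomial_p"].to_numpy())
    out["significant_after_fdr"] = out["adjusted_p"] < alpha
    return out
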