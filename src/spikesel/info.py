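"""Mutual information between spike counts and stimulus category.

A plug-in (maximum-likelihood) estimate on the joint empirical distribution
of (response-window count, category): counts enter as raw discrete symbols
without binning, logs are base 2, and zero-probability cells contribute zero
by the 0*log 0 = 0 convention.  The plug-in estimator is positively biased
at finite sample size; an optional Miller-Madow correction subtracts the
first-order bias term (K_joint - K_count - K_cat + 1) / (2 n ln 2).

The per-area "neurons to decode" figure divides the 2-bit entropy of four
equiprobable categories by the area's mean per-neuron MI — an estimate that
assumes additivity and independence across neurons and is therefore
optimistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Entropy of four equiprobable stimulus categories.
CATEGORY_BITS = 2.0


@dataclass
class InfoResult:
    neuron_id: str
    area: str
    mi_bits: float
    n_trials: int


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    counts: pd.DataFrame, bias_correction: str = "none", max_count: int | None = None
) -> InfoResult:
    """Plug-in mutual information (bits) between response counts and category.

    ``max_count`` merges the upper tail of the count distribution into one
    symbol (counts are capped at this value) — useful for pathological
    simulations with huge count supports; off by default.
    ``bias_correction`` is ``"none"`` (plain plug-in) or ``"miller-madow"``.
    """
    if bias_correction not in ("none", "miller-madow"):
        raise ValueError("bias_correction must be 'none' or 'miller-madow'")
    cats = counts["category"].to_numpy()
    if np.unique(cats).size < 2:
        raise ValueError("need at least 2 distinct categories")
    x = counts["response_count"].to_numpy()
    if max_count is not None:
        x = np.minimum(x, max_count)

    joint = pd.crosstab(x, cats).to_numpy(float)
    n = joint.sum()
    pj = joint / n
    px = pj.sum(axis=1)
    py = pj.sum(axis=0)

    mi = _entropy_bits(px) + _entropy_bits(py) - _entropy_bits(pj.ravel())
    if bias_correction == "miller-madow":
        k_joint = int((joint > 0).sum())
        k_x = int((joint.sum(axis=1) > 0).sum())
        k_y = int((joint.sum(axis=0) > 0).sum())
        mi -= (k_joint - k_x - k_y + 1) / (2.0 * n * np.log(2.0))
    mi = max(mi, 0.0)

    h_bound = min(_entropy_bits(px), _entropy_bits(py))
    assert mi <= h_bound + 1e-9, "MI exceeded marginal entropy bound"

    return InfoResult(
        neuron_id=str(counts["neuron_id"].iloc[0]),
        area=str(counts["area"].iloc[0]),
        mi_bits=float(mi),
        n_trials=int(n),
    )


def info_frame(results: list[InfoResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"neuron_id": r.neuron_id, "area": r.area, "mi_bits": r.mi_bits, "n_trials": r.n_trials}
            for r in results
        ],
        columns=["neuron_id", "area", "mi_bits", "n_trials"],
    )


def neurons_to_decode(results: list[InfoResult]) -> pd.DataFrame:
    """Per-area mean MI and the neurons needed for 2 bits (Table-3-style).

    ``neurons_to_2_bits`` is 2 / mean MI, reported to one decimal place;
    areas with zero mean MI are flagged unbounded (inf).
    """
    df = info_frame(results)
    if df.empty:
        raise ValueError("need at least one InfoResult")
    rows = []
    for area, grp in df.groupby("area", sort=False):
        mean_mi = float(grp["mi_bits"].mean())
        if mean_mi > 0:
            need = round(CATEGORY_BITS / mean_mi, 1)
            unbounded = False
        else:
            need = float("inf")
            unbounded = True
        rows.append(
            {
                "area": area,
                "n_neurons": len(grp),
                "mean_mi_bits": mean_mi,
                "neurons_to_2_bits": need,
                "unbounded": unbounded,
            }
        )
    return pd.DataFrame(rows)


def anova_mi_across_areas(results: list[InfoResult]) -> tuple[float, bool]:
    """One-way ANOVA of per-neuron MI by area.

    Returns ``(p_value, degenerate)``; degenerate (NaN p) when all groups
    have zero variance.
    """
    df = info_frame(results)
    groups = [g["mi_bits"].to_numpy(float) for _, g in df.groupby("area", sort=False)]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 areas with >= 2 neurons each")
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.f_oneway(*groups).pvalue)
    return p, bool(np.isnan(p))
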