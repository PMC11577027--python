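"""Treatment contrasts and flux-structure slopes for the nested design.

The experiment nests mesocosms in EcoUnits in blocks, with the
four-level community-history factor (soil x plant history) crossed
within every EcoUnit. Uncertainty that respects this hierarchy is
obtained by a two-stage nonparametric bootstrap: blocks are resampled
with replacement, then EcoUnits within each sampled block, each
resampled EcoUnit contributing its full set of four mesocosms.
Treatment means, their pairwise differences (and the pooled soil- and
plant-history main effects), and log-log regression slopes are
recomputed per draw; percentile intervals summarise the draws.

The decision rule mirrors common practice with credible intervals: a
difference is "clear" when the 95% interval excludes zero, "marginal"
when only the 90% interval does, and "unclear" otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synth import HISTORY_LEVELS

__all__ = [
    "ContrastResult",
    "SlopeResult",
    "hierarchical_draws",
    "pairwise_contrasts",
    "structure_slopes",
    "interval_decision",
    "contrasts_table",
]


@dataclass(frozen=True)
class ContrastResult:
    """One estimated difference with its bootstrap intervals."""

    response: str
    level_a: str
    level_b: str
    estimate: float
    ci95: tuple[float, float]
    ci90: tuple[float, float]
    draws: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def excludes_zero_95(self) -> bool:
        return self.ci95[0] > 0 or self.ci95[1] < 0

    @property
    def excludes_zero_90(self) -> bool:
        return self.ci90[0] > 0 or self.ci90[1] < 0

    @property
    def decision(self) -> str:
        return interval_decision(self)


@dataclass(frozen=True)
class SlopeResult:
    """A bootstrap regression slope (log response on log predictor)."""

    response: str
    predictor: str
    estimate: float
    ci95: tuple[float, float]
    ci90: tuple[float, float]
    draws: np.ndarray = field(repr=False, compare=False, default=None)


def interval_decision(result: ContrastResult) -> str:
    """'clear' (95% excludes 0), 'marginal' (only 90% does) or 'unclear'."""
    if result.excludes_zero_95:
        return "clear"
    if result.excludes_zero_90:
        return "marginal"
    return "unclear"


def _percentiles(draws: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
    lo95, hi95 = np.percentile(draws, [2.5, 97.5])
    lo90, hi90 = np.percentile(draws, [5.0, 95.0])
    return (float(lo95), float(hi95)), (float(lo90), float(hi90))


def _design_array(
    data: pd.DataFrame, response: str, transform: str
) -> tuple[np.ndarray, list[str]]:
    """Reshape mesocosm responses to (block, ecounit-in-block, history).

    Raises when any block x EcoUnit x history cell is missing.
    """
    required = {"block", "ecounit", "history", response}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data missing column(s): {sorted(missing)}")
    y = data[response].to_numpy(dtype=float)
    if transform == "log":
        if np.any(y <= 0):
            raise ValueError(f"log transform requires positive {response}")
        y = np.log(y)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")

    blocks = sorted(data["block"].unique())
    levels = list(HISTORY_LEVELS)
    if set(data["history"]) != set(levels):
        raise ValueError(
            f"history must have exactly the levels {levels}; "
            f"got {sorted(set(data['history']))}"
        )
    eco_of_block = {
        b: sorted(data.loc[data["block"] == b, "ecounit"].unique()) for b in blocks
    }
    n_eco = len(eco_of_block[blocks[0]])
    if any(len(e) != n_eco for e in eco_of_block.values()):
        raise ValueError("unbalanced design: unequal EcoUnits per block")
    arr = np.full((len(blocks), n_eco, len(levels)), np.nan)
    pos_h = {h: k for k, h in enumerate(levels)}
    for row, yv in zip(data.itertuples(index=False), y):
        bi = blocks.index(row.block)
        ei = eco_of_block[row.block].index(row.ecounit)
        arr[bi, ei, pos_h[row.history]] = yv
    if np.isnan(arr).any():
        raise ValueError("missing treatment cell(s) in the design")
    return arr, levels


def hierarchical_draws(
    data: pd.DataFrame,
    response: str,
    n_boot: int = 2000,
    seed: int = 0,
    transform: str = "log",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Bootstrap draws of the four treatment means.

    Returns ``(point, draws, levels)``: the observed treatment means,
    an (n_boot, 4) array of resampled means, and the level order. All
    contrasts derived from one draw set share the same resampling, so
    antisymmetry holds exactly per draw.
    """
    arr, levels = _design_array(data, response, transform)
    n_b, n_e, _ = arr.shape
    point = arr.mean(axis=(0, 1))
    rng = np.random.default_rng(seed)
    bi = rng.integers(n_b, size=(n_boot, n_b))
    ei = rng.integers(n_e, size=(n_boot, n_b, n_e))
    sel = arr[bi]  # (n_boot, n_b, n_e, 4)
    sel = np.take_along_axis(sel, ei[..., None], axis=2)
    draws = sel.mean(axis=(1, 2))
    return point, draws, levels


#: Pooled main-effect contrasts over the four-level history factor.
_POOLED = {
    "soil_history": (("S+P+", "S+P-"), ("S-P+", "S-P-")),
    "plant_history": (("S+P+", "S-P+"), ("S+P-", "S-P-")),
}


def pairwise_contrasts(
    data: pd.DataFrame,
    response: str,
    n_boot: int = 2000,
    seed: int = 0,
    transform: str = "log",
    pooled: bool = True,
    keep_draws: bool = False,
) -> list[ContrastResult]:
    """All six pairwise history contrasts (plus pooled main effects).

    Differences are level_a minus level_b on the analysis (log by
    default) scale, with 95% and 90% percentile intervals from the
    hierarchical bootstrap. ``pooled=True`` appends the soil- and
    plant-history main effects (mean of the two levels with the
    attribute minus the mean of the two without).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point, draws, levels = hierarchical_draws(data, response, n_boot, seed, transform)
    idx = {h: k for k, h in enumerate(levels)}
    results = []

    def _mk(name_a, name_b, est, dr):
        ci95, ci90 = _percentiles(dr)
        return ContrastResult(
            response=response,
            level_a=name_a,
            level_b=name_b,
            estimate=float(est),
            ci95=ci95,
            ci90=ci90,
            draws=dr if keep_draws else None,
        )

    for a, b in itertools.combinations(levels, 2):
        results.append(
            _mk(a, b, point[idx[a]] - point[idx[b]], draws[:, idx[a]] - draws[:, idx[b]])
        )
    if pooled:
        for name, (with_lv, without_lv) in _POOLED.items():
            iw = [idx[h] for h in with_lv]
            io = [idx[h] for h in without_lv]
            est = point[iw].mean() - point[io].mean()
            dr = draws[:, iw].mean(axis=1) - draws[:, io].mean(axis=1)
            results.append(_mk(f"{name}+", f"{name}-", est, dr))
    return results


def structure_slopes(
    data: pd.DataFrame,
    response: str,
    predictor: str,
    n_boot: int = 2000,
    seed: int = 0,
    standardize: bool = False,
) -> SlopeResult:
    """Bootstrap slope of log response on log predictor across mesocosms.

    Both variables are log-transformed; ``standardize=True`` rescales
    the predictor to unit variance within each draw (slope per SD of
    the log predictor instead of the raw log-log elasticity). The
    hierarchy is resampled exactly as in :func:`pairwise_contrasts`.
    """
    y_arr, _ = _design_array(data, response, "log")
    x_arr, _ = _design_array(data, predictor, "log")
    if np.var(x_arr) == 0:
        raise ValueError(f"predictor {predictor} has zero variance")
    n_b, n_e, _ = y_arr.shape
    rng = np.random.default_rng(seed)
    bi = rng.integers(n_b, size=(n_boot, n_b))
    ei = rng.integers(n_e, size=(n_boot, n_b, n_e))

    def _gather(arr):
        sel = np.take_along_axis(arr[bi], ei[..., None], axis=2)
        return sel.reshape(n_boot, -1)

    def _slope(x, y):
        xc = x - x.mean(axis=-1, keepdims=True)
        yc = y - y.mean(axis=-1, keepdims=True)
        s = (xc * yc).sum(axis=-1) / (xc**2).sum(axis=-1)
        if standardize:
            s = s * x.std(axis=-1)
        return s

    est = float(_slope(x_arr.reshape(1, -1), y_arr.reshape(1, -1))[0])
    draws = _slope(_gather(x_arr), _gather(y_arr))
    ci95, ci90 = _percentiles(draws)
    return SlopeResult(
        response=response,
        predictor=predictor,
        estimate=est,
        ci95=ci95,
        ci90=ci90,
        draws=draws,
    )


def contrasts_table(results: Sequence[ContrastResult]) -> pd.DataFrame:
    """Flatten contrast results for CSV export."""
    return pd.DataFrame(
        [
            {
                "response": r.response,
                "level_a": r.level_a,
                "level_b": r.level_b,
                "estimate": r.estimate,
                "ci95_lo": r.ci95[0],
                "ci95_hi": r.ci95[1],
                "ci90_lo": r.ci90[0],
                "ci90_hi": r.ci90[1],
                "decision": r.decision,
            }
            for r in results
        ]
    )
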