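"""Rank-exponential model of coordinated expression growth (model 1, part A).

Within one breed/tissue the ranked magnitudes are modelled as

    |FC - 1|(N) = a + K * e**N

where N is the ascending magnitude rank.  The model is linear in ``e**N``
and is fitted by ordinary least squares -- through the origin (a = 0) or
with a free intercept.  The slope K measures how tightly the panel follows
a common exponential growth; the breed-level index MGEI = K(breast)/K(thigh)
summarises the two muscles in one number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_model import FCTable, RankWindow
from .transforms import RankedSeries, rank_series

__all__ = [
    "RankFit",
    "BreedIndexSet",
    "FREE_INTERCEPT",
    "ZERO_INTERCEPT",
    "fit_pooled",
    "fit_breed",
    "compute_mgei",
    "predicted_vs_actual_correlation",
    "breed_index_table",
]

FREE_INTERCEPT = "free_intercept"
ZERO_INTERCEPT = "zero_intercept"


@dataclass(frozen=True)
class RankFit:
    """A fitted rank-exponential regression.

    ``r2``/``adj_r2`` for zero-intercept fits use the uncentered total sum
    of squares (the standard no-intercept convention), with denominator
    n - 1 in the adjusted variant.
    """

    a: float
    K: float
    mode: str
    ranks_used: RankWindow
    n_points: int
    r2: float
    adj_r2: float
    pearson_pred_actual: float

    def predict(self, ranks: Iterable[int]) -> np.ndarray:
        n = np.asarray(list(ranks), dtype=float)
        return self.a + self.K * np.exp(n)


@dataclass(frozen=True)
class BreedIndexSet:
    breed: str
    k_breast: float
    k_thigh: float
    mgei: float


def _pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    if len(obs) < 3 or np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return math.nan
    return float(np.corrcoef(pred, obs)[0, 1])


def _ls_fit(m: np.ndarray, x: np.ndarray, mode: str) -> tuple[float, float, int]:
    """Least squares of magnitude on x = e**N; returns (a, K, n_params)."""
    if mode == ZERO_INTERCEPT:
        if len(m) < 2:
            raise ValueError("zero-intercept fit needs at least 2 points")
        # closed form through the origin
        K = float(np.dot(m, x) / np.dot(x, x))
        return 0.0, K, 1
    if mode == FREE_INTERCEPT:
        if len(m) < 3:
            raise ValueError("free-intercept fit needs at least 3 points")
        design = np.column_stack([np.ones_like(x), x])
        (a, K), *_ = np.linalg.lstsq(design, m, rcond=None)
        return float(a), float(K), 2
    raise ValueError(f"unknown intercept mode {mode!r}")


def _goodness(m: np.ndarray, pred: np.ndarray, mode: str, n_params: int
              ) -> tuple[float, float]:
    rss = float(np.sum((m - pred) ** 2))
    if mode == ZERO_INTERCEPT:
        tss = float(np.sum(m ** 2))
        dof_tot = len(m) - 1
    else:
        tss = float(np.sum((m - m.mean()) ** 2))
        dof_tot = len(m) - 1
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    dof_res = len(m) - n_params
    adj = (1.0 - (rss / dof_res) / (tss / dof_tot)
           if dof_res > 0 and tss > 0 else math.nan)
    return r2, adj


def _build_fit(m: np.ndarray, ranks: np.ndarray, mode: str) -> RankFit:
    x = np.exp(ranks.astype(float))
    a, K, n_params = _ls_fit(m, x, mode)
    pred = a + K * x
    r2, adj = _goodness(m, pred, mode, n_params)
    return RankFit(
        a=a, K=K, mode=mode,
        ranks_used=RankWindow(int(ranks.min()), int(ranks.max())),
        n_points=len(m), r2=r2, adj_r2=adj,
        pearson_pred_actual=_pearson(pred, m),
    )


def fit_pooled(series_set: Sequence[RankedSeries], max_rank: int) -> RankFit:
    """Through-origin fit pooled over breeds, ranks 1..max_rank each.

    Every series must extend to ``max_rank``; the pooled design stacks the
    (rank, magnitude) points of all series and solves the closed-form
    through-origin slope K = sum(m*e^N) / sum(e^(2N)).
    """
    if max_rank < 2:
        raise ValueError("max_rank must be >= 2")
    mags, ranks = [], []
    for series in series_set:
        if len(series) < max_rank:
            raise ValueError(
                f"series {series.breed}/{series.tissue} has only "
                f"{len(series)} ranks; max_rank={max_rank} requested"
            )
        mags.extend(series.magnitudes(1, max_rank))
        ranks.extend(range(1, max_rank + 1))
    return _build_fit(np.asarray(mags), np.asarray(ranks), ZERO_INTERCEPT)


def fit_breed(series: RankedSeries, max_rank: int,
              mode: str = ZERO_INTERCEPT) -> RankFit:
    """Per-breed rank-exponential fit over ranks 1..max_rank."""
    if len(series) < max_rank:
        raise ValueError(
            f"series {series.breed}/{series.tissue} has only "
            f"{len(series)} ranks; max_rank={max_rank} requested"
        )
    m = np.asarray(series.magnitudes(1, max_rank))
    ranks = np.arange(1, max_rank + 1)
    return _build_fit(m, ranks, mode)


def compute_mgei(k_breast: float, k_thigh: float) -> float:
    """MGEI = K(breast) / K(thigh), from unrounded slopes."""
    if k_thigh == 0:
        raise ZeroDivisionError("MGEI undefined: thigh slope is zero")
    return k_breast / k_thigh


def predicted_vs_actual_correlation(fit: RankFit,
                                    series_set: Sequence[RankedSeries]) -> float:
    """Pearson correlation of fitted vs observed magnitudes over the fit's points.

    For a through-origin fit this equals corr(m, e^N) exactly, since the
    fitted values are a positive rescaling of e^N.
    """
    lo, hi = fit.ranks_used.lo, fit.ranks_used.hi
    obs, pred = [], []
    for series in series_set:
        m = series.magnitudes(lo, hi)
        obs.extend(m)
        pred.extend(fit.predict(range(lo, hi + 1)))
    if len(obs) < 3:
        raise ValueError("correlation undefined for fewer than 3 points")
    return _pearson(np.asarray(pred), np.asarray(obs))


def breed_index_table(
    table: FCTable,
    intercept_modes: Mapping[tuple[str, str], str] | None = None,
    max_rank_breast: int = 6,
    max_rank_thigh: int = 4,
) -> list[tuple[BreedIndexSet, RankFit, RankFit]]:
    """Fit both tissues for every breed and derive MGEI.

    ``intercept_modes`` maps (breed, tissue) to an intercept mode; pairs not
    listed default to the through-origin fit.  Returns one
    (indices, breast fit, thigh fit) triple per breed, in table breed order.
    """
    modes = dict(intercept_modes or {})
    out = []
    for breed in table.breeds:
        fits = {}
        for tissue, max_rank in (("breast", max_rank_breast),
                                 ("thigh", max_rank_thigh)):
            series = rank_series(table, breed, tissue)
            mode = modes.get((breed, tissue), ZERO_INTERCEPT)
            fits[tissue] = fit_breed(series, max_rank, mode)
        idx = BreedIndexSet(
            breed=breed,
            k_breast=fits["breast"].K,
            k_thigh=fits["thigh"].K,
            mgei=compute_mgei(fits["breast"].K, fits["thigh"].K),
        )
        out.append((idx, fits["breast"], fits["thigh"]))
    return out
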