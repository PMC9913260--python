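"""Log-log fractal-dimension fits over rank windows (model 1, part B).

Within one breed/tissue the ranked magnitudes are modelled as a power law

    |FC - 1|(N) = c * N**D

estimated as the slope D of an ordinary least-squares line of
log10(magnitude) on log10(rank) over a contiguous rank window.  Windows
are per-breed configuration (the bundled reference windows reproduce the
published dimensions); an automated best-r2 window search is provided as a
convenience generalisation of the published manual selection.  The
breed-level index MGEFDI = D(breast)/D(thigh) mirrors MGEI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import FCTable, PhenotypeRecord, RankWindow
from .transforms import RankedSeries, rank_series

__all__ = [
    "DimensionFit",
    "BreedDimensionSet",
    "fit_dimension",
    "select_window",
    "compute_mgefdi",
    "pointwise_dimension",
    "dimension_weight_regression",
    "breed_dimension_table",
]


@dataclass(frozen=True)
class DimensionFit:
    """A fitted log-log line: slope D, offset c = 10**intercept, window, r2."""

    D: float
    c: float
    window: RankWindow
    r2: float


@dataclass(frozen=True)
class BreedDimensionSet:
    breed: str
    d_breast: float
    d_thigh: float
    mgefdi: float


def _loglog(series: RankedSeries, window: RankWindow
            ) -> tuple[np.ndarray, np.ndarray]:
    if window.hi > len(series):
        raise ValueError(
            f"window {window} exceeds series length {len(series)} "
            f"({series.breed}/{series.tissue})"
        )
    m = np.asarray(series.magnitudes(window.lo, window.hi))
    if np.any(m <= 0):
        bad = [e.gene for e in series.entries[window.lo - 1:window.hi]
               if e.magnitude <= 0]
        raise ValueError(
            f"log undefined: zero magnitude inside window {window} for "
            f"gene(s) {bad} ({series.breed}/{series.tissue})"
        )
    n = np.arange(window.lo, window.hi + 1, dtype=float)
    return np.log10(n), np.log10(m)


def fit_dimension(series: RankedSeries, window: RankWindow) -> DimensionFit:
    """OLS of log10(magnitude) on log10(rank) over the window."""
    lx, ly = _loglog(series, window)
    D, lgc = np.polyfit(lx, ly, 1)
    pred = D * lx + lgc
    tss = float(np.sum((ly - ly.mean()) ** 2))
    rss = float(np.sum((ly - pred) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    return DimensionFit(D=float(D), c=float(10.0 ** lgc), window=window, r2=r2)


def select_window(
    series: RankedSeries,
    min_len: int = 3,
    default: RankWindow | None = None,
    manual: RankWindow | None = None,
) -> RankWindow:
    """Pick the contiguous rank window with the best log-log r2.

    A ``manual`` override always wins.  Otherwise all contiguous windows of
    length >= ``min_len`` inside the default range extended by one extra
    rank (capped at the series length) are enumerated and the one with the
    highest r2 is returned; ties prefer the longer window, then the lower
    start rank.
    """
    if manual is not None:
        return manual
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    if len(series) < min_len:
        raise ValueError(
            f"series {series.breed}/{series.tissue} shorter than min_len"
        )
    if default is None:
        default = RankWindow(1, len(series))
    lo0 = default.lo
    hi0 = min(default.hi + 1, len(series))
    best: tuple[float, int, int, RankWindow] | None = None
    for lo in range(lo0, hi0 - min_len + 2):
        for hi in range(lo + min_len - 1, hi0 + 1):
            w = RankWindow(lo, hi)
            r2 = fit_dimension(series, w).r2
            key = (r2, len(w), -lo)
            if best is None or key > best[:3]:
                best = (r2, len(w), -lo, w)
    assert best is not None
    return best[3]


def compute_mgefdi(d_breast: float, d_thigh: float) -> float:
    """MGEFDI = D(breast) / D(thigh), from unrounded slopes."""
    if d_thigh == 0:
        raise ZeroDivisionError("MGEFDI undefined: thigh dimension is zero")
    return d_breast / d_thigh


def pointwise_dimension(magnitude: float, rank: int) -> float:
    """Deprecated single-point ratio log10(magnitude)/log10(rank).

    This is the literal simplification of the power-law relation with the
    offset removed.  It is undefined at rank 1 and does not reproduce the
    regression-slope dimensions; prefer :func:`fit_dimension`.
    """
    warnings.warn(
        "pointwise_dimension is a deprecated simplification; "
        "use fit_dimension", DeprecationWarning, stacklevel=2,
    )
    if rank <= 1:
        raise ValueError("pointwise ratio undefined at rank <= 1")
    if magnitude <= 0:
        raise ValueError("log undefined for non-positive magnitude")
    return math.log10(magnitude) / math.log10(rank)


def dimension_weight_regression(
    dims: Mapping[str, float] | Sequence[tuple[str, float]],
    phenotypes: Sequence[PhenotypeRecord],
    trait: str = "bw28",
) -> tuple[float, float, float]:
    """OLS of a breed trait on the fractal dimension across breeds.

    Returns (slope, intercept, r2).  Needs at least 3 breeds common to both
    inputs.
    """
    dims = dict(dims)
    pheno = {p.breed: p for p in phenotypes}
    common = [b for b in dims if b in pheno]
    if len(common) < 3:
        raise ValueError("need at least 3 breeds common to dims and phenotypes")
    x = np.asarray([dims[b] for b in common])
    y = np.asarray([getattr(pheno[b], trait) for b in common])
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return 0.0, float(y.mean()), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def breed_dimension_table(
    table: FCTable,
    windows: Mapping[str, Mapping[str, RankWindow]],
    auto_select: bool = False,
) -> list[tuple[BreedDimensionSet, DimensionFit, DimensionFit]]:
    """Dimension fits for both tissues of every breed, plus MGEFDI.

    ``windows`` maps breed -> tissue -> window.  With ``auto_select`` the
    mapped window acts as the search default instead of a manual override.
    """
    out = []
    for breed in table.breeds:
        fits = {}
        for tissue in ("breast", "thigh"):
            series = rank_series(table, breed, tissue)
            w = windows[breed][tissue]
            if auto_select:
                w = select_window(series, default=w)
            fits[tissue] = fit_dimension(series, w)
        dset = BreedDimensionSet(
            breed=breed,
            d_breast=fits["breast"].D,
            d_thigh=fits["thigh"].D,
            mgefdi=compute_mgefdi(fits["breast"].D, fits["thigh"].D),
        )
        out.append((dset, fits["breast"], fits["thigh"]))
    return out
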