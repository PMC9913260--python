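"""Derived phenotype quantities and the breed-level statistical battery.

Growth rates are plain ratios of post-hatch body weights to day-old weight;
the NO oxidation rate is the percentage of NO metabolites already oxidised
to nitrate in the E7 embryo.  Because only eight breeds are observed, the
battery is deliberately small-sample-minded: a Shapiro-Wilk normality gate
recommends rank correlation, Spearman p-values are computed by exact
permutation when n <= 8, and a one-way fixed-effects ANOVA compares
breed-level indices across nominal categories.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import PhenotypeRecord

__all__ = [
    "CorrelationReport",
    "growth_rates",
    "no_oxidation_rate",
    "normality_gate",
    "spearman_exact",
    "correlation_matrix",
    "category_anova",
    "phenotype_frame",
]


@dataclass(frozen=True)
class CorrelationReport:
    """Pairwise correlations among breed-level variables.

    ``rho`` and ``p`` are symmetric DataFrames indexed by variable name;
    ``normality_p`` holds the per-variable Shapiro-Wilk p-values that
    motivated the method choice.  ``q`` optionally carries Benjamini-
    Hochberg adjusted p-values (annotation only; nothing is filtered).
    """

    variables: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame
    method: str
    normality_p: dict[str, float]
    q: pd.DataFrame | None = None


def growth_rates(bw1: float, bw14: float, bw28: float) -> tuple[float, float]:
    """Growth-rate ratios (bw14/bw1, bw28/bw1)."""
    if bw1 <= 0:
        raise ValueError("day-old body weight must be positive")
    return bw14 / bw1, bw28 / bw1


def no_oxidation_rate(nod: float, nitrate: float) -> float:
    """Percent of NO metabolites oxidised to nitrate: 100*nitrate/(nod+nitrate)."""
    if nod < 0 or nitrate < 0:
        raise ValueError("concentrations must be non-negative")
    if nod + nitrate == 0:
        raise ZeroDivisionError("NO oxidation rate undefined: no metabolites")
    return 100.0 * nitrate / (nod + nitrate)


def normality_gate(
    values: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> tuple[dict[str, float], str]:
    """Shapiro-Wilk p per variable and a recommended correlation method.

    Recommends "spearman" when any variable rejects normality at ``alpha``
    (or is degenerate), "pearson" otherwise.  Constant vectors get p = nan
    and count as degenerate.
    """
    pvals: dict[str, float] = {}
    for name, vec in values.items():
        arr = np.asarray(list(vec), dtype=float)
        if len(arr) < 3:
            raise ValueError(f"variable {name!r} has fewer than 3 values")
        if np.ptp(arr) == 0:
            pvals[name] = math.nan
            continue
        pvals[name] = float(stats.shapiro(arr).pvalue)
    non_normal = any(math.isnan(p) or p < alpha for p in pvals.values())
    return pvals, ("spearman" if non_normal else "pearson")


def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with an exact two-sided permutation p-value.

    Enumerates all n! orderings of one variable (feasible for the n <= 8
    breed panels this package targets); the p-value is the fraction of
    permutations whose |rho| is at least the observed |rho|.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n = len(x)
    if n != len(y) or n < 4:
        raise ValueError("need at least 4 paired observations")
    if n > 8:
        raise ValueError("exact enumeration limited to n <= 8")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return math.nan, math.nan
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt(float(np.dot(cx, cx) * np.dot(cy, cy)))
    rho = float(np.dot(cx, cy)) / denom
    perms = _all_permutations(n)
    rho_perm = (cy[perms] @ cx) / denom
    p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return rho, p


def correlation_matrix(
    table: pd.DataFrame,
    method: str = "spearman",
    bh_adjust: bool = False,
) -> CorrelationReport:
    """Pairwise correlation matrix over the columns of a breed-level table.

    Uses exact-permutation Spearman p-values when the number of rows is
    <= 8, large-sample approximations otherwise.  All-tied variables yield
    nan for their pairs (reported as missing, not an error).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    cols = tuple(table.columns)
    n = len(table)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.full((len(cols), len(cols)), math.nan),
                     index=cols, columns=cols)
    np.fill_diagonal(p.values, 0.0)
    for a, b in itertools.combinations(cols, 2):
        x = table[a].to_numpy(dtype=float)
        y = table[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r, pv = math.nan, math.nan
        elif method == "spearman":
            if n <= 8:
                r, pv = spearman_exact(x, y)
            else:
                res = stats.spearmanr(x, y)
                r, pv = float(res.statistic), float(res.pvalue)
        else:
            res = stats.pearsonr(x, y)
            r, pv = float(res.statistic), float(res.pvalue)
        rho.loc[a, b] = rho.loc[b, a] = r
        p.loc[a, b] = p.loc[b, a] = pv
    normality_p, _ = normality_gate({c: table[c] for c in cols}) \
        if n >= 3 else ({}, method)
    q = None
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        pairs = list(itertools.combinations(cols, 2))
        raw = np.array([p.loc[a, b] for a, b in pairs])
        ok = ~np.isnan(raw)
        qvals = np.full_like(raw, math.nan)
        if ok.any():
            qvals[ok] = multipletests(raw[ok], method="fdr_bh")[1]
        q = pd.DataFrame(np.full((len(cols), len(cols)), math.nan),
                         index=cols, columns=cols)
        for (a, b), qa in zip(pairs, qvals):
            q.loc[a, b] = q.loc[b, a] = qa
    return CorrelationReport(variables=cols, rho=rho, p=p, method=method,
                             normality_p=normality_p, q=q)


def category_anova(
    values: Sequence[float], labels: Sequence[str]
) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of a breed-level variable across categories."""
    values = np.asarray(list(values), dtype=float)
    labels = list(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must align")
    groups = [values[[i for i, l in enumerate(labels) if l == g]]
              for g in dict.fromkeys(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if all(len(g) == 1 for g in groups):
        raise ValueError("all groups are singletons; no residual variance")
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def phenotype_frame(phenotypes: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    """Breed-indexed frame of raw and derived phenotype variables."""
    rows = []
    for ph in phenotypes:
        gr2, gr4 = growth_rates(ph.bw1, ph.bw14, ph.bw28)
        rows.append({
            "breed": ph.breed, "bw1": ph.bw1, "bw14": ph.bw14, "bw28": ph.bw28,
            "gr2wk": gr2, "gr4wk": gr4, "nod": ph.nod, "nitrate": ph.nitrate,
            "no_oxidation": no_oxidation_rate(ph.nod, ph.nitrate),
            "breed_type": ph.breed_type,
        })
    return pd.DataFrame(rows).set_index("breed")
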