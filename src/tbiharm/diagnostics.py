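"""Site-effect and distribution diagnostics.

Screens for outlier sites (1.5 x IQR fence rule, per voxel or pooled),
excess kurtosis, Bland-Altman agreement between site pairs, two-sample
Kolmogorov-Smirnov site tests, Kruskal-Wallis group/site effects, Cohen's d
with bootstrap significance, Fligner-Killeen variance heterogeneity, and
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OutlierReport",
    "AgreementStats",
    "outlier_screen",
    "excess_kurtosis",
    "bland_altman",
    "ks_site_pairs",
    "kruskal_effects",
    "cohens_d",
    "cohens_d_bootstrap",
    "variance_heterogeneity",
    "bh_fdr",
]


@dataclass
class OutlierReport:
    """Per-site proportion of values beyond the comparison fences."""

    proportions: dict            # site -> fraction beyond fences
    flagged: dict                # site -> bool
    k: float = 1.5
    flag_at: float = 0.05
    mode: str = "per-voxel"
    fence_definition: str = field(default=(
        "values outside [Q1 - k*IQR, Q3 + k*IQR] of the comparison "
        "distribution; quartiles by linear interpolation (type 7)"))

    @property
    def flagged_sites(self) -> list:
        return sorted(s for s, f in self.flagged.items() if f)


@dataclass
class AgreementStats:
    """Bland-Altman summary for one site pair."""

    pair: tuple
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    differences: np.ndarray | None = None
    means: np.ndarray | None = None


# ----------------------------------------------------------------------

def outlier_screen(values_by_site: dict, k: float = 1.5,
                   flag_at: float = 0.05, mode: str = "per-voxel"
                   ) -> OutlierReport:
    """Fraction of each site's values beyond 1.5 x IQR fences of the others.

    ``per-voxel`` expects per-site arrays of shape (n_scans, n_voxels) and
    computes, at each voxel, fences from the other sites' values there;
    ``pooled`` flattens everything.  Quartiles use linear interpolation
    (NumPy default, type 7).
    """
    if mode not in ("per-voxel", "pooled"):
        raise ValueError("mode must be 'per-voxel' or 'pooled'")
    sites = list(values_by_site)
    for s in sites:
        if np.asarray(values_by_site[s]).size == 0:
            raise ValueError(f"site {s!r} has no values")
    proportions = {}
    for s in sites:
        own = np.asarray(values_by_site[s], dtype=float)
        others = [np.asarray(values_by_site[t], dtype=float)
                  for t in sites if t != s]
        if not others:
            raise ValueError("outlier screen needs >= 2 sites")
        if mode == "pooled":
            comp = np.concatenate([o.ravel() for o in others])
            if comp.size < 4:
                raise ValueError("need >= 4 comparison values")
            q1, q3 = np.quantile(comp, [0.25, 0.75])
            iqr = q3 - q1
            out = (own < q1 - k * iqr) | (own > q3 + k * iqr)
            proportions[s] = float(out.mean())
        else:
            comp = np.concatenate([np.atleast_2d(o) for o in others], axis=0)
            if comp.shape[0] < 4:
                raise ValueError("need >= 4 comparison values per voxel")
            q1 = np.quantile(comp, 0.25, axis=0)
            q3 = np.quantile(comp, 0.75, axis=0)
            iqr = q3 - q1
            own2 = np.atleast_2d(own)
            out = (own2 < q1 - k * iqr) | (own2 > q3 + k * iqr)
            proportions[s] = float(out.mean())
    flagged = {s: p > flag_at for s, p in proportions.items()}
    return OutlierReport(proportions=proportions, flagged=flagged, k=k,
                         flag_at=flag_at, mode=mode)


def excess_kurtosis(values: np.ndarray, bias_corrected: bool = False) -> float:
    """Fourth standardized moment minus 3.

    Population-moment estimator by default (``fisher`` definition without
    small-sample bias correction); the bias-corrected variant is selectable.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 4:
        raise ValueError("excess kurtosis needs n >= 4")
    if values.std() == 0:
        raise ValueError("excess kurtosis undefined for zero-variance data")
    return float(stats.kurtosis(values, fisher=True, bias=not bias_corrected))


def bland_altman(a: np.ndarray, b: np.ndarray, pair: tuple = ("A", "B"),
                 keep_arrays: bool = False) -> AgreementStats:
    """Paired-difference agreement between two matched value sets."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    diff = a - b
    mean = 0.5 * (a + b)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=0))
    return AgreementStats(
        pair=tuple(pair), bias=bias, sd_diff=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        differences=diff if keep_arrays else None,
        means=mean if keep_arrays else None)


def ks_site_pairs(values_by_site: dict, fdr: bool = True) -> pd.DataFrame:
    """Two-sample KS test per unordered site pair, optional BH adjustment."""
    sites = sorted(values_by_site)
    if len(sites) < 2:
        raise ValueError("need >= 2 sites")
    for s in sites:
        if np.asarray(values_by_site[s]).ravel().size < 2:
            raise ValueError(f"site {s!r} has < 2 values")
    rows = []
    for s, t in combinations(sites, 2):
        res = stats.ks_2samp(np.asarray(values_by_site[s]).ravel(),
                             np.asarray(values_by_site[t]).ravel())
        rows.append({"site_a": s, "site_b": t,
                     "D": float(res.statistic), "p": float(res.pvalue)})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_fdr(df["p"].to_numpy()) if fdr else df["p"]
    return df


def kruskal_effects(table: pd.DataFrame, value_col: str,
                    factor: str) -> dict:
    """Kruskal-Wallis H (tie-corrected) for one factor on one value column."""
    levels = table[factor].unique()
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    groups = [table.loc[table[factor] == lv, value_col].to_numpy(dtype=float)
              for lv in levels]
    values = np.concatenate(groups)
    if np.all(values == values[0]):
        return {"factor": factor, "H": 0.0, "p": 1.0, "levels": len(levels)}
    H, p = stats.kruskal(*groups)
    return {"factor": factor, "H": float(H), "p": float(p),
            "levels": len(levels)}


def cohens_d(injured: np.ndarray, sham: np.ndarray) -> float:
    """Standardized mean difference with the pooled SD denominator."""
    injured = np.asarray(injured, dtype=float)
    sham = np.asarray(sham, dtype=float)
    n1, n2 = len(injured), len(sham)
    if n1 < 2 or n2 < 2:
        raise ValueError("each arm needs >= 2 values")
    s2 = (((n1 - 1) * injured.var(ddof=1) + (n2 - 1) * sham.var(ddof=1))
          / (n1 + n2 - 2))
    if s2 <= 0:
        raise ValueError("pooled SD is zero; d undefined")
    return float((injured.mean() - sham.mean()) / np.sqrt(s2))


def cohens_d_bootstrap(injured: np.ndarray, sham: np.ndarray,
                       n_boot: int = 10_000, alpha: float = 0.05,
                       seed: int = 0) -> dict:
    """Bootstrap CI on Cohen's d over subjects; significance = CI excludes 0."""
    rng = np.random.default_rng(seed)
    injured = np.asarray(injured, dtype=float)
    sham = np.asarray(sham, dtype=float)
    d = cohens_d(injured, sham)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bi = rng.choice(injured, size=len(injured), replace=True)
        bs = rng.choice(sham, size=len(sham), replace=True)
        s2 = (((len(bi) - 1) * bi.var(ddof=1)
               + (len(bs) - 1) * bs.var(ddof=1))
              / (len(bi) + len(bs) - 2))
        boots[b] = (bi.mean() - bs.mean()) / np.sqrt(s2) if s2 > 0 else 0.0
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return {"d": d, "ci_low": float(lo), "ci_high": float(hi),
            "significant": bool(lo > 0 or hi < 0)}


def variance_heterogeneity(values_by_site: dict) -> dict:
    """Fligner-Killeen test of equal spread across sites (robust to skew)."""
    groups = [np.asarray(v, dtype=float).ravel()
              for v in values_by_site.values()]
    if len(groups) < 2:
        raise ValueError("need >= 2 sites")
    stat, p = stats.fligner(*groups)
    return {"statistic": float(stat), "p": float(p)}


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, p_adj, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return p_adj.reshape(p.shape)
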