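"""Voxel-wise effect-size, SD and statistical-power maps.

Power for the two-sided two-sample t test at level alpha with effect size d
and group sizes (n1, n2) uses the noncentral-t distribution:
ncp = d sqrt(n1 n2 / (n1 + n2)), df = n1 + n2 - 2, and

    power = 1 - F_nct(t_crit; df, ncp) + F_nct(-t_crit; df, ncp)

with t_crit the central-t upper alpha/2 quantile — the same quantity the
common two-sample power calculators (e.g. R's pwr.t2n.test) return.  Change
maps are harmonized-minus-original differences of d, pooled SD and power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["VoxelStatMaps", "t2n_power", "voxel_stat_maps", "change_maps",
           "average_change_map"]


@dataclass
class VoxelStatMaps:
    """Cohen's d, pooled SD and power lattices for one condition."""

    d: np.ndarray
    pooled_sd: np.ndarray
    power: np.ndarray
    alpha: float
    n1: int
    n2: int
    condition: str = "original"
    valid: np.ndarray | None = None


def t2n_power(d, n1: int, n2: int, alpha: float = 0.01):
    """Power of the two-sided two-sample t test; vectorized over ``d``.

    Power is a function of |d| (the test is two-sided); power(0) = alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    d = np.abs(np.asarray(d, dtype=float))
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    # scipy's noncentral t loses accuracy at extreme ncp; fall back to the
    # standard normal approximation of the noncentral t there (power ~ 1)
    bad = ~np.isfinite(np.atleast_1d(power))
    if bad.any():
        approx = stats.norm.sf(
            (t_crit - np.atleast_1d(ncp)) / np.sqrt(1 + t_crit**2 / (2 * df)))
        power = np.where(bad, approx, np.atleast_1d(power))
        if np.isscalar(d) or d.ndim == 0:
            power = power[0]
    return power if getattr(power, "ndim", 0) else float(power)


def voxel_stat_maps(tbi_stack: np.ndarray, sham_stack: np.ndarray,
                    valid: np.ndarray | None = None, alpha: float = 0.01,
                    condition: str = "original") -> VoxelStatMaps:
    """Per-voxel Cohen's d, pooled SD and power for a TBI-vs-sham contrast."""
    tbi_stack = np.asarray(tbi_stack, dtype=float)
    sham_stack = np.asarray(sham_stack, dtype=float)
    if tbi_stack.shape[1:] != sham_stack.shape[1:]:
        raise ValueError("grid mismatch between TBI and sham stacks")
    n1, n2 = tbi_stack.shape[0], sham_stack.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each arm needs >= 2 scans")
    if valid is None:
        valid = np.ones(tbi_stack.shape[1:], dtype=bool)

    m1 = tbi_stack.mean(axis=0)
    m2 = sham_stack.mean(axis=0)
    v1 = tbi_stack.var(axis=0, ddof=1)
    v2 = sham_stack.var(axis=0, ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))

    d = np.full(tbi_stack.shape[1:], np.nan)
    ok = valid & (pooled > 0)
    d[ok] = (m1[ok] - m2[ok]) / pooled[ok]

    power = np.full(tbi_stack.shape[1:], np.nan)
    power[ok] = t2n_power(d[ok], n1, n2, alpha)
    sd_map = np.where(valid, pooled, np.nan)
    return VoxelStatMaps(d=d, pooled_sd=sd_map, power=power, alpha=alpha,
                         n1=n1, n2=n2, condition=condition, valid=ok)


def change_maps(before: VoxelStatMaps, after: VoxelStatMaps) -> VoxelStatMaps:
    """Harmonized-minus-original change maps (after - before).

    The power change is reported in percentage points on the +-100 scale.
    """
    if before.d.shape != after.d.shape:
        raise ValueError("grid mismatch between conditions")
    if before.alpha != after.alpha:
        raise ValueError("alpha differs between conditions")
    if (before.n1, before.n2) != (after.n1, after.n2):
        raise ValueError("group sizes differ between conditions")
    valid = None
    if before.valid is not None and after.valid is not None:
        valid = before.valid & after.valid
    return VoxelStatMaps(
        d=after.d - before.d,
        pooled_sd=after.pooled_sd - before.pooled_sd,
        power=100.0 * (after.power - before.power),
        alpha=before.alpha, n1=before.n1, n2=before.n2,
        condition="delta", valid=valid)


def average_change_map(per_site_changes: list[VoxelStatMaps]) -> VoxelStatMaps:
    """Unweighted across-site mean of change maps (pooled-average map)."""
    if not per_site_changes:
        raise ValueError("no change maps given")
    ref = per_site_changes[0]
    stack_d = np.nanmean([c.d for c in per_site_changes], axis=0)
    stack_sd = np.nanmean([c.pooled_sd for c in per_site_changes], axis=0)
    stack_pw = np.nanmean([c.power for c in per_site_changes], axis=0)
    return VoxelStatMaps(d=stack_d, pooled_sd=stack_sd, power=stack_pw,
                         alpha=ref.alpha, n1=ref.n1, n2=ref.n2,
                         condition="delta-average", valid=None)
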