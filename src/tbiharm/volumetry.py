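"""Sham-referenced z-maps, corrected thresholds and volumes of pathology.

An injured brain is compared voxel-wise against a sham reference: the z
statistic is (value - sham mean) / sham SD.  Because the reference mean and
SD come from a small sample, a nominal threshold z0 (default 3.1, two-sided
p0 ~ 0.00194) must be corrected for the reference size n — and corrected in
opposite directions depending on whether the test subject is outside the
reference group (injured: the statistic is sqrt((n+1)/n) times a t with
n - 1 degrees of freedom, so the corrected cutoff is *larger* than z0) or a
member of it (sham leave-in: the cutoff *deflates* below z0).  Voxels below
-z_c / above +z_c are counted into Scalar_LOW / Scalar_HIGH volumes of
pathology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ShamReference",
    "ThresholdPair",
    "PathologyVolume",
    "PAPER_THRESHOLDS",
    "build_sham_reference",
    "corrected_threshold",
    "subject_zmap",
    "pathology_volume",
    "volume_table",
    "detect_above_sham",
    "frequency_map",
]

SD_FLOOR = 1e-6   # native units; voxels below are invalid, never clamped

# Printed replication thresholds keyed by (site, day): (injured, sham).
# Shipped for replication runs against the original study's site/day grid.
PAPER_THRESHOLDS: dict = {
    (1, 3): (3.85, 2.67), (1, 30): (3.75, 2.72),
    (2, 3): (3.99, 2.61), (2, 30): (3.85, 2.67),
    (3, 3): (4.19, 2.52), (3, 30): (4.19, 2.52),
    (4, 3): (5.08, 2.38), (4, 30): (5.08, 2.38),
}


@dataclass
class ShamReference:
    """Voxel-wise sham mean/SD maps with validity bookkeeping."""

    mean: np.ndarray
    sd: np.ndarray
    n: int
    valid: np.ndarray
    scope: str = "pooled"    # "pooled" or "site-specific:<id>"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("sham reference needs n >= 2")
        if (self.sd[self.valid] < 0).any():
            raise ValueError("negative SD in sham reference")


@dataclass
class ThresholdPair:
    """Nominal and size-corrected z thresholds for one reference size."""

    z_nominal: float
    z_out_of_group: float
    z_in_group: float
    n: int
    method: str = "closed-form"

    def __post_init__(self) -> None:
        if not (self.z_in_group <= self.z_nominal <= self.z_out_of_group + 1e-9):
            raise ValueError(
                "expected z_in_group <= z_nominal <= z_out_of_group, got "
                f"{self.z_in_group:.4g} / {self.z_nominal:.4g} / "
                f"{self.z_out_of_group:.4g}")


@dataclass
class PathologyVolume:
    """Voxel counts below/above the corrected thresholds for one scan."""

    scan_id: str
    scalar: str
    low_voxels: int
    high_voxels: int
    voxel_volume_mm3: float
    extra: dict = field(default_factory=dict)

    @property
    def low_mm3(self) -> float:
        return self.low_voxels * self.voxel_volume_mm3

    @property
    def high_mm3(self) -> float:
        return self.high_voxels * self.voxel_volume_mm3


# ----------------------------------------------------------------------

def build_sham_reference(sham_scans: np.ndarray, mask: np.ndarray,
                         scope: str = "pooled") -> ShamReference:
    """Voxel-wise sample mean and SD (denominator n - 1) over sham scans."""
    sham_scans = np.asarray(sham_scans, dtype=float)
    n = sham_scans.shape[0]
    if n < 2:
        raise ValueError("need >= 2 sham scans to build a reference")
    mean = sham_scans.mean(axis=0)
    sd = sham_scans.std(axis=0, ddof=1)
    valid = mask & (sd >= SD_FLOOR)
    return ShamReference(mean=mean, sd=sd, n=n, valid=valid, scope=scope)


def two_sided_p0(z0: float) -> float:
    """Tail mass of the nominal threshold, p0 = 2 (1 - Phi(z0))."""
    return float(2.0 * stats.norm.sf(z0))


def corrected_threshold(z0: float = 3.1, n: int = 8, method: str = "closed-form",
                        tail: str = "two-sided", mc_reps: int = 2_000_000,
                        mc_tol: float = 0.02, seed: int = 0,
                        in_group_method: str = "monte-carlo",
                        override: tuple[float, float] | None = None
                        ) -> ThresholdPair:
    """Distribution-corrected z thresholds for a size-n sham reference.

    Out-of-group (injured subjects, not in the reference): closed form
    ``z_c = t^{-1}(1 - p0/2; n-1) sqrt((n+1)/n)`` with p0 the two-sided tail
    mass of z0 (``method='monte-carlo'`` replaces it with a simulation of
    the exact sampling distribution).  In-group (sham subjects, included in
    the reference mean/SD): Monte-Carlo calibration of the leave-in
    statistic, whose support is bounded by (n-1)/sqrt(n) and which deflates
    the cutoff below z0; ``in_group_method='closed-form'`` instead inverts
    the internally-studentized-residual identity (t with n-2 df), useful for
    large n where simulating whole reference cohorts is wasteful.
    ``method='override-table'`` returns the caller's (injured, sham) values,
    e.g. the original study's printed thresholds.
    """
    if method == "override-table":
        if override is None:
            raise ValueError("override-table mode needs override=(out, in)")
        return ThresholdPair(z_nominal=z0, z_out_of_group=override[0],
                             z_in_group=override[1], n=n,
                             method="override-table")
    if n < 3:
        raise ValueError("corrected thresholds need n >= 3")
    if tail == "two-sided":
        p0 = two_sided_p0(z0)
    elif tail == "one-sided":
        p0 = float(stats.norm.sf(z0))
    else:
        raise ValueError("tail must be 'two-sided' or 'one-sided'")

    rng = np.random.default_rng(seed)
    if method == "closed-form":
        z_out = float(stats.t.ppf(1.0 - p0 / 2.0, n - 1)
                      * np.sqrt((n + 1.0) / n))
    elif method == "monte-carlo":
        # exact sampling distribution: x ~ N(0,1), xbar ~ N(0,1/n),
        # s^2 ~ chi2_{n-1}/(n-1), all independent
        x = rng.standard_normal(mc_reps)
        xbar = rng.standard_normal(mc_reps) / np.sqrt(n)
        s = np.sqrt(rng.chisquare(n - 1, mc_reps) / (n - 1))
        z_out, err = _mc_quantile(np.abs((x - xbar) / s), 1.0 - p0)
        if err > mc_tol:
            raise RuntimeError(
                f"out-of-group Monte-Carlo did not reach tolerance {mc_tol}; "
                f"achieved {err:.4g} at {mc_reps} reps")
    else:
        raise ValueError(f"unknown method {method!r}")

    if in_group_method == "closed-form":
        # |x_i - xbar| / s for a member of the reference: the identity
        # T = z sqrt(n (n-2)) / sqrt((n-1)^2 - n z^2) with T ~ t_{n-2}
        # inverts to the threshold below
        t_star = stats.t.ppf(1.0 - p0 / 2.0, n - 2)
        z_in = float((n - 1.0) * t_star / np.sqrt(n * (n - 2.0 + t_star**2)))
    elif in_group_method == "monte-carlo":
        # one simulated reference cohort yields one leave-in statistic
        zin = np.empty(mc_reps)
        chunk = max(1, min(mc_reps, 4_000_000 // n))
        done = 0
        while done < mc_reps:
            m = min(chunk, mc_reps - done)
            draws = rng.standard_normal((m, n))
            zin[done:done + m] = np.abs(
                (draws[:, 0] - draws.mean(axis=1))
                / draws.std(axis=1, ddof=1))
            done += m
        z_in, err = _mc_quantile(zin, 1.0 - p0)
        if err > mc_tol:
            raise RuntimeError(
                f"in-group Monte-Carlo did not reach tolerance {mc_tol}; "
                f"achieved {err:.4g} at {len(zin)} reps")
        z_in = float(z_in)
    else:
        raise ValueError(f"unknown in_group_method {in_group_method!r}")
    return ThresholdPair(z_nominal=z0, z_out_of_group=z_out,
                         z_in_group=float(z_in), n=n, method=method)


def _mc_quantile(sample: np.ndarray, q: float) -> tuple[float, float]:
    """Empirical quantile and a density-based standard-error estimate."""
    val = float(np.quantile(sample, q))
    m = len(sample)
    # local density from a narrow quantile bracket
    dq = min(0.002, (1 - q) / 2, q / 2)
    lo, hi = np.quantile(sample, [q - dq, q + dq])
    dens = max((2 * dq) / max(hi - lo, 1e-12), 1e-12)
    se = np.sqrt(q * (1 - q) / m) / dens
    return val, float(2.0 * se)   # ~95% error bound


def subject_zmap(scan: np.ndarray, reference: ShamReference) -> np.ndarray:
    """z = (x - sham mean) / sham SD on valid voxels, NaN elsewhere."""
    scan = np.asarray(scan, dtype=float)
    if scan.shape != reference.mean.shape:
        raise ValueError(
            f"grid mismatch: scan {scan.shape} vs reference "
            f"{reference.mean.shape}")
    if not reference.valid.any():
        raise ValueError(
            "sham reference has no valid voxels (SD everywhere below floor); "
            "cannot compute a z-map")
    z = np.full(scan.shape, np.nan)
    v = reference.valid
    z[v] = (scan[v] - reference.mean[v]) / reference.sd[v]
    return z


def pathology_volume(zmap: np.ndarray, z_c: float, voxel_volume_mm3: float,
                     scan_id: str = "", scalar: str = "FA") -> PathologyVolume:
    """Count voxels strictly below -z_c (LOW) and strictly above +z_c (HIGH)."""
    if z_c <= 0:
        raise ValueError("threshold must be positive")
    valid = np.isfinite(zmap)
    low = int(np.count_nonzero(zmap[valid] < -z_c))
    high = int(np.count_nonzero(zmap[valid] > z_c))
    return PathologyVolume(scan_id=scan_id, scalar=scalar, low_voxels=low,
                           high_voxels=high, voxel_volume_mm3=voxel_volume_mm3)


def volume_table(volumes: list[PathologyVolume],
                 metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tidy TSV-ready table of pathology volumes, joined to scan metadata."""
    df = pd.DataFrame([{
        "scan_id": v.scan_id, "scalar": v.scalar,
        "low_voxels": v.low_voxels, "high_voxels": v.high_voxels,
        "low_mm3": v.low_mm3, "high_mm3": v.high_mm3,
    } for v in volumes])
    if metadata is not None:
        keep = [c for c in ("scan_id", "site", "group", "sex", "day")
                if c in metadata.columns]
        df = metadata[keep].merge(df, on="scan_id", how="right")
    return df


def detect_above_sham(injured_volumes: np.ndarray, sham_volumes: np.ndarray,
                      k: float = 2.0) -> int:
    """Count injured subjects whose volume exceeds sham mean + k sham SD."""
    sham_volumes = np.asarray(sham_volumes, dtype=float)
    injured_volumes = np.asarray(injured_volumes, dtype=float)
    if len(sham_volumes) < 2:
        raise ValueError("need >= 2 sham volumes")
    cut = sham_volumes.mean() + k * sham_volumes.std(ddof=1)
    return int(np.count_nonzero(injured_volumes > cut))


def frequency_map(zmaps: np.ndarray, alpha: float = 0.01,
                  fdr: bool = True) -> np.ndarray:
    """Per voxel, how many subjects differ from the sham mean.

    Each subject's z-map yields two-sided normal p-values; with ``fdr`` on,
    Benjamini-Hochberg is applied per subject across its valid voxels before
    thresholding at ``alpha``.  Values lie in [0, n_subjects].
    """
    zmaps = np.asarray(zmaps, dtype=float)
    if zmaps.ndim == 3:
        zmaps = zmaps[None]
    count = np.zeros(zmaps.shape[1:], dtype=np.int32)
    for z in zmaps:
        valid = np.isfinite(z)
        if not valid.any():
            continue
        p = 2.0 * stats.norm.sf(np.abs(z[valid]))
        if fdr:
            _, p, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        sig = np.zeros_like(valid)
        sig[valid] = p < alpha
        count += sig
    return count
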