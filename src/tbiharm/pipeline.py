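"""End-to-end study workflow: simulate/load -> screen -> volumetry ->
harmonize -> volumetry -> diagnostics -> voxel stat maps.

The pipeline makes the analysis order explicit: the outlier-site screen runs
first and flagged sites are (by default) excluded before any harmonization,
the sham reference is then built at the configured scope, distribution-
corrected thresholds are derived from the reference sample sizes, and
volumes of pathology are computed before and after harmonization at the
univariate (count engine) and/or voxel (continuous engine) level.  Every
artifact written is recorded in a manifest with a checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag
from . import powermaps as pm
from . import volumetry as vol
from .combat import fit_combat
from .combatseq import adjust_counts
from .design import DesignSpec
from .synthdata import CohortConfig, CountTable, MultiSiteCohort, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "site_value_samples", "site_mean_maps",
           "load_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_mode: str = "synthetic"            # {synthetic, files}
    cohort: CohortConfig | None = None       # synthetic mode
    scan_dir: str | None = None              # files mode: NIfTI dir + metadata.tsv
    scalar: str = "FA"
    sham_scope: str = "pooled"               # {pooled, site-specific}
    harmonization_level: str = "both"        # {univariate, voxel, both}
    univariate_engine: str = "nb-count"      # {nb-count, eb-continuous}
    z_nominal: float = 3.1
    alpha_univariate: float = 0.05
    alpha_voxel: float = 0.01
    detection_k: float = 2.0
    auto_exclude_outlier_sites: bool = True
    site_exclusions: tuple = ()
    ks_samples_per_site: int = 2000
    mc_reps: int = 500_000
    mc_tol: float = 0.05
    write_maps: bool = True
    outdir: str = "tbiharm_run"
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.alpha_univariate, self.alpha_voxel):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha levels must lie in (0, 1)")
        if self.input_mode not in ("synthetic", "files"):
            raise ValueError("input_mode must be 'synthetic' or 'files'")
        if self.sham_scope not in ("pooled", "site-specific"):
            raise ValueError("sham_scope must be 'pooled' or 'site-specific'")
        if self.harmonization_level not in ("univariate", "voxel", "both"):
            raise ValueError("harmonization_level must be univariate/voxel/both")
        if self.input_mode == "synthetic" and self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)


# ----------------------------------------------------------------------
# cohort access helpers

def load_cohort(scan_dir: str | Path) -> MultiSiteCohort:
    """Load a cohort from a directory of NIfTI scans plus metadata.tsv."""
    import nibabel as nib

    scan_dir = Path(scan_dir)
    meta = pd.read_csv(scan_dir / "metadata.tsv", sep="\t")
    mask_img = nib.load(scan_dir / "brain_mask.nii.gz")
    mask = np.asarray(mask_img.dataobj).astype(bool)
    voxel = float(abs(mask_img.affine[0, 0]))
    scans = np.stack([
        np.asarray(nib.load(scan_dir / f"{sid}.nii.gz").dataobj, dtype=float)
        for sid in meta["scan_id"]])
    return MultiSiteCohort(scans=scans, mask=mask, metadata=meta,
                           voxel_size_mm=voxel)


def site_value_samples(cohort: MultiSiteCohort, n_per_site: int = 2000,
                       seed: int = 0, shams_only: bool = False) -> dict:
    """Seeded iid (scan, voxel) subsamples of masked values per site.

    Sampling scans and voxels independently per site yields independent
    draws from each site's value distribution, which keeps two-sample tests
    on the samples calibrated; pooling whole scan lattices would correlate
    the samples through the shared anatomical baseline.
    """
    rng = np.random.default_rng(seed)
    vox = np.flatnonzero(cohort.mask.ravel())
    out = {}
    for site in sorted(cohort.metadata["site"].unique()):
        sel = cohort.metadata["site"] == site
        if shams_only:
            sel &= cohort.metadata["group"] == "sham"
        scans = cohort.scans[np.asarray(sel)].reshape(int(sel.sum()), -1)
        si = rng.integers(0, scans.shape[0], size=n_per_site)
        vi = vox[rng.integers(0, len(vox), size=n_per_site)]
        out[int(site)] = scans[si, vi]
    return out


def site_mean_maps(cohort: MultiSiteCohort, shams_only: bool = False) -> dict:
    """Masked per-site mean maps (voxel-matched across sites)."""
    out = {}
    for site in sorted(cohort.metadata["site"].unique()):
        sel = cohort.metadata["site"] == site
        if shams_only:
            sel &= cohort.metadata["group"] == "sham"
        out[int(site)] = cohort.scans[np.asarray(sel)].mean(axis=0)[cohort.mask]
    return out


def cohort_matrix(cohort: MultiSiteCohort) -> np.ndarray:
    """Voxels-in-mask x scans matrix for voxel-level harmonization."""
    return cohort.scans[:, cohort.mask].T.copy()


def matrix_to_cohort(matrix: np.ndarray, cohort: MultiSiteCohort
                     ) -> MultiSiteCohort:
    """Rebuild a cohort from a harmonized voxels x scans matrix."""
    scans = cohort.scans.copy()
    scans[:, cohort.mask] = matrix.T
    return MultiSiteCohort(scans=scans, mask=cohort.mask,
                           metadata=cohort.metadata.copy(),
                           voxel_size_mm=cohort.voxel_size_mm,
                           true_offsets=cohort.true_offsets,
                           true_scales=cohort.true_scales,
                           lesion_mask=cohort.lesion_mask,
                           lesion_effect=cohort.lesion_effect)


# ----------------------------------------------------------------------
# volumetry over a cohort

def cohort_volumetry(cohort: MultiSiteCohort, scope: str = "pooled",
                     z0: float = 3.1, scalar: str = "FA",
                     mc_reps: int = 500_000, mc_tol: float = 0.05,
                     seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Sham-referenced volumes of pathology for every scan.

    References and corrected thresholds are computed per day (the sham
    reference size sets the correction), pooled across sites or per site
    according to ``scope``.  Sham scans use the in-group threshold, injured
    scans the out-of-group threshold.
    """
    meta = cohort.metadata
    volumes: list[vol.PathologyVolume] = []
    thresholds: dict = {}
    days = sorted(meta["day"].unique())
    units = ([None] if scope == "pooled"
             else sorted(meta["site"].unique()))
    for day in days:
        for unit in units:
            sel_sham = (meta["day"] == day) & (meta["group"] == "sham")
            sel_all = meta["day"] == day
            if unit is not None:
                sel_sham &= meta["site"] == unit
                sel_all &= meta["site"] == unit
            sham_stack = cohort.scans[np.asarray(sel_sham)]
            ref = vol.build_sham_reference(
                sham_stack, cohort.mask,
                scope=("pooled" if unit is None else f"site-specific:{unit}"))
            pair = vol.corrected_threshold(
                z0=z0, n=ref.n, method="closed-form",
                mc_reps=mc_reps, mc_tol=mc_tol, seed=seed)
            thresholds[(day, unit)] = pair
            for i in np.flatnonzero(np.asarray(sel_all)):
                z = vol.subject_zmap(cohort.scans[i], ref)
                z_c = (pair.z_in_group
                       if meta.iloc[i]["group"] == "sham"
                       else pair.z_out_of_group)
                volumes.append(vol.pathology_volume(
                    z, z_c, cohort.voxel_volume_mm3,
                    scan_id=meta.iloc[i]["scan_id"], scalar=scalar))
    table = vol.volume_table(volumes, metadata=meta)
    return table, thresholds


def detection_counts(volumes: pd.DataFrame, k: float = 2.0) -> pd.DataFrame:
    """Injured subjects whose LOW/HIGH volume exceeds sham mean + k SD, per day."""
    rows = []
    for day in sorted(volumes["day"].unique()):
        sub = volumes[volumes["day"] == day]
        sham = sub[sub["group"] == "sham"]
        tbi = sub[sub["group"] != "sham"]
        for col, label in (("low_voxels", "low"), ("high_voxels", "high")):
            rows.append({
                "day": int(day), "measure": label,
                "n_injured": len(tbi),
                "detected": vol.detect_above_sham(
                    tbi[col].to_numpy(), sham[col].to_numpy(), k=k),
            })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_nifti(arr: np.ndarray, voxel: float, path: Path) -> None:
    import nibabel as nib

    affine = np.diag([voxel] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    summary: dict = {"config": _config_dict(config)}
    stage = "setup"
    ss = np.random.SeedSequence(config.seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    try:
        # (1) load or generate -----------------------------------------
        stage = "cohort"
        if config.input_mode == "synthetic":
            cohort = generate_cohort(config.cohort)
        else:
            cohort = load_cohort(config.scan_dir)
        meta_path = outdir / "metadata.tsv"
        cohort.metadata.to_csv(meta_path, sep="\t", index=False)
        artifacts.append(meta_path)
        summary["n_scans"] = int(len(cohort.metadata))

        # (2) outlier-site screen --------------------------------------
        stage = "outlier-screen"
        screen_vals = {
            s: cohort.site_scans(s).reshape(
                len(cohort.site_scans(s)), -1)[:, cohort.mask.ravel()]
            for s in sorted(cohort.metadata["site"].unique())}
        report = diag.outlier_screen(screen_vals, mode="per-voxel")
        kurt = {int(s): diag.excess_kurtosis(v)
                for s, v in screen_vals.items()}
        excluded = set(config.site_exclusions)
        if config.auto_exclude_outlier_sites:
            excluded |= set(report.flagged_sites)
        summary["outlier_screen"] = {
            "proportions": {int(s): p for s, p in report.proportions.items()},
            "excess_kurtosis": kurt,
            "flagged": report.flagged_sites,
            "excluded": sorted(excluded),
        }
        kept = cohort.select(~cohort.metadata["site"].isin(excluded))
        logger.info("outlier screen: flagged %s, analyzing %d scans",
                    report.flagged_sites, len(kept.metadata))

        # (3-5) pre-harmonization volumetry ----------------------------
        stage = "volumetry-pre"
        vols_pre, thr = cohort_volumetry(
            kept, scope=config.sham_scope, z0=config.z_nominal,
            scalar=config.scalar, mc_reps=config.mc_reps,
            mc_tol=config.mc_tol, seed=sub_seeds[0])
        p = outdir / "volumes_original.tsv"
        vols_pre.to_csv(p, sep="\t", index=False)
        artifacts.append(p)
        det_pre = detection_counts(vols_pre, k=config.detection_k)
        summary["thresholds"] = {
            f"day{d}" + ("" if u is None else f"_site{u}"): {
                "n": t.n, "out_of_group": round(t.z_out_of_group, 4),
                "in_group": round(t.z_in_group, 4)}
            for (d, u), t in thr.items()}
        summary["detection_original"] = det_pre.to_dict("records")

        design = DesignSpec.from_dataframe(kept.metadata)

        # (6a) univariate count harmonization --------------------------
        post_tables = {}
        if config.harmonization_level in ("univariate", "both"):
            stage = "harmonize-univariate"
            counts = CountTable(
                counts=vols_pre[["low_voxels", "high_voxels"]]
                .to_numpy().T.astype(np.int64),
                annotations=kept.metadata)
            if config.univariate_engine == "nb-count":
                adj = adjust_counts(counts, design)
                adj_counts = adj.counts
            else:
                res = fit_combat(
                    counts.counts.astype(float), design, eb=True)
                adj_counts = np.maximum(
                    np.round(res.transform()), 0).astype(np.int64)
            vols_uni = vols_pre.copy()
            vols_uni["low_voxels"] = adj_counts[0]
            vols_uni["high_voxels"] = adj_counts[1]
            vox_mm3 = kept.voxel_volume_mm3
            vols_uni["low_mm3"] = vols_uni["low_voxels"] * vox_mm3
            vols_uni["high_mm3"] = vols_uni["high_voxels"] * vox_mm3
            p = outdir / "volumes_univariate_harmonized.tsv"
            vols_uni.to_csv(p, sep="\t", index=False)
            artifacts.append(p)
            post_tables["univariate"] = vols_uni
            summary["detection_univariate"] = detection_counts(
                vols_uni, k=config.detection_k).to_dict("records")

        # (6b) voxel-level harmonization -------------------------------
        harmonized = None
        if config.harmonization_level in ("voxel", "both"):
            stage = "harmonize-voxel"
            mat = cohort_matrix(kept)
            res = fit_combat(mat, design, eb=True)
            harmonized = matrix_to_cohort(res.transform(), kept)
            stage = "volumetry-post"
            vols_vox, _ = cohort_volumetry(
                harmonized, scope=config.sham_scope, z0=config.z_nominal,
                scalar=config.scalar, mc_reps=config.mc_reps,
                mc_tol=config.mc_tol, seed=sub_seeds[1])
            p = outdir / "volumes_voxel_harmonized.tsv"
            vols_vox.to_csv(p, sep="\t", index=False)
            artifacts.append(p)
            post_tables["voxel"] = vols_vox
            summary["detection_voxel"] = detection_counts(
                vols_vox, k=config.detection_k).to_dict("records")

        # (8) diagnostics ----------------------------------------------
        stage = "diagnostics"
        diag_bundle: dict = {}
        ks_pre = diag.ks_site_pairs(site_value_samples(
            kept, config.ks_samples_per_site, seed=sub_seeds[2]))
        diag_bundle["ks_pre"] = ks_pre.to_dict("records")
        diag_bundle["ks_mean_p_pre"] = float(ks_pre["p"].mean())
        maps_pre = site_mean_maps(kept)
        ba_pre = {f"{a}-{b}": diag.bland_altman(maps_pre[a], maps_pre[b],
                                                pair=(a, b)).bias
                  for a in maps_pre for b in maps_pre if a < b}
        diag_bundle["bland_altman_bias_pre"] = ba_pre
        if harmonized is not None:
            ks_post = diag.ks_site_pairs(site_value_samples(
                harmonized, config.ks_samples_per_site, seed=sub_seeds[2]))
            diag_bundle["ks_post"] = ks_post.to_dict("records")
            diag_bundle["ks_mean_p_post"] = float(ks_post["p"].mean())
            maps_post = site_mean_maps(harmonized)
            diag_bundle["bland_altman_bias_post"] = {
                f"{a}-{b}": diag.bland_altman(maps_post[a], maps_post[b],
                                              pair=(a, b)).bias
                for a in maps_post for b in maps_post if a < b}

        def _kw_block(table: pd.DataFrame) -> dict:
            out = {}
            pvals, keys = [], []
            for day in sorted(table["day"].unique()):
                sub = table[table["day"] == day]
                for col in ("low_voxels", "high_voxels"):
                    for factor in ("group", "site"):
                        r = diag.kruskal_effects(sub, col, factor)
                        key = f"day{day}_{col}_{factor}"
                        out[key] = r
                        keys.append(key)
                        pvals.append(r["p"])
            adj = diag.bh_fdr(np.asarray(pvals))
            for k_, a_ in zip(keys, adj):
                out[k_]["p_adj"] = float(a_)
            return out

        diag_bundle["kruskal_original"] = _kw_block(vols_pre)
        for level, table in post_tables.items():
            diag_bundle[f"kruskal_{level}"] = _kw_block(table)

        # per-site/day effect sizes on LOW volumes
        effects = []
        for cond, table in [("original", vols_pre)] + list(post_tables.items()):
            for day in sorted(table["day"].unique()):
                sub = table[table["day"] == day]
                sham_pool = sub.loc[sub["group"] == "sham", "low_voxels"]
                for site in sorted(sub["site"].unique()):
                    tbi = sub[(sub["site"] == site) & (sub["group"] != "sham")]
                    try:
                        d = diag.cohens_d(tbi["low_voxels"].to_numpy(),
                                          sham_pool.to_numpy())
                    except ValueError:
                        d = float("nan")
                    effects.append({"condition": cond, "day": int(day),
                                    "site": int(site), "cohens_d": d})
        diag_bundle["effect_sizes_low"] = effects
        p = outdir / "diagnostics.json"
        p.write_text(json.dumps(diag_bundle, indent=1, default=float))
        artifacts.append(p)
        summary["diagnostics"] = {
            k: diag_bundle[k] for k in
            ("ks_mean_p_pre", "ks_mean_p_post") if k in diag_bundle}

        # (9) voxel stat maps and change maps --------------------------
        if harmonized is not None and config.write_maps:
            stage = "stat-maps"
            mapdir = outdir / "maps"
            mapdir.mkdir(exist_ok=True)
            for day in sorted(kept.metadata["day"].unique()):
                meta = kept.metadata
                tbi_sel = np.asarray((meta["day"] == day)
                                     & (meta["group"] != "sham"))
                sham_sel = np.asarray((meta["day"] == day)
                                      & (meta["group"] == "sham"))
                before = pm.voxel_stat_maps(
                    kept.scans[tbi_sel], kept.scans[sham_sel],
                    valid=kept.mask, alpha=config.alpha_voxel,
                    condition="original")
                after = pm.voxel_stat_maps(
                    harmonized.scans[tbi_sel], harmonized.scans[sham_sel],
                    valid=kept.mask, alpha=config.alpha_voxel,
                    condition="harmonized")
                delta = pm.change_maps(before, after)
                for cond, maps in (("original", before),
                                   ("harmonized", after), ("delta", delta)):
                    for qty in ("d", "pooled_sd", "power"):
                        path = mapdir / f"{qty}_{cond}_day{day:02d}.nii.gz"
                        _write_nifti(getattr(maps, qty),
                                     kept.voxel_size_mm, path)
                        artifacts.append(path)
                    sidecar = mapdir / f"sidecar_{cond}_day{day:02d}.json"
                    sidecar.write_text(json.dumps({
                        "alpha": maps.alpha, "n1": maps.n1, "n2": maps.n2,
                        "scalar": config.scalar, "condition": cond,
                        "day": int(day)}))
                    artifacts.append(sidecar)

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\n{exc!r}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    # manifest ---------------------------------------------------------
    summary["elapsed_s"] = round(time.time() - t0, 2)
    manifest = {
        "summary": summary,
        "artifacts": [{"path": str(p.relative_to(outdir)),
                       "sha256": _sha256(p)} for p in artifacts],
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=float))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if d.get("cohort") is not None:
        d["cohort"]["day_effect"] = {
            int(k): float(v) for k, v in d["cohort"]["day_effect"].items()}
    return d


def run_config_from_yaml(path: str | Path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "cohort" in d and d["cohort"] is not None:
        d["cohort"] = CohortConfig(**d["cohort"])
    if "site_exclusions" in d:
        d["site_exclusions"] = tuple(d["site_exclusions"])
    return RunConfig(**d)
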