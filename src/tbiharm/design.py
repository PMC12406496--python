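"""Batch/covariate design handling shared by the harmonization engines.

The harmonization models condition on biological covariates while treating
site as the batch variable.  ``DesignSpec`` owns the encoding conventions:
categorical covariates (group, sex) are one-hot encoded with the first level
dropped; continuous covariates (atrophy in mm^3, day post-injury in days) are
centered and scaled internally so that small multi-site cohorts stay well
conditioned, and the stored center/scale allow back-transformation in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignSpec", "RankDeficientDesignError"]


class RankDeficientDesignError(ValueError):
    """Raised when batch indicators plus covariates are collinear."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(columns)
        )


@dataclass
class DesignSpec:
    """Per-sample batch labels and encoded covariates.

    Parameters
    ----------
    batch : array-like of shape (n_samples,)
        Batch (site) label per sample.  Any hashable labels.
    covariates : ndarray of shape (n_samples, n_cov)
        Encoded covariate matrix (no intercept column).
    covariate_names : list of str
        One name per covariate column.
    continuous_center, continuous_scale : dict
        Center/scale used for standardized continuous columns, keyed by name.
    """

    batch: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    continuous_center: dict = field(default_factory=dict)
    continuous_scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.batch = np.asarray(self.batch)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.size == 0:
            self.covariates = np.empty((len(self.batch), 0))
        if self.covariates.shape[0] != len(self.batch):
            raise ValueError(
                f"covariate rows ({self.covariates.shape[0]}) != "
                f"batch labels ({len(self.batch)})"
            )
        self.levels, self.batch_idx = np.unique(self.batch, return_inverse=True)
        self.n_per_batch = np.bincount(self.batch_idx)
        if (self.n_per_batch < 2).any():
            bad = self.levels[self.n_per_batch < 2]
            raise ValueError(
                f"every batch needs >= 2 samples; offending batch(es): {list(bad)}"
            )
        self._check_rank()

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.batch)

    @property
    def n_batches(self) -> int:
        return len(self.levels)

    def batch_onehot(self) -> np.ndarray:
        """One indicator column per batch (no reference level dropped)."""
        out = np.zeros((self.n_samples, self.n_batches))
        out[np.arange(self.n_samples), self.batch_idx] = 1.0
        return out

    def full_matrix(self) -> np.ndarray:
        """[batch indicators | covariates], the fitting design."""
        return np.hstack([self.batch_onehot(), self.covariates])

    def _check_rank(self) -> None:
        mat = self.full_matrix()
        rank = np.linalg.matrix_rank(mat)
        if rank < mat.shape[1]:
            # name offending columns via pivoted QR on the covariate block
            names = [f"batch[{lv}]" for lv in self.levels] + list(self.covariate_names)
            _, r = np.linalg.qr(mat)
            diag = np.abs(np.diag(r))
            tol = diag.max() * max(mat.shape) * np.finfo(float).eps
            bad = [names[j] for j in range(len(diag)) if diag[j] <= tol]
            if not bad:  # fallback: report covariate block wholesale
                bad = list(self.covariate_names)
            raise RankDeficientDesignError(bad)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        meta: pd.DataFrame,
        batch_col: str = "site",
        categorical: tuple[str, ...] = ("group", "sex"),
        continuous: tuple[str, ...] = ("atrophy", "day"),
    ) -> "DesignSpec":
        """Build a design from a tidy metadata table.

        Categorical columns are one-hot encoded dropping the first sorted
        level; continuous columns are standardized (centered and scaled by
        the sample SD; scale 1 is used for constant columns, which are then
        dropped to keep the design full rank).
        """
        cols: list[np.ndarray] = []
        names: list[str] = []
        center: dict = {}
        scale: dict = {}
        for c in categorical:
            if c not in meta:
                continue
            lv = np.unique(np.asarray(meta[c]))
            for level in lv[1:]:
                cols.append((np.asarray(meta[c]) == level).astype(float))
                names.append(f"{c}[{level}]")
        for c in continuous:
            if c not in meta:
                continue
            x = np.asarray(meta[c], dtype=float)
            mu = float(x.mean())
            sd = float(x.std(ddof=0))
            if sd <= 0:
                continue  # constant column carries no information
            center[c] = mu
            scale[c] = sd
            cols.append((x - mu) / sd)
            names.append(c)
        cov = np.column_stack(cols) if cols else np.empty((len(meta), 0))
        return cls(
            batch=np.asarray(meta[batch_col]),
            covariates=cov,
            covariate_names=names,
            continuous_center=center,
            continuous_scale=scale,
        )

    def subset(self, idx: np.ndarray) -> "DesignSpec":
        """Design restricted to the given sample indices."""
        return DesignSpec(
            batch=self.batch[idx],
            covariates=self.covariates[idx],
            covariate_names=list(self.covariate_names),
            continuous_center=dict(self.continuous_center),
            continuous_scale=dict(self.continuous_scale),
        )
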