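"""Euclidean applicability domain: APD = d_bar + Z * sigma.

The domain threshold is fitted on the z-scored training descriptors: all
pairwise Euclidean distances are computed, those no greater than their grand
mean are retained, and d_bar / sigma are the mean and population standard
deviation of the retained set. A query compound is in-domain when its
nearest-training-neighbour distance (in the same scaled space) does not
exceed APD. Z defaults to the study's empirical cutoff of 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .chem_io import DescriptorMatrix

__all__ = ["DomainModel", "fit_apd", "in_domain"]


@dataclass
class DomainModel:
    d_bar: float
    sigma: float
    z: float
    apd: float
    scaled_train: np.ndarray  # training matrix after column filtering/scaling
    mean_: np.ndarray | None  # per-descriptor training mean (None if unscaled)
    sd_: np.ndarray | None
    kept_columns: np.ndarray  # boolean mask over the original descriptor columns

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.z >= 0 and self.apd < self.d_bar - 1e-12:
            raise ValueError("apd must be >= d_bar for non-negative Z")


def fit_apd(
    train_X: DescriptorMatrix | np.ndarray,
    z: float = 0.5,
    *,
    scale: bool = True,
    retain: str = "below_mean",
) -> DomainModel:
    """Fit the applicability-domain threshold on a training descriptor matrix.

    Parameters
    ----------
    train_X
        Training descriptors (rows = compounds); needs >= 2 rows.
    z
        Empirical cutoff multiplier (study default 0.5).
    scale
        Z-score each descriptor on training mean/SD before any distance.
        Zero-variance descriptors are dropped with a warning. Disable only
        for descriptors already on a common scale.
    retain
        ``"below_mean"`` (default): d_bar and sigma come from the pairwise
        distances no greater than their grand mean. ``"all"``: use every
        pairwise distance.
    """
    X = train_X.values if isinstance(train_X, DescriptorMatrix) else np.asarray(
        train_X, dtype=float
    )
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_apd needs a 2-D matrix with >= 2 training compounds")
    if retain not in {"below_mean", "all"}:
        raise ValueError(f"unknown retain mode: {retain!r}")

    mean = sd = None
    kept = np.ones(X.shape[1], dtype=bool)
    if scale:
        sd_all = X.std(axis=0)
        kept = sd_all > 0
        if not kept.all():
            warnings.warn(
                f"dropping {int((~kept).sum())} zero-variance descriptors "
                "before domain fitting",
                stacklevel=2,
            )
        X = X[:, kept]
        mean, sd = X.mean(axis=0), X.std(axis=0)
        X = (X - mean) / sd if X.shape[1] else X

    dists = pdist(X) if X.shape[1] else np.zeros(X.shape[0] * (X.shape[0] - 1) // 2)
    if retain == "below_mean":
        retained = dists[dists <= dists.mean()] if dists.size else dists
    else:
        retained = dists
    d_bar = float(retained.mean()) if retained.size else 0.0
    sigma = float(retained.std()) if retained.size else 0.0  # population SD
    return DomainModel(
        d_bar=d_bar,
        sigma=sigma,
        z=z,
        apd=d_bar + z * sigma,
        scaled_train=X,
        mean_=mean,
        sd_=sd,
        kept_columns=kept,
    )


def in_domain(
    model: DomainModel, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Flag query compounds as inside/outside the applicability domain.

    ``x`` is one descriptor vector or a matrix of them, in the *original*
    (unscaled, unfiltered) descriptor space used to fit the model. Returns
    ``(flags, nn_distances)``: a compound is in-domain when its distance to
    the nearest training compound is <= APD (boundary inclusive).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.kept_columns.size:
        raise ValueError(
            f"descriptor vector length {x.shape[1]} does not match "
            f"training space {model.kept_columns.size}"
        )
    x = x[:, model.kept_columns]
    if model.mean_ is not None:
        x = (x - model.mean_) / model.sd_
    nn = cdist(x, model.scaled_train).min(axis=1) if x.shape[1] else np.zeros(len(x))
    return nn <= model.apd, nn
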