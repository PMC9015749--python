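"""Gaussian-mixture segmentation of binary activity vectors.

Both the 32-slot sleep-cycle vectors and the 48-slot daily vectors are
clustered the same way: a diagonal-covariance Gaussian mixture is fit
for each candidate number of components and the model minimizing BIC is
kept (ties go to the smaller k).  Each record is hard-assigned to its
maximum-posterior component, and each non-empty component yields a
binary pattern by thresholding per-slot mean activation at > 0.5, with
a weight equal to its assigned fraction of records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .errors import DataError

#: variance floor for the diagonal covariances.  The inputs are binary,
#: so without a floor components collapse to near-zero variance and BIC
#: rewards carving sparse false activations into their own components,
#: which fragments the real activity patterns.  A floor of 0.1 (binary
#: variance is at most 0.25) suppresses that over-segmentation while
#: leaving well-separated archetypes clearly distinguishable.
DEFAULT_REG_COVAR = 0.1


@dataclass
class ClusterModel:
    """Fitted mixture with hard assignments and model-selection trace."""

    k: int
    means: np.ndarray  # (k, d)
    variances: np.ndarray  # (k, d)
    mixing: np.ndarray  # (k,)
    labels: np.ndarray  # (n,) component index per record
    bic_by_k: dict[int, float] = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class ClusterPattern:
    """Binary per-slot template of one cluster and its record share."""

    slots: np.ndarray
    weight: float


def fit_vector_clusters(
    X: np.ndarray,
    k_max: int = 6,
    seed: int = 0,
    min_records: int = 10,
    reg_covar: float = DEFAULT_REG_COVAR,
) -> ClusterModel | None:
    """Fit and select a Gaussian mixture on binary row vectors.

    Returns ``None`` when fewer than ``min_records`` rows are available
    (the caller excludes the household from the stratum).  Deterministic
    for a fixed ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError("expected a 2-D record matrix")
    n = X.shape[0]
    if n < min_records:
        return None
    best: GaussianMixture | None = None
    best_bic = np.inf
    bic_by_k: dict[int, float] = {}
    for k in range(1, min(k_max, n) + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            reg_covar=reg_covar,
            random_state=seed,
            max_iter=200,
            n_init=1,
        )
        with warnings.catch_warnings():
            # duplicate binary rows routinely collapse k-means init clusters
            warnings.simplefilter("ignore", ConvergenceWarning)
            gm.fit(X)
        bic = gm.bic(X)
        bic_by_k[k] = float(bic)
        if bic < best_bic:  # strict: ties keep the smaller k
            best_bic = bic
            best = gm
    assert best is not None
    labels = best.predict(X)
    return ClusterModel(
        k=best.n_components,
        means=best.means_,
        variances=best.covariances_,
        mixing=best.weights_,
        labels=labels,
        bic_by_k=bic_by_k,
        seed=seed,
    )


def extract_pattern(member_rows: np.ndarray, weight: float) -> ClusterPattern:
    """Binary template of one cluster: slot active iff mean activation > 0.5.

    The threshold is strict, so a 50/50 split is inactive.
    """
    member_rows = np.asarray(member_rows, dtype=float)
    if member_rows.ndim != 2 or member_rows.shape[0] < 1:
        raise DataError("cluster needs >= 1 member record")
    slots = (member_rows.mean(axis=0) > 0.5).astype(np.uint8)
    return ClusterPattern(slots=slots, weight=float(weight))


def cluster_patterns(X: np.ndarray, model: ClusterModel) -> list[ClusterPattern]:
    """Patterns of all non-empty components; weights sum to 1."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    out = []
    for comp in range(model.k):
        mask = model.labels == comp
        count = int(mask.sum())
        if count == 0:
            continue
        out.append(extract_pattern(X[mask], count / n))
    return out
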