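"""Principal component analysis of stacked stance waveforms.

Each row of the data matrix X (m x 100) is one subject x speed averaged
stance curve in BW.  Column means are removed and X is decomposed by SVD
into orthonormal loading vectors (100-point waveform directions), scores
Z = (X - mean) @ loadings.T, and per-component variance fractions; no
unit-variance scaling is applied because all columns share BW units.

Each retained component is visualized as a pair of limit curves,

    upper = mean + SD(z_k) * loading_k,   lower = mean - SD(z_k) * loading_k,

i.e. the mean waveform displaced one between-observation standard
deviation along the component, and the stance-percent regions where the
upper limit clears the lower (and vice versa) summarize where on stance
the mode acts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import GroupingError, ParameterError
from .preprocess import N_STANCE_POINTS, StanceCurve

#: Relative threshold below which total variance counts as zero (degenerate).
_DEGENERATE_REL_VAR = 1e-24


@dataclass
class WaveformMatrix:
    """m x 100 stacked stance curves of one sex and channel, with row labels."""

    X: np.ndarray
    row_meta: pd.DataFrame  # columns subject_id, sex, speed
    channel: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != N_STANCE_POINTS:
            raise GroupingError(
                f"waveform matrix must have {N_STANCE_POINTS} columns"
            )
        if self.X.shape[0] < 2:
            raise GroupingError("waveform matrix needs at least 2 rows")
        if len(self.row_meta) != self.X.shape[0]:
            raise GroupingError("row_meta length does not match X")

    @property
    def m(self) -> int:
        return self.X.shape[0]


def build_matrix(
    curves: Sequence[StanceCurve], sex: str, channel: str
) -> WaveformMatrix:
    """Stack one averaged curve per subject x speed for one sex and channel.

    Rows are ordered by (speed, subject_id) regardless of input order, so
    the matrix is a pure function of the curve set.  Duplicate
    subject x speed entries are a :class:`GroupingError`.
    """
    selected = [c for c in curves if c.sex == sex and c.channel == channel]
    if not selected:
        raise GroupingError(f"no curves for sex={sex!r} channel={channel!r}")
    keys = [(c.speed, c.subject_id) for c in selected]
    if len(set(keys)) != len(keys):
        raise GroupingError("duplicate subject x speed rows")
    order = np.lexsort(
        (np.array([k[1] for k in keys]), np.array([k[0] for k in keys]))
    )
    selected = [selected[i] for i in order]
    X = np.vstack([c.values for c in selected])
    meta = pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in selected],
            "sex": [c.sex for c in selected],
            "speed": [c.speed for c in selected],
        }
    )
    return WaveformMatrix(X=X, row_meta=meta, channel=channel)


def _canonicalize_signs(components: np.ndarray) -> np.ndarray:
    """Sign vector flipping each loading so its largest-|.| element is > 0.

    Ties on |.| break toward the earliest index (np.argmax convention).
    """
    idx = np.argmax(np.abs(components), axis=1)
    picked = components[np.arange(components.shape[0]), idx]
    signs = np.where(picked < 0, -1.0, 1.0)
    return signs


@dataclass
class PCReconstruction:
    """±SD limit curves of one principal component and their regions."""

    pc_index: int  # 1-based
    mean: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    score_sd: float
    variance_fraction: float
    regions_upper_over_lower: list = field(default_factory=list)
    regions_lower_over_upper: list = field(default_factory=list)


class WaveformPCA(TransformerMixin, BaseEstimator):
    """PCA of stance waveforms with ±SD limit-curve reconstruction.

    Parameters
    ----------
    coverage : float
        Cumulative variance fraction the retained components must reach.
    k_max : int
        Hard cap on the number of retained components (the analysis
        convention is 4, covering > 95% of variance in practice).

    Attributes
    ----------
    mean_ : ndarray of shape (n_features,)
        Column means of the training matrix (the mean stance curve).
    components_ : ndarray of shape (n_components_, n_features)
        Orthonormal loading vectors, sign-canonicalized so the largest
        absolute element of each is positive.
    explained_variance_ : ndarray
        Per-component sample variances of the scores (m-1 denominator).
    explained_variance_ratio_ : ndarray
        Variance fractions over all non-null components; sums to 1.
    scores_ : ndarray of shape (m, n_components_)
        Training-row scores Z = (X - mean_) @ components_.T.
    n_components_ : int
        Number of components kept in the model, min(m-1, n_features);
        0 for a degenerate (zero-variance) matrix.
    n_retained_ : int
        Smallest k whose cumulative variance fraction reaches
        ``coverage``, capped at ``k_max``.
    coverage_achieved_ : float
        Cumulative variance fraction of the retained components.
    residual_q_ : ndarray of shape (m,)
        Per-row squared reconstruction residual using the retained k.
    """

    def __init__(self, coverage: float = 0.95, k_max: int = 4):
        self.coverage = coverage
        self.k_max = k_max

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ParameterError("X must be 2-d with at least 2 rows")
        if not np.all(np.isfinite(X)):
            raise ParameterError("X must be finite")
        m, n = X.shape
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        total_var = float(np.sum(Xc**2))
        scale = float(np.sum(X**2)) + 1.0
        if total_var <= _DEGENERATE_REL_VAR * scale:
            # identical rows: the mean carries everything, no modes exist
            self.components_ = np.empty((0, n))
            self.explained_variance_ = np.empty(0)
            self.explained_variance_ratio_ = np.empty(0)
            self.singular_values_ = np.empty(0)
            self.scores_ = np.empty((m, 0))
            self.n_components_ = 0
            self.n_retained_ = 0
            self.coverage_achieved_ = 1.0
            self.residual_q_ = np.zeros(m)
            self.n_features_in_ = n
            return self

        p = min(m - 1, n)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        U, S, Vt = U[:, :p], S[:p], Vt[:p]
        signs = _canonicalize_signs(Vt)
        Vt = Vt * signs[:, None]
        U = U * signs[None, :]

        self.components_ = Vt
        self.singular_values_ = S
        self.explained_variance_ = S**2 / (m - 1)
        self.explained_variance_ratio_ = S**2 / np.sum(S**2)
        self.scores_ = U * S
        self.n_components_ = p
        self.n_retained_ = select_components(
            self.explained_variance_ratio_, self.coverage, self.k_max
        )
        self.coverage_achieved_ = float(
            np.sum(self.explained_variance_ratio_[: self.n_retained_])
        )
        k = self.n_retained_
        recon = self.scores_[:, :k] @ self.components_[:k]
        self.residual_q_ = np.sum((Xc - recon) ** 2, axis=1)
        self.n_features_in_ = n
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, Z):
        check_is_fitted(self, "mean_")
        Z = np.asarray(Z, dtype=float)
        k = Z.shape[-1]
        return Z @ self.components_[:k] + self.mean_

    # -- limit curves -------------------------------------------------------

    def score_sd(self, pc_index: int) -> float:
        """Sample SD (m-1 denominator) of the scores of one 1-based PC."""
        check_is_fitted(self, "mean_")
        if not 1 <= pc_index <= self.n_components_:
            raise ParameterError(
                f"pc_index must be in 1..{self.n_components_}, got {pc_index}"
            )
        return float(np.std(self.scores_[:, pc_index - 1], ddof=1))

    def reconstruct_limits(self, pc_index: int) -> PCReconstruction:
        """Mean ± SD(score) * loading limit curves of one 1-based PC."""
        sd = self.score_sd(pc_index)
        g = self.components_[pc_index - 1]
        return PCReconstruction(
            pc_index=pc_index,
            mean=self.mean_.copy(),
            upper=self.mean_ + sd * g,
            lower=self.mean_ - sd * g,
            score_sd=sd,
            variance_fraction=float(
                self.explained_variance_ratio_[pc_index - 1]
            ),
        )


def fit_pca(matrix: WaveformMatrix | np.ndarray, coverage: float = 0.95,
            k_max: int = 4) -> WaveformPCA:
    """Fit a :class:`WaveformPCA` on a waveform matrix (or bare array)."""
    X = matrix.X if isinstance(matrix, WaveformMatrix) else matrix
    return WaveformPCA(coverage=coverage, k_max=k_max).fit(X)


def select_components(
    variance_fractions: np.ndarray, coverage: float = 0.95, k_max: int = 4
) -> int:
    """Smallest k with cumulative variance fraction >= coverage, capped.

    If even ``k_max`` components do not reach the coverage, ``k_max`` is
    returned (the achieved coverage is then below target and should be
    reported alongside).
    """
    fractions = np.asarray(variance_fractions, dtype=float)
    if fractions.size == 0:
        return 0
    cum = np.cumsum(fractions)
    reached = np.flatnonzero(cum >= coverage - 1e-12)
    k = int(reached[0]) + 1 if reached.size else fractions.size
    return min(k, k_max)


def extract_regions(
    rec: PCReconstruction, epsilon: float = 0.05
) -> PCReconstruction:
    """Stance-percent intervals where one limit clears the other.

    The separation d = upper - lower (= 2 SD * loading) is thresholded at
    ``epsilon`` times its maximum absolute value; maximal runs of points
    with d above (below minus) the threshold are reported as inclusive
    [start%, end%] intervals.  ``epsilon=0`` gives raw sign runs.
    """
    d = rec.upper - rec.lower
    dmax = float(np.max(np.abs(d)))
    if dmax == 0.0:
        return replace(rec, regions_upper_over_lower=[], regions_lower_over_upper=[])
    eps_abs = epsilon * dmax
    return replace(
        rec,
        regions_upper_over_lower=_runs(d > eps_abs),
        regions_lower_over_upper=_runs(-d > eps_abs),
    )


def _runs(mask: np.ndarray) -> list[list[int]]:
    """Maximal runs of True as inclusive [start, end] index pairs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [[int(s), int(e) - 1] for s, e in zip(edges[0::2], edges[1::2])]
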