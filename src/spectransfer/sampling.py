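"""Sample-set partitioning (SPXY) and master/slave spectral diagnostics.

SPXY (sample-set partitioning based on joint X-Y distances) selects a
representative training set by a greedy max-min rule on the joint distance

    d_ij = d_X(i, j) / max d_X  +  d_y(i, j) / max d_y

with Euclidean distances in both spaces; categorical labels enter through
one-hot encoding.  The standard set used to estimate a calibration-transfer
map is the SPXY-order prefix of the training set, so standard sets of
increasing size are nested.

Transfer quality between paired master/slave spectra is diagnosed by the
mean spectral angle (degrees)

    theta_i = arccos( <M_i, S_i> / (||M_i|| ||S_i||) )

and the mean per-sample Pearson correlation across wavelengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SplitResult",
    "TransferDiagnostics",
    "spxy_split",
    "select_standard_samples",
    "spectral_angle",
    "spectral_correlation",
    "size_standard_set",
]


@dataclass
class SplitResult:
    """SPXY partition of a sample set.

    ``train_indices`` are stored in SPXY *selection order*;
    ``standard_indices`` (when set) are a prefix of that order.
    """

    train_indices: np.ndarray
    prediction_indices: np.ndarray
    standard_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.prediction_indices = np.asarray(self.prediction_indices, dtype=int)
        if np.intersect1d(self.train_indices, self.prediction_indices).size:
            raise ValueError("train and prediction sets must be disjoint")
        if self.standard_indices is not None:
            self.standard_indices = np.asarray(self.standard_indices, dtype=int)
            if not np.isin(self.standard_indices, self.train_indices).all():
                raise ValueError("standard set must be a subset of the training set")


@dataclass
class TransferDiagnostics:
    """Per-sample and mean spectral angle / correlation between paired sets."""

    per_sample_angles_deg: np.ndarray | None = None
    mean_angle_deg: float | None = None
    per_sample_correlations: np.ndarray | None = None
    mean_correlation: float | None = None

    @classmethod
    def compare(cls, M, S) -> "TransferDiagnostics":
        ang = spectral_angle(M, S)
        cor = spectral_correlation(M, S)
        return cls(
            ang.per_sample_angles_deg,
            ang.mean_angle_deg,
            cor.per_sample_correlations,
            cor.mean_correlation,
        )


def _label_distance_matrix(y: np.ndarray) -> np.ndarray:
    """Euclidean y-distances: raw for float-valued y, one-hot for labels."""
    y = np.asarray(y)
    if y.ndim == 1 and np.issubdtype(y.dtype, np.floating):
        return squareform(pdist(y[:, None]))
    classes, codes = np.unique(y, return_inverse=True)
    onehot = np.eye(classes.size)[codes]
    return squareform(pdist(onehot))


def spxy_split(X, y, n_train: int) -> SplitResult:
    """Greedy SPXY max-min selection of ``n_train`` training samples.

    The first two selections are the pair with the largest joint distance;
    each subsequent selection maximises its minimum joint distance to the
    already-selected set.  Ties break to the lowest sample index.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if not 2 <= n_train < m:
        raise ValueError("need 2 <= n_train < number of samples")
    d_x = squareform(pdist(X))
    d_y = _label_distance_matrix(np.asarray(y))
    max_x, max_y = d_x.max(), d_y.max()
    if max_x == 0:
        warnings.warn("all rows of X are identical; SPXY falls back to index order")
    d = (d_x / max_x if max_x > 0 else d_x) + (d_y / max_y if max_y > 0 else d_y)
    i0, j0 = np.unravel_index(np.argmax(d), d.shape)  # first max: lowest indices
    selected = [int(min(i0, j0)), int(max(i0, j0))]
    remaining = np.ones(m, dtype=bool)
    remaining[selected] = False
    min_d = d[:, selected].min(axis=1)
    while len(selected) < n_train:
        cand = np.where(remaining, min_d, -np.inf)
        nxt = int(np.argmax(cand))
        selected.append(nxt)
        remaining[nxt] = False
        min_d = np.minimum(min_d, d[:, nxt])
    train = np.array(selected)
    pred = np.setdiff1d(np.arange(m), train)
    return SplitResult(train, pred)


def select_standard_samples(split: SplitResult, k: int) -> np.ndarray:
    """First ``k`` training samples in SPXY selection order (nested in k)."""
    if not 1 <= k <= split.train_indices.size:
        raise ValueError(f"k must be in [1, {split.train_indices.size}]")
    return split.train_indices[:k].copy()


def _as_matrix(M) -> np.ndarray:
    spectra = getattr(M, "spectra", M)
    return np.atleast_2d(np.asarray(spectra, dtype=float))


def spectral_angle(M, S) -> TransferDiagnostics:
    """Row-wise spectral angles (degrees) between paired spectra sets."""
    M, S = _as_matrix(M), _as_matrix(S)
    if M.shape != S.shape:
        raise ValueError("M and S must have the same shape")
    nm, ns = np.linalg.norm(M, axis=1), np.linalg.norm(S, axis=1)
    for name, n in (("M", nm), ("S", ns)):
        if np.any(n == 0):
            row = int(np.argmax(n == 0))
            raise ValueError(f"zero-norm spectrum in {name} at row {row}")
    cosines = np.clip(np.einsum("ij,ij->i", M, S) / (nm * ns), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosines))
    return TransferDiagnostics(ang, float(ang.mean()))


def spectral_correlation(M, S) -> TransferDiagnostics:
    """Row-wise Pearson correlations across wavelengths.

    Values are reported untruncated: anti-correlated spectra yield negative
    r even though a well-transferred pair should approach +1.
    """
    M, S = _as_matrix(M), _as_matrix(S)
    if M.shape != S.shape:
        raise ValueError("M and S must have the same shape")
    Mc = M - M.mean(axis=1, keepdims=True)
    Sc = S - S.mean(axis=1, keepdims=True)
    nm, ns = np.linalg.norm(Mc, axis=1), np.linalg.norm(Sc, axis=1)
    for name, n in (("M", nm), ("S", ns)):
        if np.any(n == 0):
            row = int(np.argmax(n == 0))
            raise ValueError(f"zero-variance spectrum in {name} at row {row}")
    r = np.clip(np.einsum("ij,ij->i", Mc, Sc) / (nm * ns), -1.0, 1.0)
    return TransferDiagnostics(None, None, r, float(r.mean()))


def size_standard_set(
    Xm_std_candidates,
    Xs_std_candidates,
    transfer_factory,
    k_grid,
    Xm_eval,
    Xs_eval,
) -> tuple[pd.DataFrame, int]:
    """Mean spectral angle on held-out data versus standard-set size.

    For each ``k`` the transfer is fitted on the first ``k`` candidate
    standards (SPXY order) and evaluated as the mean angle between the
    held-out master spectra and the transformed held-out slave spectra.
    Fit failures are recorded as NaN.  Returns the table and the argmin k.
    """
    Xm_std = _as_matrix(Xm_std_candidates)
    Xs_std = _as_matrix(Xs_std_candidates)
    rows = []
    for k in k_grid:
        if k > Xm_std.shape[0]:
            rows.append((k, np.nan))
            continue
        try:
            fitted = transfer_factory(Xm_std[:k], Xs_std[:k])
            transformed = fitted.transform(_as_matrix(Xs_eval))
            theta = spectral_angle(_as_matrix(Xm_eval), transformed).mean_angle_deg
            rows.append((k, theta))
        except Exception:
            rows.append((k, np.nan))
    table = pd.DataFrame(rows, columns=["k", "mean_angle_deg"])
    valid = table.dropna()
    if valid.empty:
        raise ValueError("transfer fitting failed at every standard-set size")
    best_k = int(valid.loc[valid["mean_angle_deg"].idxmin(), "k"])
    return table, best_k
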