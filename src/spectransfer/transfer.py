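"""Calibration-transfer estimators: PDS, SST and ATLD.

All three estimate, from a small *standard set* measured on both
instruments, a transformation that maps slave-instrument spectra into the
master instrument's response space, so that classifiers trained on master
spectra remain valid for slave data.

PDS (piecewise direct standardization)
    For every wavelength index i, the master response S1_i is regressed on
    the slave responses in the index window [i-w, i+w] by PLS regression:
    S1_i = S2_{i-w..i+w} B_i.  Windows are clipped at the spectrum ends.

SST (spectral space transformation)
    The mean-centred standards are column-concatenated, X_comb = [Xm Xs],
    and decomposed by PCA, X_comb = T [Pm^T Ps^T] + E.  The transfer matrix
    is F = I + (Ps^T)^+ (Pm^T - Ps^T); a centred slave spectrum x maps to
    x F (plus the master centre).

ATLD (alternating trilinear decomposition)
    The standards are stacked into an I x J x K tensor (samples x
    wavelengths x instruments, K = 2) and factorised as
    x_ijk = sum_n a_in b_jn c_kn + e_ijk by alternating least squares with
    Moore-Penrose pseudoinverses.  With F_k = diag(c_k) B^T, a spectrum x
    from instrument k1 transfers to instrument k2 as
    x_trans = x F_{k1}^+ F_{k2} + (x - x F_{k1}^+ F_{k1}),
    i.e. the factor-space reconstruction on the target instrument plus the
    unmodelled residual.

Model classes follow a ``Model(data, hyperparameters).fit() -> Results``
convention; thin functional wrappers (``fit_pds`` etc.) are also provided.
Hyperparameters are selected by cross-validated RMSE between master and
transformed slave standards (leave-one-out for PDS, five-fold for SST/ATLD),
with ties broken toward the smallest value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, LeaveOneOut

from .datasets import SpectrumSet
from .sampling import spectral_angle

__all__ = [
    "PDSTransfer",
    "SSTTransfer",
    "ATLDTransfer",
    "PDSResults",
    "SSTResults",
    "ATLDResults",
    "TransferFitReport",
    "resample_to_grid",
    "common_grid",
    "fit_pds",
    "apply_pds",
    "optimize_pds",
    "fit_sst",
    "apply_sst",
    "fit_atld",
    "apply_atld",
    "cv_select_components",
]

# absolute CV-RMSE slack below which hyperparameters count as tied
_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Grid utilities
# ---------------------------------------------------------------------------

def resample_to_grid(spectra: SpectrumSet, target_grid) -> SpectrumSet:
    """Linearly interpolate each spectrum onto ``target_grid`` (no extrapolation)."""
    target = np.asarray(target_grid, dtype=float)
    wl = spectra.wavelengths_nm
    if target[0] < wl[0] - 1e-9 or target[-1] > wl[-1] + 1e-9:
        raise ValueError(
            f"target grid [{target[0]}, {target[-1]}] nm extends beyond the "
            f"source grid [{wl[0]}, {wl[-1]}] nm"
        )
    out = np.vstack([np.interp(target, wl, row) for row in spectra.spectra])
    return spectra.with_spectra(out, target)


def common_grid(master: SpectrumSet, slave: SpectrumSet,
                lo: float = 400.0, hi: float = 800.0) -> np.ndarray:
    """The slave grid restricted to the master/slave overlap.

    The coarser instrument bounds the shared information, so transfers
    operate on the slave's wavelengths within the overlap region.
    """
    lo = max(lo, master.wavelengths_nm[0], slave.wavelengths_nm[0])
    hi = min(hi, master.wavelengths_nm[-1], slave.wavelengths_nm[-1])
    g = slave.wavelengths_nm
    return g[(g >= lo - 1e-9) & (g <= hi + 1e-9)]


def _mat(X) -> np.ndarray:
    return np.atleast_2d(np.asarray(getattr(X, "spectra", X), dtype=float))


@dataclass
class TransferFitReport:
    """Cross-validation record of a hyperparameter search."""

    method: str
    chosen: dict
    cv_table: pd.DataFrame

    def summary(self) -> str:
        lines = [f"{self.method} hyperparameter selection",
                 f"chosen: {self.chosen}", "", self.cv_table.to_string(index=False)]
        return "\n".join(lines)


def _argmin_with_ties(table: pd.DataFrame, value_col: str, param_cols: list[str]) -> dict:
    """Smallest parameters among cells within _TIE_TOL of the minimum RMSE."""
    valid = table.dropna(subset=[value_col])
    if valid.empty:
        raise ValueError("no hyperparameter cell could be evaluated")
    best = valid[value_col].min()
    tied = valid[valid[value_col] <= best + _TIE_TOL]
    idx = tied.sort_values(param_cols, kind="stable").index[0]
    return {c: table.at[idx, c].item() for c in param_cols}


# ---------------------------------------------------------------------------
# PDS
# ---------------------------------------------------------------------------

@dataclass
class PDSResults:
    """Fitted piecewise-direct-standardization map."""

    window_halfwidth: int
    n_components: int
    coeffs: list[np.ndarray]      # per target wavelength, length = window size
    intercepts: np.ndarray        # per target wavelength
    windows: list[tuple[int, int]]
    grid_nm: np.ndarray | None = None

    def transform(self, Xs) -> np.ndarray:
        X = _mat(Xs)
        n = len(self.coeffs)
        if X.shape[1] != n:
            raise ValueError(
                f"input has {X.shape[1]} wavelengths; model was fitted on {n}"
            )
        out = np.empty((X.shape[0], n))
        for i, ((lo, hi), b) in enumerate(zip(self.windows, self.coeffs)):
            out[:, i] = X[:, lo:hi] @ b + self.intercepts[i]
        return out

    def summary(self) -> str:
        return (
            "PDS transfer\n"
            f"  window halfwidth w = {self.window_halfwidth} "
            f"(window size {2 * self.window_halfwidth + 1})\n"
            f"  PLS components    = {self.n_components}\n"
            f"  wavelengths       = {len(self.coeffs)}"
        )


class PDSTransfer:
    """Piecewise direct standardization model.

    Parameters
    ----------
    master_std, slave_std : (m, n) arrays or SpectrumSet
        Row-aligned standard sets on a common grid.
    window_halfwidth : int
        w; each master wavelength is regressed on 2w+1 slave wavelengths.
    n_components : int
        PLS components per local regression (capped by clipped window size).
    """

    def __init__(self, master_std, slave_std, window_halfwidth: int = 12,
                 n_components: int = 6):
        self.Xm = _mat(master_std)
        self.Xs = _mat(slave_std)
        if self.Xm.shape != self.Xs.shape:
            raise ValueError("standard sets must be row-aligned on a common grid")
        self.w = int(window_halfwidth)
        self.n_components = int(n_components)
        m, n = self.Xm.shape
        if self.n_components > 2 * self.w + 1:
            raise ValueError("n_components exceeds the window size 2w+1")
        if self.n_components > m - 1:
            raise ValueError("n_components exceeds standards - 1")
        self.grid_nm = getattr(master_std, "wavelengths_nm", None)

    def fit(self) -> PDSResults:
        m, n = self.Xm.shape
        coeffs, intercepts, windows = [], np.empty(n), []
        for i in range(n):
            lo, hi = max(0, i - self.w), min(n, i + self.w + 1)
            Xw = self.Xs[:, lo:hi]
            y = self.Xm[:, i]
            ncomp = min(self.n_components, hi - lo, m - 1)
            if np.allclose(Xw.var(axis=0), 0):
                b = np.zeros(hi - lo)
                b0 = y.mean()
            else:
                pls = PLSRegression(n_components=ncomp, scale=False)
                pls.fit(Xw, y)
                b = pls.coef_.ravel()
                b0 = float(y.mean() - Xw.mean(axis=0) @ b)
            coeffs.append(b)
            intercepts[i] = b0
            windows.append((lo, hi))
        return PDSResults(self.w, self.n_components, coeffs, intercepts,
                          windows, self.grid_nm)


def fit_pds(Xm_std, Xs_std, w: int = 12, n_components: int = 6) -> PDSResults:
    return PDSTransfer(Xm_std, Xs_std, w, n_components).fit()


def apply_pds(model: PDSResults, Xs) -> np.ndarray:
    return model.transform(Xs)


def optimize_pds(Xm_std, Xs_std, w_grid=(0, 2, 5, 8, 12),
                 component_grid=(1, 2, 3, 6)) -> TransferFitReport:
    """Leave-one-out CV over (w, components); RMSE master vs transformed slave.

    Cells infeasible for the standard count are recorded as NaN.  The
    default grids include window size 25 (w=12) with 6 components.
    """
    Xm, Xs = _mat(Xm_std), _mat(Xs_std)
    m = Xm.shape[0]
    rows = []
    for w in w_grid:
        for nc in component_grid:
            if nc > 2 * w + 1 or nc > m - 2:
                rows.append((w, nc, np.nan))
                continue
            sq = 0.0
            for tr, te in LeaveOneOut().split(Xm):
                res = PDSTransfer(Xm[tr], Xs[tr], w, nc).fit()
                pred = res.transform(Xs[te])
                sq += float(((pred - Xm[te]) ** 2).mean())
            rows.append((w, nc, np.sqrt(sq / m)))
    table = pd.DataFrame(rows, columns=["w", "n_components", "rmse"])
    chosen = _argmin_with_ties(table, "rmse", ["w", "n_components"])
    return TransferFitReport("PDS", chosen, table)


# ---------------------------------------------------------------------------
# SST
# ---------------------------------------------------------------------------

@dataclass
class SSTResults:
    """Fitted spectral-space-transformation map x -> (x - c_s) F + c_m."""

    n_components: int
    F: np.ndarray
    loadings_master: np.ndarray
    loadings_slave: np.ndarray
    center_master: np.ndarray
    center_slave: np.ndarray
    grid_nm: np.ndarray | None = None

    def transform(self, Xs) -> np.ndarray:
        X = _mat(Xs)
        if X.shape[1] != self.F.shape[0]:
            raise ValueError(
                f"input has {X.shape[1]} wavelengths; model was fitted on "
                f"{self.F.shape[0]}"
            )
        return (X - self.center_slave) @ self.F + self.center_master

    def summary(self) -> str:
        dev = float(np.abs(self.F - np.eye(self.F.shape[0])).max())
        return (
            "SST transfer\n"
            f"  PCA components = {self.n_components}\n"
            f"  ||F - I||_inf  = {dev:.3e}\n"
            f"  wavelengths    = {self.F.shape[0]}"
        )


class SSTTransfer:
    """Spectral space transformation model (PCA on [Xm Xs])."""

    def __init__(self, master_std, slave_std, n_components: int = 6):
        self.Xm = _mat(master_std)
        self.Xs = _mat(slave_std)
        if self.Xm.shape != self.Xs.shape:
            raise ValueError("standard sets must be row-aligned on a common grid")
        m, n = self.Xm.shape
        self.n_components = int(n_components)
        if self.n_components > min(m - 1, 2 * n):
            raise ValueError(
                f"n_components={n_components} exceeds min(standards-1, columns)"
            )
        self.grid_nm = getattr(master_std, "wavelengths_nm", None)

    def fit(self) -> SSTResults:
        cm = self.Xm.mean(axis=0)
        cs = self.Xs.mean(axis=0)
        Xc = np.hstack([self.Xm - cm, self.Xs - cs])
        # PCA loadings via SVD of the centred combined matrix
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        P = Vt[: self.n_components]            # (f, 2n)
        n = self.Xm.shape[1]
        PmT, PsT = P[:, :n], P[:, n:]          # (f, n) each
        F = np.eye(n) + np.linalg.pinv(PsT) @ (PmT - PsT)
        return SSTResults(self.n_components, F, PmT.T, PsT.T, cm, cs, self.grid_nm)


def fit_sst(Xm_std, Xs_std, n_components: int = 6) -> SSTResults:
    return SSTTransfer(Xm_std, Xs_std, n_components).fit()


def apply_sst(model: SSTResults, Xs) -> np.ndarray:
    return model.transform(Xs)


# ---------------------------------------------------------------------------
# ATLD
# ---------------------------------------------------------------------------

def _khatri_rao(C: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Khatri-Rao product; rows ordered (k, j) -> k*J + j."""
    K, N = C.shape
    J, _ = B.shape
    return (C[:, None, :] * B[None, :, :]).reshape(K * J, N)


@dataclass
class ATLDResults:
    """Fitted trilinear decomposition and instrument-transfer maps."""

    n_factors: int
    A: np.ndarray                 # samples x N
    B: np.ndarray                 # wavelengths x N
    C: np.ndarray                 # instruments x N (K = 2)
    error_history: np.ndarray     # SSE after each accepted iteration
    converged: bool
    n_iterations: int
    grid_nm: np.ndarray | None = None

    @property
    def relative_error(self) -> float:
        """Final reconstruction SSE relative to the data sum of squares."""
        return float(self.error_history[-1] / self._data_ss)

    _data_ss: float = 1.0

    def F_k(self, k: int) -> np.ndarray:
        """Per-instrument factor map F_k = diag(c_k) B^T (1-based k)."""
        if k not in (1, 2):
            raise ValueError("instrument index must be 1 or 2")
        return np.diag(self.C[k - 1]) @ self.B.T

    def transform(self, Xs, from_instrument: int = 2, to_instrument: int = 1) -> np.ndarray:
        """Map spectra between instrument spaces via the factor projection."""
        X = _mat(Xs)
        F1, F2 = self.F_k(from_instrument), self.F_k(to_instrument)
        P1 = np.linalg.pinv(F1)
        return X @ (np.eye(X.shape[1]) + P1 @ F2 - P1 @ F1)

    def summary(self) -> str:
        return (
            "ATLD transfer\n"
            f"  factors N            = {self.n_factors}\n"
            f"  iterations           = {self.n_iterations} "
            f"(converged: {self.converged})\n"
            f"  relative recon error = {self.relative_error:.3e}"
        )


class ATLDTransfer:
    """Alternating trilinear decomposition of the master/slave standards.

    The tensor slice k=1 is the master standard set, k=2 the slave.
    Initialisation is deterministic: A and B from the singular vectors of
    the mean slice, C from ones.
    """

    def __init__(self, master_std, slave_std, n_factors: int = 2,
                 tol: float = 1e-10, max_iter: int = 500):
        self.Xm = _mat(master_std)
        self.Xs = _mat(slave_std)
        if self.Xm.shape != self.Xs.shape:
            raise ValueError("standard sets must be row-aligned on a common grid")
        I, J = self.Xm.shape
        if n_factors > min(I, J):
            raise ValueError(
                f"n_factors={n_factors} exceeds min(samples, wavelengths)="
                f"{min(I, J)}"
            )
        self.n_factors = int(n_factors)
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        self.grid_nm = getattr(master_std, "wavelengths_nm", None)

    def fit(self) -> ATLDResults:
        X = np.stack([self.Xm, self.Xs], axis=2)  # I x J x 2
        I, J, K = X.shape
        N = self.n_factors
        X1 = X.transpose(0, 2, 1).reshape(I, K * J)   # rows i, cols (k, j)
        X2 = X.transpose(1, 2, 0).reshape(J, K * I)   # rows j, cols (k, i)
        X3 = X.transpose(2, 0, 1).reshape(K, I * J)   # rows k, cols (i, j)
        mean_slice = X.mean(axis=2)
        U, s, Vt = np.linalg.svd(mean_slice, full_matrices=False)
        A = U[:, :N] * s[:N]
        B = Vt[:N].T
        C = np.ones((K, N))
        ss_data = float((X**2).sum())
        errors = []
        prev = None
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            A = X1 @ np.linalg.pinv(_khatri_rao(C, B)).T
            B = X2 @ np.linalg.pinv(_khatri_rao(C, A)).T
            C = X3 @ np.linalg.pinv(_khatri_rao(A, B)).T
            # rebalance: unit-norm B and C columns, scale into A
            nb = np.linalg.norm(B, axis=0)
            nc = np.linalg.norm(C, axis=0)
            nb[nb == 0] = 1.0
            nc[nc == 0] = 1.0
            B /= nb
            C /= nc
            A *= nb * nc
            recon = _khatri_rao(C, B) @ A.T  # (K*J, I)
            sse = float(((recon.T - X1) ** 2).sum())
            errors.append(sse)
            if prev is not None and prev - sse <= self.tol * max(prev, 1e-300):
                converged = True
                break
            prev = sse
        res = ATLDResults(N, A, B, C, np.array(errors), converged, it, self.grid_nm)
        res._data_ss = ss_data if ss_data > 0 else 1.0
        return res


def fit_atld(Xm_std, Xs_std, n_factors: int = 2, tol: float = 1e-10,
             max_iter: int = 500) -> ATLDResults:
    return ATLDTransfer(Xm_std, Xs_std, n_factors, tol, max_iter).fit()


def apply_atld(model: ATLDResults, Xs_new, from_instrument: int = 2,
               to_instrument: int = 1) -> np.ndarray:
    return model.transform(Xs_new, from_instrument, to_instrument)


# ---------------------------------------------------------------------------
# Cross-validated component selection (SST / ATLD)
# ---------------------------------------------------------------------------

def cv_select_components(method: str, Xm_std, Xs_std, grid,
                         n_folds: int = 5, seed: int = 0) -> TransferFitReport:
    """Five-fold CV RMSE between held-out master and transformed slave.

    Fold assignment is seeded; ties pick the smallest component count.
    Folds with fewer than 2 training samples trigger a fold reduction.
    """
    method = method.lower()
    if method not in ("sst", "atld"):
        raise ValueError("method must be 'sst' or 'atld'")
    Xm, Xs = _mat(Xm_std), _mat(Xs_std)
    m = Xm.shape[0]
    if m < 5:
        raise ValueError("at least 5 standards are required for 5-fold CV")
    n_folds = min(n_folds, m)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(Xm))
    rows = []
    for g in grid:
        sqs = []
        for tr, te in folds:
            try:
                if method == "sst":
                    fitted = SSTTransfer(Xm[tr], Xs[tr], int(g)).fit()
                    pred = fitted.transform(Xs[te])
                else:
                    fitted = ATLDTransfer(Xm[tr], Xs[tr], int(g)).fit()
                    pred = fitted.transform(Xs[te])
                sqs.append(float(((pred - Xm[te]) ** 2).mean()))
            except ValueError:
                sqs.append(np.nan)
        rows.append((int(g), float(np.sqrt(np.mean(sqs))) if not np.any(np.isnan(sqs)) else np.nan))
    col = "n_components" if method == "sst" else "n_factors"
    table = pd.DataFrame(rows, columns=[col, "rmse"])
    chosen = _argmin_with_ties(table, "rmse", [col])
    return TransferFitReport(method.upper(), chosen, table)
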