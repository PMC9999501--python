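"""NIPALS chemometrics: PCA, PLS1 calibration, and correlation statistics.

Both decompositions follow the classical NIPALS (nonlinear iterative
partial least squares) recipe of sequential component extraction with
deflation, the algorithm used by the commercial chemometrics software
this workflow descends from. Preprocessing follows the published
settings: spectra TIC-normalized and mean-centered for PCA; restricted
to m/z 50-250 and mean-centered (no column scaling — "all variables
weighted equally") for PLS. Cross-validation in the paper-faithful mode
holds out a single seeded random subset (default 20 samples); a
repeated-random-split mode is provided because one split is
statistically fragile.

Sign convention: the largest-magnitude element of every loading vector
is made positive, so comparisons against SVD oracles are sign-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, NumericalError
from .screening import rank_samples
from .spectra import SpectraMatrix, restrict_mz, align_mz

DEFAULT_MZ_WINDOW = (50, 250)


# ---------------------------------------------------------------------------
# correlation statistics

def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("pearson requires two 1-d vectors of equal length")
    if len(x) < 3:
        raise InputError("pearson requires n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc * xc).sum()))
    sy = float(np.sqrt((yc * yc).sum()))
    if sx == 0.0 or sy == 0.0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan")
    return float((xc * yc).sum() / (sx * sy))


def spearman(x, y) -> float:
    """Rank correlation: Pearson applied to average-tie ranks."""
    rx = rank_samples(pd.Series(np.asarray(x, dtype=float)), descending=False)
    ry = rank_samples(pd.Series(np.asarray(y, dtype=float)), descending=False)
    return pearson(rx.to_numpy(), ry.to_numpy())


def r_squared_linfit(x, y) -> float:
    """Coefficient of determination of the simple linear fit y ~ x.

    For one predictor this equals the squared Pearson correlation, the
    convention behind paired reports such as "PCC 0.87 and R^2 0.78".
    """
    r = pearson(x, y)
    return float(r * r)


@dataclass
class CorrelationReport:
    """Pearson/Spearman/R^2 between a predicted and an observed trait."""

    pearson_r: float
    spearman_rho: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if np.isfinite(self.pearson_r):
            assert abs(self.r_squared - self.pearson_r**2) < 1e-12

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "r_squared": self.r_squared,
            "n": self.n,
        }


def correlation_report(x, y) -> CorrelationReport:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return CorrelationReport(
        pearson_r=pearson(x, y),
        spearman_rho=spearman(x, y),
        r_squared=r_squared_linfit(x, y),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# NIPALS PCA

@dataclass
class PCAModel:
    n_components: int
    loadings: np.ndarray          # components x variables, unit norm rows
    scores: np.ndarray            # samples x components
    explained_variance_fraction: np.ndarray
    preprocessing: dict = field(default_factory=dict)

    def cumulative_explained(self, k: int | None = None) -> float:
        k = self.n_components if k is None else k
        return float(self.explained_variance_fraction[:k].sum())


def _fix_sign(p: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    i = int(np.argmax(np.abs(p)))
    if p[i] < 0:
        return -p, -t
    return p, t


def pca_nipals(
    X,
    n_components: int,
    tol: float = 1e-10,
    max_iter: int = 1000,
    center: bool = True,
) -> PCAModel:
    """Sequential NIPALS principal-component extraction with deflation.

    ``X`` is samples x variables; it is mean-centered by default (pass
    ``center=False`` for an already-centered matrix). Explained variance
    per component is ||t||^2 over the total centered sum of squares.
    """
    X = np.asarray(X, dtype=float).copy()
    n, p = X.shape
    if center:
        X -= X.mean(axis=0)
    if n_components > min(n - 1, p):
        raise InputError(
            f"n_components {n_components} exceeds min(n_samples-1, n_variables) "
            f"= {min(n - 1, p)}"
        )
    total_ss = float((X * X).sum())
    if total_ss <= 0:
        raise InputError("zero-variance matrix: no components to extract")

    scores = np.zeros((n, n_components))
    loadings = np.zeros((n_components, p))
    evf = np.zeros(n_components)
    for k in range(n_components):
        t = X[:, int(np.argmax((X * X).sum(axis=0)))].copy()
        if not np.any(t):
            # residual exhausted; remaining components carry no variance
            break
        for _ in range(max_iter):
            pvec = X.T @ t / (t @ t)
            pvec /= np.linalg.norm(pvec)
            t_new = X @ pvec
            if np.linalg.norm(t_new - t) < tol:
                t = t_new
                break
            t = t_new
        else:
            raise NumericalError(
                f"NIPALS PCA did not converge for component {k + 1} "
                f"within {max_iter} iterations"
            )
        pvec, t = _fix_sign(pvec, t)
        X -= np.outer(t, pvec)
        scores[:, k] = t
        loadings[k] = pvec
        evf[k] = (t @ t) / total_ss
    return PCAModel(
        n_components=n_components,
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=evf,
        preprocessing={"mean_centered": center},
    )


# ---------------------------------------------------------------------------
# NIPALS PLS1

@dataclass
class PLSModel:
    """NIPALS PLS1 calibration linking a spectral window to one trait.

    Coefficients are stored for the original (uncentered) variable space:
    ``yhat = (X_window - x_mean) @ coefficients + y_mean``.
    """

    n_factors: int
    mz_window: tuple[int, int]
    mz: np.ndarray
    x_weights: np.ndarray         # factors x variables
    x_loadings: np.ndarray        # factors x variables
    y_loadings: np.ndarray        # factors
    coefficients: np.ndarray      # variables
    x_mean: np.ndarray
    y_mean: float
    cv_stats: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "n_factors": int(self.n_factors),
            "mz_window": list(self.mz_window),
            "mz": self.mz.tolist(),
            "coefficients": self.coefficients.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "cv_stats": {
                k: (v if isinstance(v, list) else float(v))
                for k, v in self.cv_stats.items()
            },
        }


def _window_matrix(m: SpectraMatrix, window: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    sub = restrict_mz(m, *window)
    return sub.intensities, sub.mz


def fit_pls_nipals(
    m: SpectraMatrix,
    y,
    n_factors: int,
    mz_window: tuple[int, int] = DEFAULT_MZ_WINDOW,
) -> PLSModel:
    """Fit a PLS1 calibration by NIPALS factor extraction with deflation.

    The spectra are restricted to the m/z window and mean-centered with
    stored offsets; the trait is mean-centered. No column scaling is
    applied (all variables weighted equally).
    """
    y = np.asarray(y, dtype=float)
    X, mz = _window_matrix(m, mz_window)
    if len(y) != X.shape[0]:
        raise InputError(
            f"trait length {len(y)} does not match {X.shape[0]} spectra"
        )
    if n_factors < 1:
        raise InputError("n_factors must be >= 1")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    rank = int(np.linalg.matrix_rank(Xc))
    if n_factors > rank:
        raise InputError(
            f"n_factors {n_factors} exceeds the rank {rank} of the centered matrix"
        )

    p = Xc.shape[1]
    W = np.zeros((n_factors, p))
    P = np.zeros((n_factors, p))
    q = np.zeros(n_factors)
    Xr, yr = Xc.copy(), yc.copy()
    extracted = 0
    scale = max(float(np.abs(Xc).max()), 1.0) * max(float(np.abs(yc).max()), 1.0)
    for k in range(n_factors):
        cov = Xr.T @ yr
        nc = np.linalg.norm(cov)
        if nc <= 1e-14 * max(scale, 1.0):
            break  # trait residual exhausted (e.g. constant y): stop early
        w = cov / nc
        t = Xr @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        pvec = Xr.T @ t / tt
        qk = float(yr @ t / tt)
        Xr = Xr - np.outer(t, pvec)
        yr = yr - qk * t
        W[k], P[k], q[k] = w, pvec, qk
        extracted += 1

    if extracted == 0:
        coef = np.zeros(p)
    else:
        Wk, Pk, qk = W[:extracted], P[:extracted], q[:extracted]
        # B = W (P^T W)^-1 q for the extracted factors
        coef = Wk.T @ np.linalg.solve(Pk @ Wk.T, qk)

    model = PLSModel(
        n_factors=n_factors,
        mz_window=mz_window,
        mz=mz,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=coef,
        x_mean=x_mean,
        y_mean=y_mean,
    )
    yhat = pls_predict(model, m)
    degenerate = np.std(yhat) == 0 or np.std(y) == 0
    model.cv_stats["r2_calibration"] = 0.0 if degenerate else r_squared_linfit(yhat, y)
    model.cv_stats["rmse_calibration"] = float(np.sqrt(np.mean((yhat - y) ** 2)))
    return model


def pls_predict(model: PLSModel, m: SpectraMatrix) -> np.ndarray:
    """Predict the calibrated trait for new spectra.

    Bins missing inside the model window are treated as zero intensity
    (with a warning), consistent with axis alignment elsewhere.
    """
    lo, hi = model.mz_window
    in_window = m.mz[(m.mz >= lo) & (m.mz <= hi)]
    missing = sorted(set(model.mz.tolist()) - set(in_window.tolist()))
    if missing:
        warnings.warn(
            f"{len(missing)} model bins missing from input axis; treated as zero",
            stacklevel=2,
        )
    aligned = align_mz(m, model.mz)
    return (aligned.intensities - model.x_mean) @ model.coefficients + model.y_mean


def cross_validate_pls(
    m: SpectraMatrix,
    y,
    n_factors: int,
    n_holdout: int = 20,
    seed: int = 0,
    mz_window: tuple[int, int] = DEFAULT_MZ_WINDOW,
) -> dict:
    """Single seeded random-holdout cross-validation.

    ``n_holdout`` samples are set aside (seeded, reproducible), the model
    is fit on the remainder, and validation R^2 / RMSE are computed on
    the holdout. This mirrors the published procedure of validating with
    20 random samples.
    """
    y = np.asarray(y, dtype=float)
    n = m.n_spectra
    if n_holdout >= n:
        raise InputError(f"n_holdout {n_holdout} must be smaller than n = {n}")
    rng = np.random.default_rng(seed)
    holdout = np.sort(rng.choice(n, size=n_holdout, replace=False))
    train = np.setdiff1d(np.arange(n), holdout)

    def take(idx):
        return SpectraMatrix(
            sample_ids=[m.sample_ids[i] for i in idx],
            mz=m.mz,
            intensities=m.intensities[idx],
            replicate_ids=None,
            norm_state=m.norm_state,
        )

    model = fit_pls_nipals(take(train), y[train], n_factors, mz_window)
    yhat = pls_predict(model, take(holdout))
    yv = y[holdout]
    return {
        "r2_calibration": model.cv_stats["r2_calibration"],
        "rmse_calibration": model.cv_stats["rmse_calibration"],
        "r2_validation": (
            0.0 if np.std(yhat) == 0 or np.std(yv) == 0 else r_squared_linfit(yhat, yv)
        ),
        "rmse_validation": float(np.sqrt(np.mean((yhat - yv) ** 2))),
        "holdout_indices": holdout.tolist(),
    }


def cross_validate_pls_repeated(
    m: SpectraMatrix,
    y,
    n_factors: int,
    n_holdout: int = 20,
    n_repeats: int = 50,
    seed: int = 0,
    mz_window: tuple[int, int] = DEFAULT_MZ_WINDOW,
) -> dict:
    """Repeated random-split cross-validation (mean +/- sd over splits)."""
    rng = np.random.default_rng(seed)
    r2s, rmses = [], []
    for _ in range(n_repeats):
        stats = cross_validate_pls(
            m, y, n_factors, n_holdout,
            seed=int(rng.integers(2**31 - 1)), mz_window=mz_window,
        )
        r2s.append(stats["r2_validation"])
        rmses.append(stats["rmse_validation"])
    return {
        "n_repeats": n_repeats,
        "r2_validation_mean": float(np.mean(r2s)),
        "r2_validation_sd": float(np.std(r2s, ddof=1)),
        "rmse_validation_mean": float(np.mean(rmses)),
        "rmse_validation_sd": float(np.std(rmses, ddof=1)),
    }


# ---------------------------------------------------------------------------
# ion discovery

def ion_trait_correlations(m: SpectraMatrix, trait) -> pd.Series:
    """Pearson correlation of every m/z column against a per-sample trait.

    Constant columns yield NaN (undefined correlation). The trait must be
    aligned to the spectra samples; a pandas Series is matched by index.
    """
    if isinstance(trait, pd.Series):
        missing = [s for s in m.sample_ids if s not in trait.index]
        extra = [s for s in trait.index if s not in m.sample_ids]
        if missing or extra:
            raise InputError(
                f"trait/sample mismatch: spectra samples missing from trait {missing}; "
                f"trait samples not in spectra {extra}"
            )
        t = trait.loc[m.sample_ids].to_numpy(dtype=float)
    else:
        t = np.asarray(trait, dtype=float)
        if len(t) != m.n_spectra:
            raise InputError(
                f"trait length {len(t)} does not match {m.n_spectra} spectra"
            )
    out = np.full(len(m.mz), np.nan)
    tc = t - t.mean()
    st = np.sqrt((tc * tc).sum())
    if st == 0:
        raise InputError("trait has zero variance")
    Xc = m.intensities - m.intensities.mean(axis=0)
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    ok = sx > 0
    with np.errstate(invalid="ignore"):
        out[ok] = (Xc[:, ok].T @ tc) / (sx[ok] * st)
    return pd.Series(out, index=m.mz, name="pearson_r")


def select_ions(per_ion_r: pd.Series, threshold: float) -> list[int]:
    """m/z bins whose trait correlation meets the threshold, sorted."""
    sel = per_ion_r[per_ion_r >= threshold]
    return sorted(int(i) for i in sel.index)
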