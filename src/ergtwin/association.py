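"""Kinship-adjusted linear mixed model association, implemented from scratch.

Model:  y = Xβ + u + ε,  u ~ N(0, σg² K),  ε ~ N(0, σe² I), with K the
expected additive relatedness matrix (MZ co-twins 1, DZ 0.5).  Writing
λ = σg²/σe², the covariance is σe²(λK + I).  :func:`fit_lmm` maximizes the
restricted likelihood over λ using a single eigendecomposition of K
(rotate once, then every λ costs only diagonal reweighting), a log-spaced
grid scan and golden-section refinement.  The fixed effects are estimated
by GLS at λ̂ and the dosage coefficient is tested with a Wald t statistic
on n − rank(X) degrees of freedom.

:func:`gls_oracle` is a deliberately slow and simple verification path —
dense Cholesky solves of V = λK + I at each candidate λ, no
eigendecomposition — used to cross-check the spectral implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "LMMFit",
    "build_design",
    "fit_lmm",
    "gls_oracle",
    "association_scan",
    "summarize_by_group",
]

LAMBDA_BOUNDS = (1e-5, 1e5)


@dataclass
class LMMFit:
    """Result of one mixed-model fit."""

    beta: np.ndarray          # fixed-effect estimates, per design column
    se: np.ndarray            # standard errors
    names: List[str]          # design column names
    sigma_g2: float           # genetic variance component (µV²)
    sigma_e2: float           # residual variance component (µV²)
    lam: float                # λ = σg²/σe²
    loglik: float             # restricted (or full) log-likelihood at λ̂
    df: int                   # n - rank(X)
    method: str               # "reml" or "ml"
    t_stat: float             # Wald t for the tested column
    p_wald: float             # two-sided Wald p for the tested column
    test_column: str

    def __getitem__(self, name: str) -> Tuple[float, float]:
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se[i])


def build_design(
    cohort: pd.DataFrame, dosage_coding: str = "additive"
) -> Tuple[np.ndarray, List[str]]:
    """Design matrix [intercept, dosage, age, sex] from a cohort table.

    Constant non-intercept columns (e.g. sex in an all-female cohort) are
    pruned.  ``dosage_coding="genotypic"`` replaces the additive 0/1/2
    column with two indicator columns.
    """
    cols: Dict[str, np.ndarray] = {"intercept": np.ones(len(cohort))}
    d = cohort["dosage"].to_numpy(dtype=float)
    if dosage_coding == "additive":
        cols["dosage"] = d
    elif dosage_coding == "genotypic":
        cols["dosage_het"] = (d == 1).astype(float)
        cols["dosage_hom"] = (d == 2).astype(float)
    else:
        raise ValueError(f"unknown dosage coding {dosage_coding!r}")
    cols["age"] = cohort["age"].to_numpy(dtype=float)
    cols["sex"] = (cohort["sex"] == "M").to_numpy(dtype=float)
    names, arrays = [], []
    for name, arr in cols.items():
        if name != "intercept" and np.ptp(arr) == 0.0:
            warnings.warn(f"dropping constant design column {name!r}")
            continue
        names.append(name)
        arrays.append(arr)
    return np.column_stack(arrays), names


def _prune_rank_deficient(
    X: np.ndarray, names: Sequence[str]
) -> Tuple[np.ndarray, List[str]]:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    keep = sorted(piv[: int((diag > tol).sum())])
    if len(keep) < X.shape[1]:
        dropped = [names[i] for i in range(X.shape[1]) if i not in keep]
        warnings.warn(f"dropping rank-deficient design columns {dropped}")
        return X[:, keep], [names[i] for i in keep]
    return X, list(names)


def _kinship_eig(K: np.ndarray, ridge_tol: float = 1e-6) -> Tuple[np.ndarray, np.ndarray]:
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("K must be symmetric")
    d, U = np.linalg.eigh(K)
    if d.min() < -ridge_tol:
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {d.min():.3g})")
    return np.clip(d, 0.0, None), U


def _reml_pieces(
    lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray, method: str
) -> Tuple[float, np.ndarray, np.ndarray, float]:
    """(loglik, beta, cov_unscaled, sigma_e2) at a given λ on rotated data."""
    n, p = Xt.shape
    w = 1.0 / (lam * d + 1.0)
    Xw = Xt * w[:, None]
    A = Xw.T @ Xt
    beta = np.linalg.solve(A, Xw.T @ yt)
    r = yt - Xt @ beta
    rss = float((w * r * r).sum())
    logdet_v = float(np.log(lam * d + 1.0).sum())
    if method == "reml":
        dof = n - p
        sigma_e2 = rss / dof
        sign, logdet_a = np.linalg.slogdet(A)
        sign0, logdet_xx = np.linalg.slogdet(Xt.T @ Xt)
        ll = -0.5 * (
            dof * np.log(2.0 * np.pi * max(sigma_e2, 1e-300)) + dof
            + logdet_v + logdet_a - logdet_xx
        )
    else:
        sigma_e2 = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * max(sigma_e2, 1e-300)) + n + logdet_v)
    return float(ll), beta, np.linalg.inv(A), sigma_e2


def _golden_max(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Golden-section maximizer on [lo, hi] (scalar, deterministic)."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    e = a + invphi * (b - a)
    fc, fe = f(c), f(e)
    while b - a > tol:
        if fc >= fe:
            b, e, fe = e, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, e, fe
            e = a + invphi * (b - a)
            fe = f(e)
    return (a + b) / 2.0


def _optimize_lambda(
    loglik, bounds: Tuple[float, float], grid_size: int, tol: float
) -> float:
    lg_lo, lg_hi = np.log10(bounds[0]), np.log10(bounds[1])
    grid = np.linspace(lg_lo, lg_hi, grid_size)
    vals = np.array([loglik(10.0 ** g) for g in grid])
    # near-ties break toward the smaller lambda (flat profiles, e.g. K = I,
    # otherwise pick an arbitrary grid point)
    i = int(np.argmax(vals >= vals.max() - 1e-9 * max(abs(vals.max()), 1.0)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    lg = _golden_max(lambda g: loglik(10.0 ** g), lo, hi, tol=tol)
    # keep the better of the refined point and the raw grid optimum
    if loglik(10.0 ** lg) >= vals[i]:
        return float(10.0 ** lg)
    return float(10.0 ** grid[i])


def _finalize(
    beta: np.ndarray,
    cov_unscaled: np.ndarray,
    sigma_e2: float,
    lam: float,
    ll: float,
    names: List[str],
    n: int,
    method: str,
    test_column: str,
) -> LMMFit:
    p = len(names)
    se = np.sqrt(np.clip(sigma_e2 * np.diag(cov_unscaled), 0.0, None))
    df = n - p
    if test_column in names:
        j = names.index(test_column)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = float(beta[j] / se[j]) if se[j] > 0 else np.inf * np.sign(beta[j])
        p_wald = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        p_wald = max(p_wald, np.finfo(float).tiny)
    else:
        t, p_wald = np.nan, np.nan
    return LMMFit(
        beta=beta,
        se=se,
        names=names,
        sigma_g2=float(lam * sigma_e2),
        sigma_e2=float(sigma_e2),
        lam=float(lam),
        loglik=float(ll),
        df=df,
        method=method,
        t_stat=t,
        p_wald=p_wald,
        test_column=test_column,
    )


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    K: Optional[np.ndarray] = None,
    *,
    eig: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    names: Optional[Sequence[str]] = None,
    method: str = "reml",
    test_column: str = "dosage",
    bounds: Tuple[float, float] = LAMBDA_BOUNDS,
    grid_size: int = 100,
    tol: float = 1e-6,
) -> LMMFit:
    """Fit the kinship mixed model by spectral (RE)ML.

    Either ``K`` or a precomputed ``eig = (eigenvalues, eigenvectors)`` of
    K must be given; passing ``eig`` lets callers fitting many phenotypes
    against one kinship matrix pay for the eigendecomposition once.
    """
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("y and X have incompatible shapes")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    X, names = _prune_rank_deficient(X, list(names))
    if eig is None:
        if K is None:
            raise ValueError("either K or eig must be supplied")
        if K.shape != (n, n):
            raise ValueError("K has wrong shape")
        eig = _kinship_eig(K)
    d, U = eig
    yt = U.T @ y
    Xt = U.T @ X

    def loglik(lam: float) -> float:
        return _reml_pieces(lam, d, yt, Xt, method)[0]

    lam_hat = _optimize_lambda(loglik, bounds, grid_size, tol)
    ll, beta, cov_u, s_e2 = _reml_pieces(lam_hat, d, yt, Xt, method)
    return _finalize(beta, cov_u, s_e2, lam_hat, ll, names, n, method, test_column)


def gls_oracle(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    lambda_grid: Optional[np.ndarray] = None,
    *,
    names: Optional[Sequence[str]] = None,
    method: str = "reml",
    test_column: str = "dosage",
    refine: bool = True,
    tol: float = 1e-6,
) -> LMMFit:
    """Brute-force mixed-model fit by direct dense solves.

    For each candidate λ it forms V = λK + I explicitly, computes GLS
    estimates and the restricted likelihood via Cholesky factorization,
    and returns the optimum (golden-section refined on the same dense
    objective when ``refine``).  Shares no linear-algebra path with
    :func:`fit_lmm`; intended for verification at small n.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = np.asarray(K, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)

    def pieces(lam: float):
        V = lam * K + np.eye(n)
        try:
            c, low = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return None
        Viy = linalg.cho_solve((c, low), y)
        ViX = linalg.cho_solve((c, low), X)
        A = X.T @ ViX
        beta = np.linalg.solve(A, X.T @ Viy)
        r = y - X @ beta
        Vir = linalg.cho_solve((c, low), r)
        rss = float(r @ Vir)
        logdet_v = 2.0 * float(np.log(np.diag(c)).sum())
        if method == "reml":
            dof = n - p
            s_e2 = rss / dof
            _, logdet_a = np.linalg.slogdet(A)
            _, logdet_xx = np.linalg.slogdet(X.T @ X)
            ll = -0.5 * (
                dof * np.log(2.0 * np.pi * max(s_e2, 1e-300)) + dof
                + logdet_v + logdet_a - logdet_xx
            )
        else:
            s_e2 = rss / n
            ll = -0.5 * (n * np.log(2.0 * np.pi * max(s_e2, 1e-300)) + n + logdet_v)
        return float(ll), beta, np.linalg.inv(A), s_e2

    if lambda_grid is None:
        lambda_grid = np.logspace(
            np.log10(LAMBDA_BOUNDS[0]), np.log10(LAMBDA_BOUNDS[1]), 100
        )
    vals = []
    for lam in lambda_grid:
        pc = pieces(float(lam))
        vals.append(-np.inf if pc is None else pc[0])
    vals = np.asarray(vals)
    i = int(np.argmax(vals >= vals.max() - 1e-9 * max(abs(vals.max()), 1.0)))
    lam_hat = float(lambda_grid[i])
    if refine:
        lg = np.log10(lambda_grid)
        lo = lg[max(i - 1, 0)]
        hi = lg[min(i + 1, len(lg) - 1)]

        def f(g: float) -> float:
            pc = pieces(10.0 ** g)
            return -np.inf if pc is None else pc[0]

        lg_hat = _golden_max(f, lo, hi, tol=tol)
        if f(lg_hat) >= vals[i]:
            lam_hat = float(10.0 ** lg_hat)
    pc = pieces(lam_hat)
    if pc is None:
        raise np.linalg.LinAlgError("V singular at the optimum")
    ll, beta, cov_u, s_e2 = pc
    return _finalize(beta, cov_u, s_e2, lam_hat, ll, names, n, method, test_column)


def association_scan(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    K: np.ndarray,
    parameters: Optional[Sequence[str]] = None,
    *,
    alpha: float = 0.05,
    method: str = "reml",
    dosage_coding: str = "additive",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """One mixed-model association per ERG parameter.

    ``features`` is a wide table (rows = subjects, columns = parameters);
    ``cohort`` carries dosage/age/sex, indexed by subject id in the same
    order as ``K``.  Missing phenotypes are handled per parameter by
    complete-case restriction (counts reported in the output).  The
    significance flag applies the plain P < alpha rule; no multiple-testing
    correction is applied by default, with an optional Benjamini–Hochberg
    column.
    """
    if parameters is None:
        parameters = list(features.columns)
    features = features.reindex(cohort.index)
    X_full, names = build_design(cohort, dosage_coding)
    test_column = "dosage" if dosage_coding == "additive" else "dosage_hom"
    eig_cache: Dict[bytes, Tuple[np.ndarray, np.ndarray]] = {}
    rows = []
    for param in parameters:
        y = features[param].to_numpy(dtype=float)
        mask = np.isfinite(y)
        key = mask.tobytes()
        if key not in eig_cache:
            eig_cache[key] = _kinship_eig(K[np.ix_(mask, mask)])
        fit = fit_lmm(
            y[mask],
            X_full[mask],
            eig=eig_cache[key],
            names=names,
            method=method,
            test_column=test_column,
        )
        b, se = fit[test_column]
        rows.append(
            {
                "parameter": param,
                "beta": b,
                "se": se,
                "p": fit.p_wald,
                "sigma_g2": fit.sigma_g2,
                "sigma_e2": fit.sigma_e2,
                "lambda": fit.lam,
                "n": int(mask.sum()),
                "n_missing": int((~mask).sum()),
                "significant": bool(fit.p_wald < alpha),
            }
        )
    out = pd.DataFrame(rows)
    if bh_correction and len(out):
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj


def summarize_by_group(
    features: pd.DataFrame, dosages: pd.Series
) -> pd.DataFrame:
    """Mean (SD) per parameter per dosage group, with group sizes.

    Rows follow the feature-column order; the SD of a single observation
    is reported as 0 by convention; empty groups yield blank (NaN) cells.
    """
    dosages = dosages.reindex(features.index)
    if not dosages.dropna().isin([0, 1, 2]).all():
        raise ValueError("dosage must be 0, 1 or 2")
    rows = []
    for param in features.columns:
        row: Dict[str, object] = {"parameter": param}
        for g in (0, 1, 2):
            vals = features.loc[dosages == g, param].dropna()
            row[f"n_{g}"] = int(len(vals))
            row[f"mean_{g}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"sd_{g}"] = float(vals.std(ddof=1)) if len(vals) > 1 else (
                0.0 if len(vals) == 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
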