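"""Variance components for the single-trait animal model by AI-REML.

Model: y = Xb + Zu + e with u ~ N(0, K sigma_a^2) and e ~ N(0, I sigma_e^2),
where K is a relationship matrix (pedigree A for the conventional
analysis, genomic G for marker-based ones). The REML log-likelihood is
maximised over (sigma_a^2, sigma_e^2) by average-information updates with
monotone step-halving, so the likelihood never decreases between
iterations. Standard errors come from the inverse average-information
matrix at convergence; the heritability SE uses the delta method.

Numerically, everything runs in the eigenbasis of S = Z K Z': after one
symmetric eigendecomposition, V = sigma_a^2 D + sigma_e^2 I is diagonal,
and each iteration costs O(n p^2). This is exact and comfortably handles
the package's target scale (up to a few thousand records).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

from .core import NumericalError, RelationshipMatrix, ValidationError


class DesignError(ValidationError):
    """Design matrix problem (rank deficiency, unknown column)."""


class LinkageError(ValidationError):
    """A phenotyped animal is absent from the relationship structure."""


@dataclass
class AnimalModelSpec:
    """Which columns of the phenotype table enter the animal model.

    ``factors`` are categorical fixed effects (e.g. a contemporary group
    combining batch, test place and sex; birth place); ``covariates`` are
    numeric regressions (e.g. age at recording). ``relationship`` names
    the relationship-matrix kind used for the additive effect.
    """

    response: str
    factors: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    relationship: str = "A"


@dataclass
class DesignMatrices:
    y: np.ndarray
    X: np.ndarray
    Z: sp.csr_matrix
    columns: tuple[str, ...]
    dropped: tuple[str, ...]
    record_animals: tuple[str, ...]


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    se_a2: float
    se_e2: float
    h2: float
    se_h2: float
    converged: bool
    n_iter: int
    loglik: float = np.nan
    boundary: bool = False
    cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def sigma_p2(self) -> float:
        return self.sigma_a2 + self.sigma_e2

    @property
    def se_p2(self) -> float:
        if self.cov is None:
            return np.nan
        return float(np.sqrt(np.sum(self.cov)))


def _full_rank_columns(X: np.ndarray, names: list[str], tol: float = 1e-8):
    """Greedy first-seen full-rank column selection (Gram-Schmidt)."""
    n = X.shape[0]
    basis: list[np.ndarray] = []
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        c = X[:, j].astype(float)
        r = c.copy()
        for q in basis:
            r -= (q @ c) * q
        nrm0 = np.linalg.norm(c)
        if nrm0 == 0 or np.linalg.norm(r) <= tol * max(nrm0, 1.0):
            dropped.append(names[j])
            continue
        basis.append(r / np.linalg.norm(r))
        keep.append(j)
    return X[:, keep], [names[j] for j in keep], dropped


def build_design(
    spec: AnimalModelSpec, phenotypes, ids
) -> DesignMatrices:
    """Assemble y, X (full-rank, reference-coded) and Z for the model.

    ``phenotypes`` is a table with an ``animal`` column plus the response,
    factor and covariate columns; ``ids`` is the ordered id list of the
    relationship structure. Records with a missing response are dropped.
    Factor levels are reference-coded in first-seen order; columns aliased
    with earlier ones are dropped deterministically (first-seen kept).
    """
    needed = [spec.response, *spec.factors, *spec.covariates]
    for col in ("animal", *needed):
        if col not in phenotypes.columns:
            raise DesignError(f"phenotype table lacks column {col!r}")
    df = phenotypes.loc[phenotypes[spec.response].notna()].reset_index(drop=True)
    if df.empty:
        raise DesignError(f"no non-missing records for {spec.response!r}")
    y = df[spec.response].to_numpy(dtype=float)
    n = len(df)

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for f in spec.factors:
        levels = list(dict.fromkeys(df[f].astype(str)))
        if len(levels) < 1:
            raise DesignError(f"factor {f!r} has no levels")
        vals = df[f].astype(str).to_numpy()
        for lev in levels[1:]:  # first-seen level is the reference
            cols.append((vals == lev).astype(float))
            names.append(f"{f}[{lev}]")
    for c in spec.covariates:
        v = df[c].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise DesignError(f"covariate {c!r} has missing values")
        cols.append(v)
        names.append(c)
    X = np.column_stack(cols)
    X, kept_names, dropped = _full_rank_columns(X, names)

    index = {str(a): i for i, a in enumerate(ids)}
    animals = df["animal"].astype(str).tolist()
    rows, zcols = [], []
    for r, a in enumerate(animals):
        if a not in index:
            raise LinkageError(
                f"phenotyped animal {a!r} is not in the relationship structure"
            )
        rows.append(r)
        zcols.append(index[a])
    Z = sp.csr_matrix(
        (np.ones(n), (rows, zcols)), shape=(n, len(index))
    )
    return DesignMatrices(y, X, Z, tuple(kept_names), tuple(dropped), tuple(animals))


def _as_dense_K(K) -> np.ndarray:
    if isinstance(K, RelationshipMatrix):
        if K.kind.endswith("_inverse"):
            raise ValidationError("reml_estimate needs K itself, not its inverse")
        return K.dense()
    return np.asarray(K, dtype=float)


def reml_estimate(
    y: np.ndarray,
    X: np.ndarray,
    Z: sp.spmatrix | np.ndarray,
    K,
    init: tuple[float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> VarianceComponents:
    """REML estimates of (sigma_a^2, sigma_e^2) and the heritability.

    Non-convergence and boundary/unidentifiable fits are reported through
    the ``converged`` and ``boundary`` flags rather than exceptions.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n != y.size:
        raise ValidationError("y and X row counts differ")
    if n <= p:
        raise ValidationError("more fixed-effect parameters than records")
    Kd = _as_dense_K(K)
    Zd = Z.toarray() if sp.issparse(Z) else np.asarray(Z, dtype=float)
    S = Zd @ Kd @ Zd.T
    d, U = la.eigh(0.5 * (S + S.T), check_finite=False)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    vary = float(np.var(y))
    if vary == 0.0:
        raise ValidationError("response has zero variance")
    floor = 1e-10 * vary
    theta = np.array(init if init is not None else (vary / 2.0, vary / 2.0))
    theta = np.maximum(theta, floor)

    def profile(th):
        v = th[0] * d + th[1]
        vinv = 1.0 / v
        W = Xt * vinv[:, None]
        C = Xt.T @ W
        try:
            cf = la.cho_factor(C, check_finite=False)
        except la.LinAlgError as exc:
            raise DesignError("X is rank deficient after coding") from exc
        beta = la.cho_solve(cf, W.T @ yt, check_finite=False)
        r = yt - Xt @ beta
        Py = vinv * r
        yPy = float(r @ Py)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * (float(np.sum(np.log(v))) + logdetC + yPy)

        def apply_P(z):
            return vinv * z - W @ la.cho_solve(cf, W.T @ z, check_finite=False)

        WdW = (W * d[:, None]).T @ W
        WW = W.T @ W
        trPD = float(np.sum(d * vinv)) - float(np.trace(la.cho_solve(cf, WdW)))
        trPI = float(np.sum(vinv)) - float(np.trace(la.cho_solve(cf, WW)))
        fa, fe = d * Py, Py
        Pfa, Pfe = apply_P(fa), apply_P(fe)
        score = np.array(
            [-0.5 * (trPD - float(fa @ Py)), -0.5 * (trPI - float(fe @ Py))]
        )
        # y'P Vi P y = f_i' Py  (f_i = Vi P y); AI_ij = 0.5 f_i' P f_j
        AI = 0.5 * np.array(
            [[float(fa @ Pfa), float(fa @ Pfe)], [float(fe @ Pfa), float(fe @ Pfe)]]
        )
        return ll, score, AI

    ll, score, AI = profile(theta)
    converged = False
    boundary = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.linalg.cond(AI) > 1e10:
            boundary = True
            warnings.warn(
                "average-information matrix is singular: variance components "
                "not separately identifiable", stacklevel=2,
            )
            break
        step = np.linalg.solve(AI, score)
        accepted = False
        for _ in range(40):  # monotone step-halving keeps logL non-decreasing
            cand = theta + step
            if (cand > 0.0).all() and cand[1] > floor:
                cand = np.maximum(cand, floor)
                ll_c, score_c, AI_c = profile(cand)
                if ll_c >= ll - 1e-10:
                    accepted = True
                    break
            step = 0.5 * step
        if not accepted:
            converged = np.linalg.norm(score) < 1e-4
            break
        rel = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), floor))
        theta, ll, score, AI = cand, ll_c, score_c, AI_c
        if rel < tol:
            converged = True
            break

    if theta[0] <= 1e-6 * vary:
        boundary = True
    try:
        cov = np.linalg.inv(AI)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            cov = None
    except np.linalg.LinAlgError:
        cov = None
    sa2, se2 = float(theta[0]), float(theta[1])
    h2 = sa2 / (sa2 + se2)
    if cov is not None:
        se_a2, se_e2 = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        gp = sa2 + se2
        grad = np.array([se2, -sa2]) / gp**2
        se_h2 = float(np.sqrt(grad @ cov @ grad))
    else:
        se_a2 = se_e2 = se_h2 = np.nan
    return VarianceComponents(
        sigma_a2=sa2, sigma_e2=se2, se_a2=se_a2, se_e2=se_e2, h2=h2,
        se_h2=se_h2, converged=converged, n_iter=n_iter, loglik=float(ll),
        boundary=boundary, cov=cov,
    )


def varcomp_table(results: dict[str, VarianceComponents]):
    """Per-trait variance-component table: sigma_a^2 (SE), sigma_e^2 (SE),
    sigma_p^2 (SE), h^2 (SE)."""
    import pandas as pd

    rows = []
    for trait, vc in results.items():
        rows.append(
            {
                "trait": trait,
                "sigma_a2": vc.sigma_a2, "se_a2": vc.se_a2,
                "sigma_e2": vc.sigma_e2, "se_e2": vc.se_e2,
                "sigma_p2": vc.sigma_p2, "se_p2": vc.se_p2,
                "h2": vc.h2, "se_h2": vc.se_h2,
                "converged": vc.converged, "n_iter": vc.n_iter,
            }
        )
    return pd.DataFrame(rows)
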