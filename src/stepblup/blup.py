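"""Adjusted phenotypes and the four BLUP model variants.

Phenotypes are first adjusted for fixed effects by ordinary least
squares (y_adj = y - X b_hat, b_hat = (X'X)^-1 X'y); breeding values are
then predicted from the simple repeatability-free animal model
y_adj = 1 mu + Z u + e by solving Henderson's mixed model equations

    [ 1'1   1'Z            ] [mu]   [1'y]
    [ Z'1   Z'Z + K^-1 lam ] [u ] = [Z'y],   lam = sigma_e^2 / sigma_a^2.

Model variants differ only in K and in which records enter:
PBLUP uses the full pedigree A with all phenotypes; PBLUP-G restricts
both phenotypes and pedigree to genotyped animals; GBLUP uses the
genomic G over genotyped animals; ssGBLUP uses H^-1 so genotyped and
non-genotyped animals are evaluated jointly. When K (not its inverse) is
available, the equations are solved in the equivalent u = K alpha
parameterization, which avoids inverting K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core import NumericalError, RelationshipMatrix, ValidationError
from .grm import BlendWeights, build_H_inverse
from .pedigree import Pedigree, build_A, build_A_inverse, extract_A22, parse_pedigree
from .reml import VarianceComponents, _full_rank_columns

MODEL_TAGS = ("PBLUP_G", "PBLUP", "GBLUP", "ssGBLUP")


@dataclass
class AdjustedPhenotypes:
    y_adj: np.ndarray
    fitted_b: np.ndarray
    columns: tuple[str, ...]


@dataclass
class EBVResult:
    model: str
    mu_hat: float
    ebv: pd.Series  # indexed by animal id, covers every animal in K
    lam: float


def adjust_phenotypes(y: np.ndarray, X: np.ndarray, column_names=None) -> AdjustedPhenotypes:
    """OLS residuals of y on X (fixed effects only).

    X is reduced to full column rank deterministically (first-seen columns
    kept) before solving the normal equations.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    names = list(column_names) if column_names is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]
    Xf, kept, _dropped = _full_rank_columns(X, names)
    XtX = Xf.T @ Xf
    b = la.solve(XtX, Xf.T @ y, assume_a="pos")
    return AdjustedPhenotypes(y - Xf @ b, b, tuple(kept))


def solve_mme(
    y_adj: np.ndarray,
    record_animals,
    K: RelationshipMatrix,
    sigma_a2: float,
    sigma_e2: float,
    model: str = "custom",
) -> EBVResult:
    """Solve the mixed model equations for y_adj = 1 mu + Z u + e.

    ``record_animals`` maps each record to an id in ``K``; every animal in
    K receives an EBV, including those without records (their predictions
    flow through the relationships).
    """
    if sigma_a2 <= 0.0 or sigma_e2 <= 0.0:
        raise ValidationError("variance components must be positive")
    y_adj = np.asarray(y_adj, dtype=float)
    n = y_adj.size
    q = K.n
    pos = K.index(record_animals)
    if len(pos) != n:
        raise ValidationError("record_animals length does not match y_adj")
    lam = sigma_e2 / sigma_a2
    Z = sp.csr_matrix((np.ones(n), (np.arange(n), pos)), shape=(n, q))
    Zt1 = np.asarray(Z.sum(axis=0)).ravel()
    Zty = Z.T @ y_adj

    if K.kind.endswith("_inverse"):
        Kinv = K.values
        ZtZ = (Z.T @ Z).toarray() if q <= 4000 else Z.T @ Z
        if q <= 4000:
            lhs = np.zeros((q + 1, q + 1))
            lhs[0, 0] = n
            lhs[0, 1:] = Zt1
            lhs[1:, 0] = Zt1
            Kin = Kinv.toarray() if sp.issparse(Kinv) else np.asarray(Kinv)
            lhs[1:, 1:] = ZtZ + lam * Kin
            rhs = np.concatenate(([y_adj.sum()], Zty))
            try:
                sol = la.solve(lhs, rhs, assume_a="sym")
            except la.LinAlgError as exc:
                raise NumericalError(
                    f"singular mixed-model equations (n={n}, q={q}, "
                    f"lambda={lam:.3e})"
                ) from exc
        else:
            one = sp.csr_matrix(np.concatenate(([n], Zt1))[None, :])
            lower = sp.hstack(
                [sp.csr_matrix(Zt1[:, None]), Z.T @ Z + lam * Kinv]
            )
            lhs = sp.vstack([one, lower]).tocsc()
            rhs = np.concatenate(([y_adj.sum()], Zty))
            sol = spla.spsolve(lhs, rhs)
        mu = float(sol[0])
        u = np.asarray(sol[1:], dtype=float)
    else:
        # u = K alpha substitution: no inverse of K required
        Kd = K.dense()
        ZK = np.asarray((Z @ Kd))
        lhs = np.zeros((q + 1, q + 1))
        lhs[0, 0] = n
        lhs[0, 1:] = ZK.sum(axis=0)
        lhs[1:, 0] = Zt1
        lhs[1:, 1:] = Z.T @ ZK + lam * np.eye(q)
        rhs = np.concatenate(([y_adj.sum()], Zty))
        try:
            sol = la.solve(lhs, rhs)
        except la.LinAlgError as exc:
            raise NumericalError(
                f"singular mixed-model equations (n={n}, q={q}, lambda={lam:.3e})"
            ) from exc
        mu = float(sol[0])
        u = Kd @ sol[1:]
    if not np.all(np.isfinite(u)):
        raise NumericalError("non-finite breeding values from MME solve")
    return EBVResult(model, mu, pd.Series(u, index=list(K.ids)), lam)


@dataclass
class EvalData:
    """Everything the four models need, with lazily cached matrices.

    ``y_adj`` is a per-animal adjusted phenotype (one record per animal);
    ``genotyped_ids`` is a subset of the pedigree; ``G`` is over exactly
    the genotyped animals.
    """

    pedigree: Pedigree
    y_adj: pd.Series
    genotyped_ids: tuple[str, ...]
    G: RelationshipMatrix
    blend: BlendWeights = None
    _cache: dict = None

    def __post_init__(self) -> None:
        if self.blend is None:
            self.blend = BlendWeights()
        self._cache = {}
        self.genotyped_ids = tuple(str(a) for a in self.genotyped_ids)
        missing = [a for a in self.y_adj.index if str(a) not in self.pedigree._index]
        if missing:
            raise ValidationError(
                f"phenotyped animal {missing[0]!r} is not in the pedigree"
            )
        if tuple(self.G.ids) != self.genotyped_ids:
            raise ValidationError("G id order must equal genotyped_ids")

    def matrix(self, name: str):
        if name in self._cache:
            return self._cache[name]
        if name == "A":
            val = build_A(self.pedigree)
        elif name == "A_inv":
            val = build_A_inverse(self.pedigree)
        elif name == "A22":
            val = extract_A22(self.matrix("A"), self.genotyped_ids)
        elif name == "H_inv":
            val = build_H_inverse(
                self.matrix("A_inv"), self.matrix("A22"), self.G, self.blend
            )
        elif name == "A_trunc":
            ped_g = parse_pedigree(
                self.pedigree.subset_records(self.genotyped_ids),
                unknown_tokens=(),  # parents outside the subset are already None
            )
            A_t = build_A(ped_g).submatrix(self.genotyped_ids, kind="A")
            val = A_t
        else:
            raise KeyError(name)
        self._cache[name] = val
        return val


def run_model(
    model_tag: str,
    data: EvalData,
    varcomp: VarianceComponents,
    mask_ids=(),
    keep_ancestral_links: bool = False,
) -> EBVResult:
    """Dispatch one of PBLUP_G, PBLUP, GBLUP, ssGBLUP.

    ``mask_ids`` phenotypes are excluded from the equations (used for
    cross-validation); the masked animals still receive EBVs through the
    relationship structure. ``keep_ancestral_links`` switches PBLUP-G from
    the truncated within-genotyped pedigree to the full-ancestry A22.
    """
    if model_tag not in MODEL_TAGS:
        raise ValidationError(f"unknown model {model_tag!r}; expected {MODEL_TAGS}")
    mask = {str(a) for a in mask_ids}
    geno = set(data.genotyped_ids)

    def records(restrict_genotyped: bool):
        idx = [
            a for a in data.y_adj.index
            if str(a) not in mask and (not restrict_genotyped or str(a) in geno)
        ]
        return data.y_adj.loc[idx].to_numpy(dtype=float), [str(a) for a in idx]

    if model_tag == "PBLUP":
        y, animals = records(restrict_genotyped=False)
        K = data.matrix("A_inv")
    elif model_tag == "ssGBLUP":
        y, animals = records(restrict_genotyped=False)
        K = data.matrix("H_inv")
    elif model_tag == "GBLUP":
        y, animals = records(restrict_genotyped=True)
        K = data.G
    else:  # PBLUP_G
        y, animals = records(restrict_genotyped=True)
        K = data.matrix("A22") if keep_ancestral_links else data.matrix("A_trunc")
    if y.size == 0:
        raise ValidationError(f"no training records for model {model_tag}")
    return solve_mme(y, animals, K, varcomp.sigma_a2, varcomp.sigma_e2, model=model_tag)
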