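"""Genomic relationship matrix (VanRaden method 1), blending, and H^-1.

G = M M' / (2 * sum_i p_i (1 - p_i)) with M the column-centered dosage
matrix. The single-step matrix inverse is assembled as

    H^-1 = A^-1 + [0 0; 0 (w_g G + w_a A22)^-1 - A22^-1]

with the genotyped block placed at the genotyped animals' positions in
the full pedigree order. The default 95/5 blend keeps the genotyped block
invertible and acknowledges that markers do not capture all pedigree
variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

from .core import (
    AlignmentError,
    NumericalError,
    RelationshipMatrix,
    ValidationError,
    require_same_ids,
)
from .qc import GenotypePanel


@dataclass
class CenteredGenotypes:
    """Column-centered dosages M with the frequencies used for centering."""

    M: np.ndarray
    p: np.ndarray
    ids: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.p)


@dataclass
class BlendWeights:
    """Convex weights for w_g * G + w_a * A22; default 0.95 / 0.05."""

    w_g: float = 0.95
    w_a: float = 0.05

    def __post_init__(self) -> None:
        if not np.isclose(self.w_g + self.w_a, 1.0):
            raise ValidationError("blend weights must sum to 1")
        if not 0.0 < self.w_g <= 1.0:
            raise ValidationError("w_g must be in (0, 1]")


def center_genotypes(
    panel: GenotypePanel, freqs: np.ndarray | None = None
) -> CenteredGenotypes:
    """Center dosages by twice the allele frequency: M[j, i] = x - 2 p_i.

    Frequencies default to those observed in the panel itself; a provided
    vector (e.g. base-population frequencies) overrides. Monomorphic SNPs
    (p in {0, 1}) are allowed with a warning — they contribute nothing to
    either the numerator or the denominator of G.
    """
    if np.isnan(panel.dosages).any():
        raise ValidationError("panel has missing dosages; impute before centering")
    p = panel.allele_frequencies() if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (panel.n_snps,):
        raise ValidationError("frequency vector length does not match SNP count")
    n_mono = int(((p <= 0.0) | (p >= 1.0)).sum())
    if n_mono:
        warnings.warn(f"{n_mono} monomorphic SNPs contribute nothing to G", stacklevel=2)
    M = panel.dosages - 2.0 * p
    return CenteredGenotypes(M, p, panel.animal_ids)


def build_G(cg: CenteredGenotypes) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix G = MM' / (2 sum p(1-p))."""
    denom = 2.0 * float(np.sum(cg.p * (1.0 - cg.p)))
    if denom <= 0.0:
        raise NumericalError("all SNPs monomorphic: G denominator 2*sum p(1-p) is zero")
    G = (cg.M @ cg.M.T) / denom
    G = 0.5 * (G + G.T)  # remove floating-point asymmetry
    return RelationshipMatrix(G, cg.ids, "G")


def blend(
    G: RelationshipMatrix, A22: RelationshipMatrix, w: BlendWeights | None = None
) -> RelationshipMatrix:
    """Convex combination w_g G + w_a A22 on a shared id order."""
    w = w or BlendWeights()
    require_same_ids(G, A22)
    vals = w.w_g * G.dense() + w.w_a * A22.dense()
    return RelationshipMatrix(vals, G.ids, "blended")


def _spd_inverse(mat: np.ndarray, label: str) -> np.ndarray:
    try:
        c, low = la.cho_factor(mat, check_finite=False)
    except la.LinAlgError as exc:
        cond = np.linalg.cond(mat)
        raise NumericalError(
            f"{label} is not positive definite (condition number {cond:.3e})"
        ) from exc
    inv = la.cho_solve((c, low), np.eye(mat.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)


def build_H_inverse(
    A_inv: RelationshipMatrix,
    A22: RelationshipMatrix,
    G: RelationshipMatrix,
    w: BlendWeights | None = None,
) -> RelationshipMatrix:
    """Single-step H^-1 in full pedigree order.

    Adds the genotyped-block correction (w_g G + w_a A22)^-1 - A22^-1 to
    the sparse pedigree inverse at the genotyped animals' positions. The
    genotyped id order is taken from G (which must match A22).
    """
    if A_inv.kind != "A_inverse":
        raise ValidationError("build_H_inverse expects an A_inverse matrix")
    require_same_ids(G, A22)
    pos = A_inv.index(G.ids)  # raises for genotyped ids missing from pedigree
    if G.n == 0:
        return RelationshipMatrix(A_inv.values.copy(), A_inv.ids, "H_inverse")
    blended = blend(G, A22, w)
    corr = _spd_inverse(blended.dense(), "blended matrix (w_g G + w_a A22)") - \
        _spd_inverse(A22.dense(), "A22")
    corr_sparse = sp.coo_matrix(
        (corr.ravel(), (np.repeat(pos, G.n), np.tile(pos, G.n))),
        shape=(A_inv.n, A_inv.n),
    )
    H_inv = (A_inv.values + corr_sparse).tocsr()
    return RelationshipMatrix(H_inv, A_inv.ids, "H_inverse")
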