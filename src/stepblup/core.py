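"""Shared containers for relationship matrices and common errors.

Every relationship matrix in the pipeline (pedigree ``A``, its inverse,
the genotyped block ``A22``, the genomic ``G``, the blended matrix and the
single-step ``H^-1``) is carried together with the ordered animal ids it is
indexed by, so that no stage relies on positional coupling between files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

KINDS = frozenset({"A", "A_inverse", "A22", "G", "blended", "H_inverse"})

SYMMETRY_TOL = 1e-10


class StepblupError(Exception):
    """Base class for pipeline errors."""


class ValidationError(StepblupError, ValueError):
    """Malformed or inconsistent input data."""


class AlignmentError(StepblupError, ValueError):
    """Two labelled objects do not share the same id order."""


class NumericalError(StepblupError, ArithmeticError):
    """A factorization or solve failed; message carries diagnostics."""


@dataclass
class RelationshipMatrix:
    """A symmetric relationship matrix labelled by animal ids.

    Parameters
    ----------
    values
        Dense ``(n, n)`` array or a scipy sparse matrix (used for the
        sparse inverses).
    ids
        Animal ids in matrix order; must be unique.
    kind
        One of ``A``, ``A_inverse``, ``A22``, ``G``, ``blended``,
        ``H_inverse``.
    """

    values: np.ndarray | sp.spmatrix
    ids: tuple[str, ...]
    kind: str
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        if self.kind not in KINDS:
            raise ValidationError(f"unknown relationship-matrix kind {self.kind!r}")
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValidationError("relationship matrix ids are not unique")
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        self._index = {a: i for i, a in enumerate(self.ids)}
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
            if not np.allclose(self.values, self.values.T, atol=SYMMETRY_TOL, rtol=0.0):
                raise ValidationError(f"{self.kind} matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, ids) -> np.ndarray:
        """Positions of ``ids`` in this matrix; KeyError for unknown ids."""
        try:
            return np.array([self._index[str(a)] for a in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in {self.kind} matrix") from None

    def loc(self, i: str, j: str) -> float:
        a, b = self._index[str(i)], self._index[str(j)]
        if sp.issparse(self.values):
            return float(self.values[a, b])
        return float(self.values[a, b])

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return self.values

    def submatrix(self, ids, kind: str | None = None) -> "RelationshipMatrix":
        """Principal submatrix in the stated id order."""
        pos = self.index(ids)
        vals = self.dense()[np.ix_(pos, pos)]
        return RelationshipMatrix(vals, tuple(str(a) for a in ids), kind or self.kind)


def require_same_ids(a: RelationshipMatrix, b: RelationshipMatrix) -> None:
    if a.ids != b.ids:
        raise AlignmentError(
            f"id order mismatch between {a.kind} ({a.n} ids) and {b.kind} ({b.n} ids)"
        )
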