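"""Pedigree parsing, inbreeding, and the numerator relationship matrix.

The pedigree is the backbone of every model variant: the numerator
relationship matrix **A** (expected additive relationships under the
infinitesimal model) enters PBLUP directly, its genotyped block ``A22``
enters the single-step blend, and its sparse inverse (Henderson's rules,
with inbreeding) is the leading term of ``H^-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .core import RelationshipMatrix, ValidationError

UNKNOWN = -1
DEFAULT_UNKNOWN_TOKENS = ("0", "", ".", "NA")


class PedigreeError(ValidationError):
    """Structural pedigree problem (cycle, duplicate id)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree: every parent precedes its offspring.

    ``sire``/``dam`` hold positions into ``ids`` or ``UNKNOWN`` (-1).
    Unknown parents are treated as unrelated, non-inbred founders.
    """

    ids: tuple[str, ...]
    sire: np.ndarray
    dam: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {a: i for i, a in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def position(self, animal_id: str) -> int:
        try:
            return self._index[str(animal_id)]
        except KeyError:
            raise KeyError(f"animal {animal_id!r} not in pedigree") from None

    def parents_of(self, animal_id: str) -> tuple[str | None, str | None]:
        i = self.position(animal_id)
        s, d = self.sire[i], self.dam[i]
        return (self.ids[s] if s >= 0 else None, self.ids[d] if d >= 0 else None)

    def founders(self) -> list[str]:
        return [
            self.ids[i]
            for i in range(self.n)
            if self.sire[i] == UNKNOWN and self.dam[i] == UNKNOWN
        ]

    def depth(self) -> int:
        """Pedigree depth: number of generations on the longest ancestor path."""
        gen = np.ones(self.n, dtype=int)
        for i in range(self.n):
            for p in (self.sire[i], self.dam[i]):
                if p >= 0:
                    gen[i] = max(gen[i], gen[p] + 1)
        return int(gen.max(initial=0))

    def subset_records(self, keep_ids) -> list[tuple[str, str | None, str | None]]:
        """Records restricted to ``keep_ids``; parents outside become unknown."""
        keep = {str(a) for a in keep_ids}
        out = []
        for a in keep_ids:
            s, d = self.parents_of(a)
            out.append(
                (
                    str(a),
                    s if (s is not None and s in keep) else None,
                    d if (d is not None and d in keep) else None,
                )
            )
        return out


def parse_pedigree(records, unknown_tokens=DEFAULT_UNKNOWN_TOKENS) -> Pedigree:
    """Build a validated, topologically ordered :class:`Pedigree`.

    ``records`` is an iterable of ``(animal, sire, dam)`` triples; parents
    equal to ``None`` or to one of ``unknown_tokens`` are unknown. Parents
    that never appear as animals are promoted to founders (placed at first
    appearance). Raises :class:`PedigreeError` on duplicate ids or cycles.
    """
    unknown = {str(t) for t in unknown_tokens}

    def norm(x) -> str | None:
        if x is None:
            return None
        s = str(x).strip()
        return None if s in unknown else s

    triples: list[tuple[str, str | None, str | None]] = []
    seen: set[str] = set()
    order: list[str] = []
    for rec in records:
        a, s, d = rec
        a = norm(a)
        if a is None:
            raise PedigreeError("animal id missing or equal to the unknown token")
        if a in seen:
            raise PedigreeError(f"duplicate animal id {a!r}")
        seen.add(a)
        order.append(a)
        triples.append((a, norm(s), norm(d)))
    if not triples:
        raise PedigreeError("empty pedigree")

    parent_map = {a: (s, d) for a, s, d in triples}
    # promote implicit founders in order of first appearance as a parent
    for a, s, d in triples:
        for p in (s, d):
            if p is not None and p not in seen:
                seen.add(p)
                order.append(p)
                parent_map[p] = (None, None)

    # Kahn-style topological sort, stable in input order
    placed: dict[str, int] = {}
    ordered: list[str] = []
    pending = list(order)
    while pending:
        progressed = False
        remaining = []
        for a in pending:
            s, d = parent_map[a]
            if (s is None or s in placed) and (d is None or d in placed):
                placed[a] = len(ordered)
                ordered.append(a)
                progressed = True
            else:
                remaining.append(a)
        if not progressed:
            raise PedigreeError(
                f"pedigree cycle detected involving animal {remaining[0]!r}"
            )
        pending = remaining

    n = len(ordered)
    sire = np.full(n, UNKNOWN, dtype=int)
    dam = np.full(n, UNKNOWN, dtype=int)
    for a in ordered:
        i = placed[a]
        s, d = parent_map[a]
        if s is not None:
            sire[i] = placed[s]
        if d is not None:
            dam[i] = placed[d]
    return Pedigree(tuple(ordered), sire, dam)


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F (Meuwissen–Luo style).

    Uses the L·D decomposition of A: for animal *i* with known parents
    (s, d), ``1 + F_i = A_xx`` of a virtual offspring x of (s, d), which
    is accumulated over ancestors j as ``sum_j L_xj^2 D_j`` where D_j is
    j's Mendelian sampling variance given its parents' inbreeding. An
    unknown parent contributes as an unrelated, non-inbred founder.
    """
    n = ped.n
    F = np.zeros(n)
    D = np.zeros(n)
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            D[i] = 0.75 - 0.25 * F[s if s >= 0 else d]
        else:
            D[i] = 1.0
        if s < 0 or d < 0:
            continue
        # A_xx of a virtual offspring x of (s, d): 1 + F_x with
        # F_x = 0.5 * a(s, d). Accumulate sum_j L_xj^2 D_j over real
        # ancestors j (L_xx = 1, D_x plays no role in F_x).
        coeff = {int(s): 0.5, int(d): 0.5} if s != d else {int(s): 1.0}
        acc = 0.0
        while coeff:
            j = max(coeff)
            c = coeff.pop(j)
            acc += c * c * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    coeff[int(p)] = coeff.get(int(p), 0.0) + 0.5 * c
        # acc = A_xx - D_x where D_x = 0.5 - 0.25(F_s + F_d)
        F[i] = acc + D[i] - 1.0
    return F


def build_A(ped: Pedigree, subset=None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    If ``subset`` is given, the full-ancestry A is computed and the
    rows/columns for ``subset`` (in the stated order) are returned.
    """
    n = ped.n
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    full = RelationshipMatrix(A, ped.ids, "A")
    if subset is None:
        return full
    return full.submatrix([str(a) for a in subset], kind="A")


def build_A_inverse(ped: Pedigree, account_inbreeding: bool = True) -> RelationshipMatrix:
    """Sparse A^-1 by Henderson's rules, inbreeding-adjusted by default.

    The Mendelian sampling variance of animal *i* is
    ``0.5 - 0.25(F_s + F_d)`` with both parents known,
    ``0.75 - 0.25 F_p`` with one, and 1 with none; its reciprocal drives
    the familiar element contributions.
    """
    n = ped.n
    F = compute_inbreeding(ped) if account_inbreeding else np.zeros(n)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        parents = [p for p in (s, d) if p >= 0]
        if len(parents) == 2:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif len(parents) == 1:
            di = 0.75 - 0.25 * F[parents[0]]
        else:
            di = 1.0
        alpha = 1.0 / di
        add(i, i, alpha)
        for p in parents:
            add(i, p, -0.5 * alpha)
            add(p, i, -0.5 * alpha)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * alpha)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(Ainv, ped.ids, "A_inverse")


def extract_A22(A: RelationshipMatrix, genotyped_ids) -> RelationshipMatrix:
    """Principal submatrix of A for the genotyped animals, in their order."""
    if A.kind != "A":
        raise ValidationError(f"extract_A22 expects kind 'A', got {A.kind!r}")
    return A.submatrix([str(a) for a in genotyped_ids], kind="A22")
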