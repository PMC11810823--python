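"""Numerator relationship matrix (A) and its sparse inverse from a pedigree.

A pedigree is a :class:`pandas.DataFrame` with columns ``animal``, ``sire``,
``dam`` (missing parent = ``None``/NaN/empty string) and optionally
``generation``.  Rows must be topologically ordered: every parent appears
before its offspring.  Unknown parents are treated as unrelated, non-inbred
founders, which matches the recurrent-testing design where commercial
daughters have an unidentified dam from a single dam line.

The dense A is built with the tabular method; the inverse is assembled
directly with Henderson's rules using Meuwissen–Luo inbreeding coefficients,
so it stays sparse for pedigrees far too large to invert densely.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PedigreeError",
    "RelationshipMatrix",
    "pedigree_codes",
    "inbreeding",
    "build_A",
    "build_A_inverse",
    "read_pedigree",
    "write_pedigree",
    "write_relationship_coo",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (unordered rows, unknown parent id...)."""


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix (or its inverse) with its row ordering.

    ``values`` is dense ``ndarray`` for :func:`build_A` and a CSR sparse
    matrix for :func:`build_A_inverse`.  ``log_det_A`` carries
    :math:`\\log|A| = \\sum_i \\log d_i` (Mendelian sampling variances), which
    the REML likelihood needs; it is filled by :func:`build_A_inverse`.
    """

    ids: list
    values: object
    inbreeding: np.ndarray = field(default=None, repr=False)
    log_det_A: float = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        """Positions of ``ids`` in this matrix's ordering."""
        idx = pd.Index(self.ids).get_indexer(pd.Index(ids))
        if (idx < 0).any():
            missing = list(pd.Index(ids)[idx < 0][:5])
            raise KeyError(f"ids not in relationship matrix: {missing}")
        return idx


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or value == ""


def pedigree_codes(pedigree: pd.DataFrame):
    """Map a pedigree frame to integer codes ``(ids, sire_codes, dam_codes)``.

    Unknown parents get code ``-1``.  Raises :class:`PedigreeError` if a
    parent id is absent from the animal column or appears after its
    offspring (which also rules out cycles).
    """
    ids = list(pedigree["animal"])
    pos = {a: i for i, a in enumerate(ids)}
    if len(pos) != len(ids):
        raise PedigreeError("duplicate animal ids in pedigree")
    n = len(ids)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i, (s, d) in enumerate(zip(pedigree["sire"], pedigree["dam"])):
        for arr, parent in ((sire, s), (dam, d)):
            if _is_missing(parent):
                continue
            j = pos.get(parent)
            if j is None:
                raise PedigreeError(f"parent {parent!r} of {ids[i]!r} not in pedigree")
            if j >= i:
                raise PedigreeError(
                    f"pedigree not topologically ordered: parent {parent!r} "
                    f"listed at or after offspring {ids[i]!r}"
                )
            arr[i] = j
    return ids, sire, dam


def _inbreeding_and_d(sire: np.ndarray, dam: np.ndarray):
    """Meuwissen–Luo recursion: inbreeding F and Mendelian variances d.

    For animal *i* with parents *s*, *d*:
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` (unknown parent contributes F = 0 and
    an extra 0.25), and ``1 + F_i = a_ii = sum_j L_ij^2 d_j`` over the
    ancestors *j* of *i*, accumulated by walking path coefficients L
    downward from *i*.
    """
    n = len(sire)
    F = np.zeros(n)
    d = np.ones(n)
    for i in range(n):
        s, dm = sire[i], dam[i]
        if s >= 0 and dm >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[dm])
        elif s >= 0 or dm >= 0:
            d[i] = 0.75 - 0.25 * F[max(s, dm)]
        else:
            d[i] = 1.0
        if s < 0 or dm < 0:
            F[i] = 0.0  # unknown parent is an unrelated founder
            continue
        # a_ii by descending-code traversal of i's ancestors
        L = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j)
            a_ii += lj * lj * d[j]
            for p in (sire[j], dam[j]):
                if p < 0:
                    continue
                if p in L:
                    L[p] += 0.5 * lj
                else:
                    L[p] = 0.5 * lj
                    heapq.heappush(heap, -p)
        F[i] = a_ii - 1.0
    return F, d


def inbreeding(pedigree: pd.DataFrame) -> np.ndarray:
    """Inbreeding coefficients in pedigree order (Meuwissen–Luo)."""
    _, sire, dam = pedigree_codes(pedigree)
    return _inbreeding_and_d(sire, dam)[0]


def build_A(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Dense numerator relationship matrix by the tabular method.

    ``a(i,i) = 1 + F_i`` with ``F_i = 0.5 a(sire_i, dam_i)`` and
    ``a(i,j) = 0.5 [a(sire_i, j) + a(dam_i, j)]`` for j < i; unknown parents
    contribute zero.  Quadratic in pedigree size — intended for pedigrees up
    to a few thousand animals (model fitting only ever uses the inverse).
    """
    ids, sire, dam = pedigree_codes(pedigree)
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        s, dm = sire[i], dam[i]
        row = np.zeros(n)
        if s >= 0:
            row += 0.5 * A[s]
        if dm >= 0:
            row += 0.5 * A[dm]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
        f_i = 0.5 * A[s, dm] if (s >= 0 and dm >= 0) else 0.0
        A[i, i] = 1.0 + f_i
    return RelationshipMatrix(ids=ids, values=A, inbreeding=np.diag(A) - 1.0)


def build_A_inverse(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Sparse A⁻¹ by Henderson's rules with inbreeding.

    Each animal contributes ``alpha = 1/d_i`` to its own diagonal,
    ``-alpha/2`` to animal×parent cells and ``alpha/4`` to parent×parent
    cells.  Also records ``log|A| = sum log d_i``.
    """
    ids, sire, dam = pedigree_codes(pedigree)
    F, d = _inbreeding_and_d(sire, dam)
    rows, cols, vals = [], [], []
    for i in range(len(ids)):
        alpha = 1.0 / d[i]
        parents = [p for p in (sire[i], dam[i]) if p >= 0]
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * alpha, -0.5 * alpha]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * alpha)
    n = len(ids)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(
        ids=ids, values=Ainv, inbreeding=F, log_det_A=float(np.log(d).sum())
    )


def read_pedigree(path) -> pd.DataFrame:
    """Read a pedigree CSV (columns animal, sire, dam[, generation])."""
    ped = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str})
    for col in ("sire", "dam"):
        ped[col] = ped[col].where(ped[col].notna() & (ped[col] != ""), None)
    return ped


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    out = pedigree.copy()
    for col in ("sire", "dam"):
        out[col] = out[col].fillna("")
    out.to_csv(path, index=False)


def write_relationship_coo(rel: RelationshipMatrix, path) -> None:
    """Write A (or A⁻¹) in coordinate text format: row,col,value (1-based)."""
    m = sp.coo_matrix(rel.values)
    frame = pd.DataFrame({"row": m.row + 1, "col": m.col + 1, "value": m.data})
    frame = frame.sort_values(["row", "col"])
    frame.to_csv(path, index=False)
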