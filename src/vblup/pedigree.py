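"""Pedigrees, the numerator relationship matrix A, its sparse-rule inverse
and pedigree inbreeding coefficients.

Conventions: unknown parents are treated as unrelated, non-inbred founders;
an individual with any unknown parent has inbreeding coefficient 0.  A is
built by the tabular (recursive) method; A-inverse is assembled directly
from per-individual Mendelian-sampling variances (Henderson's rules with
inbreeding); inbreeding itself uses the Meuwissen-Luo style L-recursion so
the full A never has to be materialised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .kinship import RelationshipMatrix

UNKNOWN_TOKENS = {"0", "NA", "", ".", "na"}


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    ``ids[i]`` is the identifier of individual ``i``; ``sire[i]`` and
    ``dam[i]`` are integer positions of its parents or -1 if unknown.
    Parents always precede offspring.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise PedigreeError("pedigree IDs must be unique")
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if par.shape != (n,):
                raise PedigreeError(f"{name} array has wrong length")
            bad = np.flatnonzero(par >= np.arange(n))
            if bad.size:
                raise PedigreeError(
                    f"{name} of {self.ids[bad[0]]} does not precede it "
                    "(pedigree not topologically ordered)"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {iid: i for i, iid in enumerate(self.ids)}


def _topological_order(
    records: list[tuple[str, str | None, str | None]],
) -> Pedigree:
    parents: dict[str, tuple[str | None, str | None]] = {}
    order_seen: list[str] = []
    for iid, s, d in records:
        if iid in parents:
            if parents[iid] != (s, d):
                raise PedigreeError(
                    f"individual {iid} listed with conflicting parent pairs"
                )
            continue
        parents[iid] = (s, d)
        order_seen.append(iid)
    # individuals appearing only as parents become founders
    for iid, (s, d) in list(parents.items()):
        for p in (s, d):
            if p is not None and p not in parents:
                parents[p] = (None, None)
                order_seen.append(p)

    # depth-first topological sort with cycle detection
    ids: list[str] = []
    state: dict[str, int] = {}  # 0 unseen / 1 on stack / 2 done
    for root in order_seen:
        if state.get(root, 0) == 2:
            continue
        stack = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                state[node] = 2
                ids.append(node)
                continue
            st = state.get(node, 0)
            if st == 2:
                continue
            if st == 1:
                raise PedigreeError(f"cyclic parentage involving {node}")
            state[node] = 1
            stack.append((node, True))
            for p in parents[node]:
                if p is not None and state.get(p, 0) != 2:
                    if state.get(p, 0) == 1:
                        raise PedigreeError(f"cyclic parentage involving {p}")
                    stack.append((p, False))

    pos = {iid: i for i, iid in enumerate(ids)}
    sire = np.array(
        [pos[parents[i][0]] if parents[i][0] is not None else -1 for i in ids]
    )
    dam = np.array(
        [pos[parents[i][1]] if parents[i][1] is not None else -1 for i in ids]
    )
    return Pedigree(ids, sire, dam)


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 3-column (individual, sire, dam) text pedigree.

    Whitespace- or comma-delimited; the tokens ``0``, ``NA``, ``.`` and the
    empty string denote an unknown parent.  Rows may appear in any order.
    """
    records: list[tuple[str, str | None, str | None]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 3:
                raise PedigreeError(f"expected 3 columns, got: {line!r}")
            iid, s, d = fields
            records.append(
                (
                    iid,
                    None if s in UNKNOWN_TOKENS else s,
                    None if d in UNKNOWN_TOKENS else d,
                )
            )
    if not records:
        raise PedigreeError(f"{path}: empty pedigree")
    return _topological_order(records)


def pedigree_from_records(
    records: list[tuple[str, str | None, str | None]],
) -> Pedigree:
    """Build a Pedigree from in-memory (individual, sire, dam) triples."""
    return _topological_order(records)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iid in enumerate(ped.ids):
            s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else "0"
            d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else "0"
            fh.write(f"{iid}\t{s}\t{d}\n")


def make_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method."""
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        # relationship to all earlier individuals
        if si >= 0 or di >= 0:
            row = np.zeros(i)
            if si >= 0:
                row += A[si, :i]
            if di >= 0:
                row += A[di, :i]
            A[i, :i] = 0.5 * row
            A[:i, i] = A[i, :i]
    return RelationshipMatrix(A, list(ped.ids), kind="A")


def _mendelian_variance(F: np.ndarray, si: int, di: int) -> float:
    if si >= 0 and di >= 0:
        return 0.5 - 0.25 * (F[si] + F[di])
    if si >= 0:
        return 0.75 - 0.25 * F[si]
    if di >= 0:
        return 0.75 - 0.25 * F[di]
    return 1.0


def make_inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F (A_ii - 1) without building the full A.

    Per individual, the diagonal A_ii = sum_j L_ij^2 d_j is accumulated by
    walking the ancestor graph with the coefficients of the Cholesky factor
    L of A, where d_j is the Mendelian-sampling variance of ancestor j.
    """
    n = len(ped)
    s, d = ped.sire, ped.dam
    F = np.zeros(n)
    dvar = np.zeros(n)
    for i in range(n):
        dvar[i] = _mendelian_variance(F, s[i], d[i])
        if s[i] < 0 or d[i] < 0:
            continue  # unknown parent -> F = 0 by convention
        coeff: dict[int, float] = {i: 1.0}
        a_ii = 0.0
        for j in range(i, -1, -1):
            c = coeff.pop(j, 0.0)
            if c == 0.0:
                continue
            a_ii += c * c * dvar[j]
            half = 0.5 * c
            if s[j] >= 0:
                coeff[s[j]] = coeff.get(s[j], 0.0) + half
            if d[j] >= 0:
                coeff[d[j]] = coeff.get(d[j], 0.0) + half
        F[i] = a_ii - 1.0
        # d_i depends on parents only, but recompute in case F_i feeds later d
        dvar[i] = _mendelian_variance(F, s[i], d[i])
    return F


def make_A_inverse(ped: Pedigree) -> RelationshipMatrix:
    """A-inverse assembled from Henderson's rules with inbreeding."""
    n = len(ped)
    F = make_inbreeding(ped)
    Ainv = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        alpha = 1.0 / _mendelian_variance(F, s[i], d[i])
        Ainv[i, i] += alpha
        known = [p for p in (s[i], d[i]) if p >= 0]
        for p in known:
            Ainv[i, p] -= 0.5 * alpha
            Ainv[p, i] -= 0.5 * alpha
        for p in known:
            for q in known:
                Ainv[p, q] += 0.25 * alpha
    return RelationshipMatrix(Ainv, list(ped.ids), kind="A_inverse")
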