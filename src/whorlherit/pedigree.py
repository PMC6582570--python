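"""Pedigrees, inbreeding, and the numerator relationship matrix.

A pedigree is an ordered set of individuals with optional sire/dam links.
From it we compute inbreeding coefficients F, the dense numerator
relationship matrix A (tabular method), and the sparse inverse A^-1
(Henderson's rules, accounting for inbreeding) used by the mixed-model
Gibbs sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

#: sex codes accepted in pedigree files
SEXES = ("M", "F", "U")

#: tokens that denote an unknown parent in input files
UNKNOWN_TOKENS = ("", "0", ".", "NA")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, missing ids)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: id, parent links (None = unknown), and sex code."""

    individual_id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = "U"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PedigreeError(
                f"invalid sex code {self.sex!r} for {self.individual_id!r}; "
                f"expected one of {SEXES}"
            )


class Pedigree:
    """A validated, topologically sorted pedigree.

    Every parent precedes all of its offspring in ``records``; every
    non-unknown parent id is itself an individual in the pedigree.
    Construction validates uniqueness, referential closure, and acyclicity.
    """

    def __init__(self, records: Iterable[PedigreeRecord]):
        records = list(records)
        seen: set[str] = set()
        for rec in records:
            if rec.individual_id in seen:
                raise PedigreeError(f"duplicate individual id {rec.individual_id!r}")
            seen.add(rec.individual_id)
        for rec in records:
            for parent in (rec.sire_id, rec.dam_id):
                if parent is not None and parent not in seen:
                    raise PedigreeError(
                        f"parent {parent!r} of {rec.individual_id!r} is not in the pedigree"
                    )
        self.records: list[PedigreeRecord] = _topological_sort(records)
        self.order_index: dict[str, int] = {
            rec.individual_id: i for i, rec in enumerate(self.records)
        }
        # integer parent indices, -1 = unknown; parents always precede offspring
        self.sire_index = np.array(
            [
                -1 if r.sire_id is None else self.order_index[r.sire_id]
                for r in self.records
            ],
            dtype=np.int64,
        )
        self.dam_index = np.array(
            [
                -1 if r.dam_id is None else self.order_index[r.dam_id]
                for r in self.records
            ],
            dtype=np.int64,
        )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.order_index

    @property
    def ids(self) -> list[str]:
        return [rec.individual_id for rec in self.records]

    def record(self, individual_id: str) -> PedigreeRecord:
        return self.records[self.order_index[individual_id]]

    def is_founder(self, individual_id: str) -> bool:
        rec = self.record(individual_id)
        return rec.sire_id is None and rec.dam_id is None

    def sire_of(self, individual_id: str) -> str | None:
        return self.record(individual_id).sire_id

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [r.sire_id or "0" for r in self.records],
                "dam": [r.dam_id or "0" for r in self.records],
                "sex": [r.sex for r in self.records],
            }
        )


def _topological_sort(records: list[PedigreeRecord]) -> list[PedigreeRecord]:
    """Kahn's algorithm, stable with respect to input order; raises on cycles."""
    by_id = {r.individual_id: r for r in records}
    n_unsorted_parents = {
        r.individual_id: sum(p is not None for p in (r.sire_id, r.dam_id))
        for r in records
    }
    children: dict[str, list[str]] = {r.individual_id: [] for r in records}
    for r in records:
        for p in {r.sire_id, r.dam_id}:
            if p is not None:
                children[p].append(r.individual_id)
    ready = [r.individual_id for r in records if n_unsorted_parents[r.individual_id] == 0]
    out: list[PedigreeRecord] = []
    head = 0
    while head < len(ready):
        iid = ready[head]
        head += 1
        out.append(by_id[iid])
        for child in children[iid]:
            n_unsorted_parents[child] -= 1
            if n_unsorted_parents[child] == 0:
                ready.append(child)
    if len(out) != len(records):
        stuck = next(i for i, k in n_unsorted_parents.items() if k > 0)
        raise PedigreeError(f"cyclic ancestry detected involving {stuck!r}")
    return out


def _normalize_parent(token: object) -> str | None:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    token = str(token).strip()
    if token in UNKNOWN_TOKENS:
        return None
    return token


def read_pedigree(path, delimiter: str | None = None) -> Pedigree:
    """Read a pedigree from a delimited file with columns id, sire, dam, sex.

    Unknown parents may be encoded as an empty field or ``0``.  Parents that
    are referenced but never defined in the file are auto-inserted as
    founders (with a logged warning) — registry extracts routinely omit
    distant ancestors.  Row order need not be sorted.
    """
    df = pd.read_csv(
        path,
        sep=delimiter,
        engine="python" if delimiter is None else "c",
        dtype=str,
        keep_default_na=False,
    )
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"id", "sire", "dam", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file {path} lacks columns: {sorted(missing)}")
    records: list[PedigreeRecord] = []
    defined: set[str] = set()
    for row in df.itertuples(index=False):
        iid = str(row.id).strip()
        sex = str(row.sex).strip().upper() or "U"
        records.append(
            PedigreeRecord(iid, _normalize_parent(row.sire), _normalize_parent(row.dam), sex)
        )
        defined.add(iid)
    undefined: list[str] = []
    for rec in records:
        for parent, psex in ((rec.sire_id, "M"), (rec.dam_id, "F")):
            if parent is not None and parent not in defined:
                undefined.append(parent)
                defined.add(parent)
                records.append(PedigreeRecord(parent, None, None, psex))
    if undefined:
        logger.warning(
            "auto-inserted %d undefined parent(s) as founders: %s",
            len(undefined),
            ", ".join(undefined[:10]) + ("..." if len(undefined) > 10 else ""),
        )
    return Pedigree(records)


def trace_generations(ped: Pedigree, probands: Iterable[str], depth: int) -> Pedigree:
    """Sub-pedigree of ``probands`` plus ancestors within ``depth`` parent links.

    Parent links pointing outside the retained set are replaced by the
    unknown marker, so truncated individuals become founders.  Depth counts
    parent = 1, grandparent = 2, great-grandparent = 3.
    """
    probands = set(probands)
    if depth < 0:
        raise ValueError("depth must be non-negative")
    unknown = probands - set(ped.order_index)
    if unknown:
        raise PedigreeError(f"unknown proband id(s): {sorted(unknown)[:10]}")
    keep = set(probands)
    frontier = set(probands)
    for _ in range(depth):
        nxt: set[str] = set()
        for iid in frontier:
            rec = ped.record(iid)
            for parent in (rec.sire_id, rec.dam_id):
                if parent is not None and parent not in keep:
                    nxt.add(parent)
        if not nxt:
            break
        keep |= nxt
        frontier = nxt
    new_records = []
    for rec in ped.records:
        if rec.individual_id not in keep:
            continue
        sire = rec.sire_id if rec.sire_id in keep else None
        dam = rec.dam_id if rec.dam_id in keep else None
        new_records.append(PedigreeRecord(rec.individual_id, sire, dam, rec.sex))
    return Pedigree(new_records)


def _kinship(ped: Pedigree) -> "_KinshipCache":
    return _KinshipCache(ped.sire_index, ped.dam_index)


class _KinshipCache:
    """Memoized recursive kinship coefficients phi(i, j); a_ij = 2 phi_ij."""

    def __init__(self, sire: np.ndarray, dam: np.ndarray):
        self.sire = sire
        self.dam = dam
        self.cache: dict[tuple[int, int], float] = {}

    def phi(self, i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i < j:
            i, j = j, i
        key = (i, j)
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        if i == j:
            val = 0.5 * (1.0 + self.phi(self.sire[i], self.dam[i]))
        else:
            # i is topologically later, so neither parent of i can be i itself
            val = 0.5 * (self.phi(self.sire[i], j) + self.phi(self.dam[i], j))
        self.cache[key] = val
        return val


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-individual inbreeding coefficient F = kinship of the parents.

    F = 0 whenever either parent is unknown.
    """
    kin = _kinship(ped)
    n = len(ped)
    F = np.zeros(n)
    for i in range(n):
        s, d = ped.sire_index[i], ped.dam_index[i]
        if s >= 0 and d >= 0:
            F[i] = kin.phi(s, d)
    return F


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix A aligned to a pedigree ordering.

    ``values`` is symmetric with diagonal 1 + F; ``inbreeding`` holds F.
    """

    ids: list[str]
    values: np.ndarray
    inbreeding: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.inbreeding = np.asarray(self.inbreeding, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.values)


def numerator_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Dense A by the tabular (recursive) method.

    For individual i with parents s, d (in pedigree order, parents first):
    a_ii = 1 + 0.5 a_sd and a_ij = 0.5 (a_js + a_jd) for j < i; unknown
    parents contribute 0.
    """
    n = len(ped)
    s, d = ped.sire_index, ped.dam_index
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            row = 0.5 * (A[si, :i] + A[di, :i])
            aii = 1.0 + 0.5 * A[si, di]
        elif si >= 0:
            row = 0.5 * A[si, :i]
            aii = 1.0
        elif di >= 0:
            row = 0.5 * A[di, :i]
            aii = 1.0
        else:
            row = np.zeros(i)
            aii = 1.0
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = aii
    return RelationshipMatrix(ids=ped.ids, values=A, inbreeding=np.diag(A) - 1.0)


def sparse_a_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse A^-1 by Henderson's rules, with inbreeding.

    Contract-equivalent to inverting the dense tabular A, but never forms A;
    the Mendelian-sampling variance of individual i is
    0.5 - 0.25 (F_s + F_d) with both parents known, 0.75 - 0.25 F_p with one
    known parent p, and 1 for founders.
    """
    n = len(ped)
    F = inbreeding_coefficients(ped)
    s, d = ped.sire_index, ped.dam_index
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            mend = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0:
            mend = 0.75 - 0.25 * F[si]
        elif di >= 0:
            mend = 0.75 - 0.25 * F[di]
        else:
            mend = 1.0
        alpha = 1.0 / mend
        add(i, i, alpha)
        for p in (si, di):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
                add(p, p, 0.25 * alpha)
        if si >= 0 and di >= 0:
            add(si, di, 0.25 * alpha)
            add(di, si, 0.25 * alpha)
            # the 0.25*alpha diagonal terms were added once per parent above
    m = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    m.sum_duplicates()
    return m
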