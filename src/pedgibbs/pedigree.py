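"""Pedigree validation and additive-relationship algebra.

A pedigree is a set of (animal, sire, dam) triples.  After
:func:`validate_and_sort`, parents always precede offspring, which is the
precondition for the recursive algorithms: inbreeding coefficients
(Meuwissen–Luo), the dense numerator relationship matrix ``A`` (tabular
method) and its sparse inverse (Henderson's rules with inbreeding).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = -1

_SEXES = frozenset({"male", "female", "unknown"})


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass
class PedigreeTable:
    """Topologically ordered pedigree.

    ``sire`` and ``dam`` hold row indices into ``ids`` (``-1`` = unknown
    parent).  Instances produced by :func:`validate_and_sort` satisfy
    ``sire[i] < i`` and ``dam[i] < i`` for every animal ``i``.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray
    sex: np.ndarray
    is_sorted: bool = False
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        """Row indices for a sequence of animal identifiers."""
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from None

    def to_frame(self) -> pd.DataFrame:
        sire = np.where(self.sire >= 0, self.ids[np.maximum(self.sire, 0)], "")
        dam = np.where(self.dam >= 0, self.ids[np.maximum(self.dam, 0)], "")
        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": sire,
                "dam": dam,
                "birth_year": self.birth_year,
                "sex": self.sex,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PedigreeTable":
        """Build an (unsorted) table from a data frame.

        Expected columns: ``animal``, ``sire``, ``dam`` and optionally
        ``birth_year`` and ``sex``.  Empty strings, ``"0"``, ``0`` and NA
        denote unknown parents.
        """
        required = {"animal", "sire", "dam"}
        missing = required - set(frame.columns)
        if missing:
            raise PedigreeError(f"pedigree frame missing columns: {sorted(missing)}")
        ids = frame["animal"].astype(str).to_numpy()
        n = len(ids)

        def _clean(col: pd.Series) -> list[str | None]:
            out = []
            for v in col:
                if pd.isna(v):
                    out.append(None)
                    continue
                s = str(v).strip()
                out.append(None if s in ("", "0", "0.0") else s)
            return out

        sires = _clean(frame["sire"])
        dams = _clean(frame["dam"])
        if "birth_year" in frame.columns:
            by = pd.to_numeric(frame["birth_year"], errors="coerce").fillna(0)
            birth_year = by.astype(np.int64).to_numpy()
        else:
            birth_year = np.zeros(n, dtype=np.int64)
        if "sex" in frame.columns:
            sex = frame["sex"].astype(str).str.strip().str.lower().to_numpy()
            sex = np.where(np.isin(sex, list(_SEXES)), sex, "unknown")
        else:
            sex = np.full(n, "unknown", dtype=object)

        lookup: dict[str, int] = {}
        for i, a in enumerate(ids):
            if a in lookup:
                raise PedigreeError(f"duplicate animal_id {a!r}")
            lookup[a] = i

        def _idx(parents: list[str | None]) -> np.ndarray:
            return np.array(
                [UNKNOWN if p is None else lookup.get(p, -2) for p in parents],
                dtype=np.int64,
            )

        # -2 marks a phantom parent; resolved in validate_and_sort
        sire_idx = _idx(sires)
        dam_idx = _idx(dams)
        table = cls(
            ids=np.asarray(ids, dtype=object),
            sire=sire_idx,
            dam=dam_idx,
            birth_year=birth_year,
            sex=np.asarray(sex, dtype=object),
        )
        table.meta["raw_sire"] = sires
        table.meta["raw_dam"] = dams
        return table


def _as_table(ped) -> PedigreeTable:
    if isinstance(ped, PedigreeTable):
        return ped
    if isinstance(ped, pd.DataFrame):
        return PedigreeTable.from_frame(ped)
    raise TypeError(f"cannot interpret {type(ped).__name__} as a pedigree")


def validate_and_sort(ped) -> PedigreeTable:
    """Normalize, validate and topologically sort a pedigree.

    Unknown parents become the ``-1`` sentinel.  Parents referenced but not
    listed (phantoms) are materialized as founders with unknown birth year
    and sex.  Output order is deterministic: a parent always precedes its
    offspring, ties broken by ``(birth_year, animal_id)``.

    Raises
    ------
    PedigreeError
        On duplicate identifiers or a cycle in the parentage graph (the
        message names an animal on the cycle).
    """
    table = _as_table(ped)

    ids = list(table.ids)
    sires = table.meta.get("raw_sire")
    dams = table.meta.get("raw_dam")
    if sires is None:
        sires = [None if s < 0 else ids[s] for s in table.sire]
        dams = [None if d < 0 else ids[d] for d in table.dam]
    birth_year = list(table.birth_year)
    sex = list(table.sex)

    known = set(ids)
    phantoms = []
    for p in list(sires) + list(dams):
        if p is not None and p not in known:
            known.add(p)
            phantoms.append(p)
    for p in sorted(phantoms):
        ids.append(p)
        sires.append(None)
        dams.append(None)
        birth_year.append(0)
        sex.append("unknown")

    n = len(ids)
    lookup = {a: i for i, a in enumerate(ids)}
    sire_idx = [UNKNOWN if p is None else lookup[p] for p in sires]
    dam_idx = [UNKNOWN if p is None else lookup[p] for p in dams]

    # Kahn's algorithm with a deterministic (birth_year, id) ready-queue.
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = [0] * n
    for i in range(n):
        for p in (sire_idx[i], dam_idx[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    ready = [(birth_year[i], ids[i], i) for i in range(n) if indeg[i] == 0]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        _, _, i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, (birth_year[c], ids[c], c))
    if len(order) < n:
        stuck = next(ids[i] for i in range(n) if indeg[i] > 0)
        raise PedigreeError(f"cycle in parentage involving animal {stuck!r}")

    new_pos = {old: new for new, old in enumerate(order)}
    return PedigreeTable(
        ids=np.array([ids[i] for i in order], dtype=object),
        sire=np.array(
            [UNKNOWN if sire_idx[i] < 0 else new_pos[sire_idx[i]] for i in order],
            dtype=np.int64,
        ),
        dam=np.array(
            [UNKNOWN if dam_idx[i] < 0 else new_pos[dam_idx[i]] for i in order],
            dtype=np.int64,
        ),
        birth_year=np.array([birth_year[i] for i in order], dtype=np.int64),
        sex=np.array([sex[i] for i in order], dtype=object),
        is_sorted=True,
    )


def _require_sorted(ped: PedigreeTable) -> None:
    if not ped.is_sorted:
        raise PedigreeError("pedigree must pass validate_and_sort first")


def mendelian_variance_scale(ped: PedigreeTable, F: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian-sampling) variance scale ``d_i``.

    ``0.5 - 0.25 (F_s + F_d)`` with both parents known,
    ``0.75 - 0.25 F_p`` with one, and ``1`` for founders.
    """
    _require_sorted(ped)
    # F of an unknown parent enters as -1, which folds the three cases
    # into the two-parent formula.
    fs = np.where(ped.sire >= 0, F[np.maximum(ped.sire, 0)], -1.0)
    fd = np.where(ped.dam >= 0, F[np.maximum(ped.dam, 0)], -1.0)
    return 0.5 - 0.25 * (fs + fd)


def compute_inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Per-animal inbreeding coefficients via the Meuwissen–Luo recursion.

    Equals ``diag(A) - 1`` of the tabular relationship matrix but runs in
    roughly linear time for shallow pedigrees.
    """
    _require_sorted(ped)
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 or d < 0:
            continue  # F stays 0
        # trace a_ii = sum_j L_j^2 D_j over ancestors, descending index
        coeff = {i: 1.0}
        heap = [-i]
        in_heap = {i}
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = coeff.pop(j)
            in_heap.discard(j)
            a_ii += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    coeff[p] = coeff.get(p, 0.0) + 0.5 * lj
                    if p not in in_heap:
                        heapq.heappush(heap, -p)
                        in_heap.add(p)
        F[i] = a_ii - 1.0
    return F


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix with its animal ordering."""

    order: np.ndarray
    values: np.ndarray
    inbreeding: np.ndarray

    @property
    def n(self) -> int:
        return len(self.order)


def build_A(ped: PedigreeTable, max_order: int = 3000) -> RelationshipMatrix:
    """Dense ``A`` by the tabular method.

    ``a_ij = 0.5 (a_{j,s(i)} + a_{j,d(i)})`` for ``j < i`` and
    ``a_ii = 1 + 0.5 a_{s(i),d(i)}``; unknown-parent terms are zero.
    """
    _require_sorted(ped)
    n = ped.n
    if n > max_order:
        raise PedigreeError(
            f"pedigree of {n} animals exceeds the dense cap ({max_order}); "
            "use build_A_inverse for the sampler instead"
        )
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(order=ped.ids.copy(), values=A, inbreeding=np.diag(A) - 1.0)


def build_A_inverse(ped: PedigreeTable, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse ``A^{-1}`` by Henderson's rules, accounting for inbreeding."""
    _require_sorted(ped)
    if F is None:
        F = compute_inbreeding(ped)
    F = np.asarray(F, dtype=float)
    if F.shape != (ped.n,):
        raise PedigreeError(
            f"inbreeding vector of length {F.shape} does not match pedigree of {ped.n}"
        )
    d = mendelian_variance_scale(ped, F)
    alpha = 1.0 / d
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(ped.n):
        a = alpha[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        add(i, i, a)
        for p in parents:
            add(i, p, -0.5 * a)
            add(p, i, -0.5 * a)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * a)
    out = sparse.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n)).tocsr()
    out.sum_duplicates()
    return out


def count_generations(
    ped: PedigreeTable, evaluated=None
) -> tuple[np.ndarray, float]:
    """Complete-generation depth per animal and its mean over a subset.

    Depth is the number of fully known ancestral generations: founders are
    0, an animal with one unknown parent is 0, and otherwise depth is
    ``1 + min(depth_sire, depth_dam)``.
    """
    _require_sorted(ped)
    depth = np.zeros(ped.n, dtype=np.int64)
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        ds = depth[s] if s >= 0 else -1
        dd = depth[d] if d >= 0 else -1
        depth[i] = 1 + min(ds, dd)
    if evaluated is None:
        idx = np.arange(ped.n)
    else:
        idx = ped.index_of(evaluated)
    return depth, float(depth[idx].mean()) if len(idx) else float("nan")
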