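"""Pedigree parsing, inbreeding, and numerator-relationship matrices.

The pedigree is the backbone of every single-step evaluation: it supplies the
sparse inverse numerator relationship matrix A^-1 over all animals and the
dense block A22 over the genotyped subset.  Animals are identified by opaque
string ids; after topological renumbering all matrices are indexed by integer
position, with the id <-> index map carried on the :class:`Pedigree`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import _kernels

logger = logging.getLogger(__name__)

#: tokens interpreted as "parent unknown" by default
DEFAULT_UNKNOWN_CODES = frozenset({"0", "", "NA", "na", ".", "nan"})


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, conflicting duplicate, ...)."""


@dataclass
class Pedigree:
    """Topologically renumbered pedigree.

    ``ids[i]`` is the id of the animal at index ``i``; every parent index in
    ``sire``/``dam`` is smaller than its offspring's index or -1 (unknown).
    Unknown parents are treated as draws from a single unrelated, non-inbred
    base population (no genetic groups).
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    _f: np.ndarray | None = field(default=None, repr=False)
    _index: dict[str, int] | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        if self._index is None:
            self._index = {a: i for i, a in enumerate(self.ids)}
        return self._index

    @property
    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficient F (computed lazily, cached)."""
        if self._f is None:
            self._f = compute_inbreeding(self)
        return self._f

    def indices_of(self, animal_ids) -> np.ndarray:
        idx = self.index
        try:
            return np.array([idx[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise KeyError(f"animal id {exc.args[0]!r} not in pedigree") from None

    def founders(self) -> np.ndarray:
        return np.flatnonzero((self.sire < 0) & (self.dam < 0))


def _find_cycle(parents: dict[str, tuple[str | None, str | None]]) -> list[str]:
    """Return one directed cycle (as an id list) in the parent graph."""
    WHITE, GREY, BLACK = 0, 1, 2
    color = {a: WHITE for a in parents}
    stack_path: list[str] = []

    def visit(a: str) -> list[str] | None:
        color[a] = GREY
        stack_path.append(a)
        for p in parents[a]:
            if p is None or p not in parents:
                continue
            if color[p] == GREY:
                return stack_path[stack_path.index(p):] + [p]
            if color[p] == WHITE:
                cyc = visit(p)
                if cyc is not None:
                    return cyc
        stack_path.pop()
        color[a] = BLACK
        return None

    for a in parents:
        if color[a] == WHITE:
            cyc = visit(a)
            if cyc is not None:
                return cyc
    return []


def from_records(
    records,
    unknown_codes=DEFAULT_UNKNOWN_CODES,
) -> Pedigree:
    """Build a renumbered :class:`Pedigree` from (animal, sire, dam) triples."""
    unknown = set(unknown_codes)
    parents: dict[str, tuple[str | None, str | None]] = {}
    order_seen: list[str] = []
    for row in records:
        animal, s, d = (str(x).strip() for x in row[:3])
        s_ = None if s in unknown else s
        d_ = None if d in unknown else d
        if animal in unknown:
            raise PedigreeError(f"animal id {animal!r} is an unknown-parent token")
        if animal in parents:
            if parents[animal] != (s_, d_):
                raise PedigreeError(
                    f"duplicate animal {animal!r} with conflicting parents "
                    f"{parents[animal]} vs {(s_, d_)}"
                )
            continue
        parents[animal] = (s_, d_)
        order_seen.append(animal)
    # implicit founders for ids appearing only as parents
    implicit = []
    for a, (s, d) in list(parents.items()):
        for p in (s, d):
            if p is not None and p not in parents:
                parents[p] = (None, None)
                order_seen.append(p)
                implicit.append(p)
    if implicit:
        logger.info("added %d implicit founder records: %s%s",
                    len(implicit), ", ".join(implicit[:5]),
                    "..." if len(implicit) > 5 else "")
    if any(a in parents[a] for a in parents):
        bad = next(a for a in parents if a in parents[a])
        raise PedigreeError(f"cycle detected: {bad} -> {bad}")

    # keep the input order when it is already topological (stability: writing
    # and re-reading a pedigree must not permute it); otherwise Kahn-sort
    seen_at = {a: i for i, a in enumerate(order_seen)}
    already_sorted = all(
        all(p is None or seen_at[p] < seen_at[a] for p in parents[a])
        for a in order_seen
    )
    if already_sorted:
        order = order_seen
        idx = seen_at
        sire = np.full(len(order), -1, dtype=np.int64)
        dam = np.full(len(order), -1, dtype=np.int64)
        for a, (s, d) in parents.items():
            i = idx[a]
            if s is not None:
                sire[i] = idx[s]
            if d is not None:
                dam[i] = idx[d]
        return Pedigree(ids=order, sire=sire, dam=dam)

    # Kahn topological sort (parents before offspring), stable in input order
    n_unresolved = {a: sum(p is not None for p in ps) for a, ps in parents.items()}
    children: dict[str, list[str]] = {a: [] for a in parents}
    for a, (s, d) in parents.items():
        for p in (s, d):
            if p is not None:
                children[p].append(a)
    ready = [a for a in order_seen if n_unresolved[a] == 0]
    order: list[str] = []
    head = 0
    resolved_parents: dict[str, int] = dict(n_unresolved)
    while head < len(ready):
        a = ready[head]
        head += 1
        order.append(a)
        for c in children[a]:
            resolved_parents[c] -= 1
            if resolved_parents[c] == 0:
                ready.append(c)
    if len(order) != len(parents):
        cyc = _find_cycle(parents)
        raise PedigreeError("cycle detected: " + " -> ".join(cyc))

    idx = {a: i for i, a in enumerate(order)}
    sire = np.full(len(order), -1, dtype=np.int64)
    dam = np.full(len(order), -1, dtype=np.int64)
    for a, (s, d) in parents.items():
        i = idx[a]
        if s is not None:
            sire[i] = idx[s]
        if d is not None:
            dam[i] = idx[d]
    return Pedigree(ids=order, sire=sire, dam=dam)


def read_pedigree(
    path,
    unknown_codes=DEFAULT_UNKNOWN_CODES,
    sep: str | None = None,
    header: bool | None = None,
) -> Pedigree:
    """Read a pedigree from a CSV or whitespace table (animal, sire, dam).

    ``sep=None`` sniffs commas vs whitespace from the first line; ``header=None``
    drops a first row whose cells look like column names (non-numeric and not
    reappearing as ids).
    """
    with open(path) as fh:
        first = fh.readline()
    if sep is None:
        sep = "," if "," in first else r"\s+"
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#",
                     skip_blank_lines=True, engine="python")
    if df.shape[1] < 3:
        raise PedigreeError(
            f"pedigree file needs >=3 columns (animal, sire, dam); got {df.shape[1]}"
        )
    if header is None:
        head = [str(x).strip().lower() for x in df.iloc[0, :3]]
        header = any(h in {"animal", "id", "animal_id", "sire", "dam"} for h in head)
    if header:
        df = df.iloc[1:]
    df = df.fillna("")
    return from_records(df.iloc[:, :3].itertuples(index=False, name=None),
                        unknown_codes=unknown_codes)


# ---------------------------------------------------------------------------
# kinship computations
# ---------------------------------------------------------------------------


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Exact inbreeding coefficients (Meuwissen & Luo style recursion)."""
    return _kernels.meuwissen_luo_inbreeding(ped.sire, ped.dam)


def tabular_a(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method."""
    return _kernels.tabular_a(ped.sire, ped.dam)


def build_a_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Only the animal/sire/dam triples contribute non-zeros.  The within-family
    variance uses F=-1 for unknown parents, which reproduces the textbook
    coefficients for 0, 1 or 2 known parents.
    """
    f = ped.inbreeding
    n = ped.n
    cap = 9 * n
    rows = np.empty(cap, dtype=np.int64)
    cols = np.empty(cap, dtype=np.int64)
    vals = np.empty(cap, dtype=np.float64)
    k = 0

    def add(i, j, v):
        nonlocal k
        rows[k] = i
        cols[k] = j
        vals[k] = v
        k += 1

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        fs = f[s] if s >= 0 else -1.0
        fd = f[d] if d >= 0 else -1.0
        b = 0.5 - 0.25 * (fs + fd)
        al = 1.0 / b
        add(i, i, al)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * al)
                add(p, i, -0.5 * al)
                add(p, p, 0.25 * al)
        if s >= 0 and d >= 0:
            add(s, d, 0.25 * al)
            add(d, s, 0.25 * al)
    a_inv = sp.coo_matrix((vals[:k], (rows[:k], cols[:k])), shape=(n, n))
    return a_inv.tocsr()


def ancestor_closure(ped: Pedigree, indices) -> np.ndarray:
    """Sorted indices of the given animals plus all their known ancestors."""
    seen = set()
    stack = list(int(i) for i in indices)
    while stack:
        i = stack.pop()
        if i in seen:
            continue
        seen.add(i)
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0 and p not in seen:
                stack.append(int(p))
    return np.array(sorted(seen), dtype=np.int64)


def build_a22(ped: Pedigree, genotyped_ids) -> np.ndarray:
    """Dense numerator relationships among the genotyped animals.

    Computed by the tabular method on the genotyped animals' ancestor closure
    (exact), then subset to the genotyped animals in the order given.
    """
    g_idx = ped.indices_of(genotyped_ids)
    closure = ancestor_closure(ped, g_idx)
    pos = {int(j): k for k, j in enumerate(closure)}
    sub_sire = np.array(
        [pos.get(int(ped.sire[j]), -1) for j in closure], dtype=np.int64
    )
    sub_dam = np.array(
        [pos.get(int(ped.dam[j]), -1) for j in closure], dtype=np.int64
    )
    a_sub = _kernels.tabular_a(sub_sire, sub_dam)
    sel = np.array([pos[int(j)] for j in g_idx], dtype=np.int64)
    return a_sub[np.ix_(sel, sel)]


def equivalent_generations(ped: Pedigree) -> np.ndarray:
    """Pedigree completeness: EqG(i) = sum over known ancestors of (1/2)^depth.

    Founders score 0; an animal with both parents known founders scores 1.
    """
    eqg = np.zeros(ped.n)
    for i in range(ped.n):
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                eqg[i] += 0.5 * (1.0 + eqg[p])
    return eqg


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------


def write_sparse_coordinate(matrix, ids, path) -> None:
    """Write the upper triangle as whitespace ``i j value`` text with an
    ``# id`` header block mapping indices to animal ids."""
    coo = sp.coo_matrix(matrix)
    with open(path, "w") as fh:
        for i, a in enumerate(ids):
            fh.write(f"# {i} {a}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if j >= i:
                fh.write(f"{i} {j} {float(v)!r}\n")


def save_matrix_bundle(path, **named) -> None:
    """Persist matrices plus id arrays in one indexed binary (npz) container."""
    arrays = {}
    for key, val in named.items():
        if sp.issparse(val):
            coo = val.tocoo()
            arrays[f"{key}__row"] = coo.row
            arrays[f"{key}__col"] = coo.col
            arrays[f"{key}__data"] = coo.data
            arrays[f"{key}__shape"] = np.array(coo.shape)
        elif isinstance(val, (list, tuple)) and val and isinstance(val[0], str):
            arrays[key] = np.array(val, dtype=object).astype(str)
        else:
            arrays[key] = np.asarray(val)
    np.savez_compressed(path, **arrays)


def load_matrix_bundle(path) -> dict:
    """Inverse of :func:`save_matrix_bundle`."""
    raw = dict(np.load(path, allow_pickle=False))
    out: dict = {}
    sparse_keys = {k[: -len("__row")] for k in raw if k.endswith("__row")}
    for key in sparse_keys:
        shape = tuple(raw.pop(f"{key}__shape"))
        out[key] = sp.coo_matrix(
            (raw.pop(f"{key}__data"), (raw.pop(f"{key}__row"), raw.pop(f"{key}__col"))),
            shape=shape,
        ).tocsr()
    out.update(raw)
    return out
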