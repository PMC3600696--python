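"""Pedigree parsing, validation, and additive-relationship machinery.

The additive (numerator) relationship matrix A collects the expected
proportions of additive genetic effects shared between pedigree members:
``a_ii = 1 + F_i`` (F the inbreeding coefficient) and, for j preceding i,
``a_ij = 0.5 * (a_{j,sire(i)} + a_{j,dam(i)})`` with unknown parents
contributing zero.  Its sparse inverse is assembled directly from
Mendelian-sampling variances (Henderson's rules, with inbreeding).
"""

from __future__ import annotations

import dataclasses
from collections import deque
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = -1
#: tokens interpreted as "parent unknown" in pedigree files
UNKNOWN_TOKENS = {"", "0", "na", "nan", "none", ".", None}

CANONICAL_COLUMNS = ("animal", "sire", "dam", "sex", "generation", "line")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, ...)."""


@dataclasses.dataclass
class Pedigree:
    """A validated pedigree in topological (parents-first) order.

    ``sire`` / ``dam`` hold positional indices into ``ids`` (``-1`` for an
    unknown parent).  ``input_order`` records, for each animal in the current
    order, its position in the original source so file order is recoverable.
    """

    ids: np.ndarray          # dtype=object, topologically ordered
    sire: np.ndarray         # int indices into ids, -1 unknown
    dam: np.ndarray
    sex: np.ndarray          # {"M","F","unknown"}
    generation: np.ndarray   # {"F0","F1","F2","unknown"}
    line: np.ndarray         # breed/line token or "unknown"
    input_order: np.ndarray  # original positions

    _inbreeding: np.ndarray | None = dataclasses.field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        for arr in (self.sire, self.dam, self.sex, self.generation,
                    self.line, self.input_order):
            if len(arr) != n:
                raise PedigreeError("pedigree field lengths disagree")
        for i in range(n):
            for p in (self.sire[i], self.dam[i]):
                if p >= i:
                    raise PedigreeError(
                        f"parent of {self.ids[i]!r} does not precede it")

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return self.n

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    @property
    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficient F (founders 0), cached."""
        if self._inbreeding is None:
            self._inbreeding = inbreeding_coefficients(self)
        return self._inbreeding

    def index_of(self, ids: Iterable) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"animal {exc.args[0]!r} not in pedigree") from None

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular form (unknown parents coded '0')."""
        def par(idx):
            return ["0" if p == UNKNOWN else str(self.ids[p]) for p in idx]

        return pd.DataFrame({
            "animal": [str(a) for a in self.ids],
            "sire": par(self.sire),
            "dam": par(self.dam),
            "sex": self.sex,
            "generation": self.generation,
            "line": self.line,
        })


def _order_records(records: list[tuple]) -> list[int]:
    """Stable topological order (Kahn's algorithm, ties by input order)."""
    n = len(records)
    ids = [r[0] for r in records]
    pos = {a: i for i, a in enumerate(ids)}
    indeg = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, (_aid, s, d, *_rest) in enumerate(records):
        for p in (s, d):
            if p is not None:
                j = pos[p]
                indeg[i] += 1
                children[j].append(i)
    queue = deque(i for i in range(n) if indeg[i] == 0)
    order: list[int] = []
    while queue:
        i = queue.popleft()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        member = ids[next(i for i in range(n) if indeg[i] > 0)]
        raise PedigreeError(
            f"pedigree contains a cycle involving animal {member!r}")
    # Kahn with a FIFO queue seeded in input order is already stable.
    return order


def pedigree_from_records(
    records: Sequence[tuple],
    auto_add_founders: bool = False,
) -> Pedigree:
    """Build a validated, ordered :class:`Pedigree`.

    Each record is ``(animal, sire, dam, sex, generation, line)`` where the
    last three may be omitted; parent tokens in :data:`UNKNOWN_TOKENS` mean
    unknown.  With ``auto_add_founders`` parents never listed as animals are
    appended as founder records instead of raising.
    """
    def norm_parent(tok):
        if tok in UNKNOWN_TOKENS:
            return None
        tok = str(tok).strip()
        return None if tok.lower() in UNKNOWN_TOKENS else tok

    full = []
    seen = set()
    for rec in records:
        aid = str(rec[0]).strip()
        if aid in UNKNOWN_TOKENS:
            raise PedigreeError(f"invalid animal id {rec[0]!r}")
        if aid in seen:
            raise PedigreeError(f"duplicate animal id {aid!r}")
        seen.add(aid)
        s = norm_parent(rec[1]) if len(rec) > 1 else None
        d = norm_parent(rec[2]) if len(rec) > 2 else None
        sex = str(rec[3]) if len(rec) > 3 and rec[3] not in UNKNOWN_TOKENS else "unknown"
        gen = str(rec[4]) if len(rec) > 4 and rec[4] not in UNKNOWN_TOKENS else "unknown"
        line = str(rec[5]) if len(rec) > 5 and rec[5] not in UNKNOWN_TOKENS else "unknown"
        if s == aid or d == aid:
            raise PedigreeError(
                f"pedigree contains a cycle involving animal {aid!r}")
        full.append((aid, s, d, sex, gen, line))

    known = {r[0] for r in full}
    missing = []
    for _aid, s, d, *_ in full:
        for p in (s, d):
            if p is not None and p not in known and p not in missing:
                missing.append(p)
    if missing:
        if not auto_add_founders:
            raise PedigreeError(
                f"parent id(s) never defined as animals: {missing[:5]}")
        for p in missing:
            full.insert(0, (p, None, None, "unknown", "unknown", "unknown"))

    order = _order_records(full)
    ordered = [full[i] for i in order]
    pos = {r[0]: i for i, r in enumerate(ordered)}
    n = len(ordered)
    sire = np.array([UNKNOWN if r[1] is None else pos[r[1]] for r in ordered])
    dam = np.array([UNKNOWN if r[2] is None else pos[r[2]] for r in ordered])
    return Pedigree(
        ids=np.array([r[0] for r in ordered], dtype=object),
        sire=sire,
        dam=dam,
        sex=np.array([r[3] for r in ordered], dtype=object),
        generation=np.array([r[4] for r in ordered], dtype=object),
        line=np.array([r[5] for r in ordered], dtype=object),
        input_order=np.array(order),
    )


def read_pedigree(
    path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
    auto_add_founders: bool = False,
) -> Pedigree:
    """Read a pedigree CSV/TSV (header required).

    ``dialect`` maps canonical names (``animal``, ``sire``, ``dam``, and
    optionally ``sex``, ``generation``, ``line``) to the file's column names.
    Separator is sniffed from the extension unless given.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    dialect = dict(dialect or {})
    cols = {c: dialect.get(c, c) for c in CANONICAL_COLUMNS}
    for required in ("animal", "sire", "dam"):
        if cols[required] not in df.columns:
            raise PedigreeError(
                f"column {cols[required]!r} (for {required}) not in file")
    recs = []
    for _, row in df.iterrows():
        recs.append(tuple(
            row[cols[c]] if cols[c] in df.columns else None
            for c in CANONICAL_COLUMNS))
    return pedigree_from_records(recs, auto_add_founders=auto_add_founders)


def write_pedigree(ped: Pedigree, path, sep: str = ",") -> None:
    """Write the canonical column order (animal,sire,dam,sex,generation,line)."""
    ped.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# relationship matrices


@dataclasses.dataclass
class RelationshipMatrix:
    """Additive relationships among ``ids``: dense ``A`` and/or sparse ``Ainv``."""

    ids: np.ndarray
    A: np.ndarray | None = None
    Ainv: sparse.csr_matrix | None = None


def additive_relationship_matrix(
    ped: Pedigree, max_animals: int = 5000
) -> RelationshipMatrix:
    """Dense A by the tabular (recursive) method.

    Refuses to build a dense matrix for pedigrees above ``max_animals``.
    """
    n = ped.n
    if n > max_animals:
        raise MemoryError(
            f"dense A for {n} animals exceeds the ceiling of {max_animals}; "
            "raise max_animals explicitly if this is intended")
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        row = np.zeros(i)
        if si != UNKNOWN:
            row += A[si, :i]
        if di != UNKNOWN:
            row += A[di, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        aii = 1.0
        if si != UNKNOWN and di != UNKNOWN:
            aii += 0.5 * A[si, di]
        A[i, i] = aii
    return RelationshipMatrix(ids=ped.ids.copy(), A=A)


def inbreeding_coefficients(ped: Pedigree, method: str = "tabular") -> np.ndarray:
    """Per-animal F: half the additive relationship between the parents.

    ``tabular`` reads F off the diagonal of the tabular A (exact, O(n^2));
    ``meuwissen-luo`` uses the Meuwissen & Luo recursion (O(n * depth^2)),
    avoiding the dense matrix.
    """
    if method == "tabular":
        A = additive_relationship_matrix(ped, max_animals=10**9).A
        return np.diag(A) - 1.0
    if method != "meuwissen-luo":
        raise ValueError(f"unknown inbreeding method {method!r}")

    n = ped.n
    s, d = ped.sire, ped.dam
    F = np.zeros(n)
    # F only accrues when both parents are known; a_ii of a virtual offspring
    # equals sum_j c_j^2 v_j over ancestors (c the gene-contribution vector,
    # v the Mendelian-sampling variance), and that sum expands to
    # 0.25 (a_ss + a_dd) + 0.5 a_sd = 0.5 + 0.25 (F_s + F_d) + F_i.
    for i in range(n):
        if s[i] == UNKNOWN or d[i] == UNKNOWN:
            continue
        contrib = np.zeros(n)
        contrib[s[i]] += 0.5
        contrib[d[i]] += 0.5
        acc = 0.0
        for j in range(i - 1, -1, -1):
            cj = contrib[j]
            if cj == 0.0:
                continue
            sj, dj = s[j], d[j]
            if sj != UNKNOWN and dj != UNKNOWN:
                vj = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj != UNKNOWN or dj != UNKNOWN:
                p = sj if sj != UNKNOWN else dj
                vj = 0.75 - 0.25 * F[p]
            else:
                vj = 1.0
            acc += cj * cj * vj
            if sj != UNKNOWN:
                contrib[sj] += 0.5 * cj
            if dj != UNKNOWN:
                contrib[dj] += 0.5 * cj
        F[i] = acc - 0.5 - 0.25 * (F[s[i]] + F[d[i]])
    return F


def mendelian_sampling_variances(ped: Pedigree) -> np.ndarray:
    """d_i used by Henderson's inverse: 0.5 - 0.25(F_s + F_d) (both parents),
    0.75 - 0.25 F_p (one parent), 1 (founder)."""
    F = ped.inbreeding
    s, d = ped.sire, ped.dam
    out = np.ones(ped.n)
    both = (s != UNKNOWN) & (d != UNKNOWN)
    out[both] = 0.5 - 0.25 * (F[s[both]] + F[d[both]])
    one_s = (s != UNKNOWN) & (d == UNKNOWN)
    out[one_s] = 0.75 - 0.25 * F[s[one_s]]
    one_d = (s == UNKNOWN) & (d != UNKNOWN)
    out[one_d] = 0.75 - 0.25 * F[d[one_d]]
    if np.any(out <= 0):
        raise RuntimeError("non-positive Mendelian sampling variance; "
                           "pedigree inbreeding is inconsistent")
    return out


def a_inverse(ped: Pedigree, method: str = "henderson") -> RelationshipMatrix:
    """Sparse A^-1 assembled per animal from Mendelian-sampling variances.

    For each animal i with parent index set P (weights 1 for i, -0.5 per
    known parent), add ``(1/d_i) * w w'`` on the pattern {i} ∪ P.
    ``method`` selects how inbreeding is computed ("henderson" = tabular F,
    "meuwissen-luo" = M&L recursion); the assembly rules are identical.
    """
    if method not in ("henderson", "meuwissen-luo"):
        raise ValueError(f"unknown a_inverse method {method!r}")
    if method == "meuwissen-luo" and ped._inbreeding is None:
        ped._inbreeding = inbreeding_coefficients(ped, method="meuwissen-luo")
    dvec = mendelian_sampling_variances(ped)
    rows, cols, vals = [], [], []
    s, d = ped.sire, ped.dam
    for i in range(ped.n):
        members = [(i, 1.0)]
        if s[i] != UNKNOWN:
            members.append((s[i], -0.5))
        if d[i] != UNKNOWN:
            members.append((d[i], -0.5))
        inv_d = 1.0 / dvec[i]
        for j, wj in members:
            for k, wk in members:
                rows.append(j)
                cols.append(k)
                vals.append(wj * wk * inv_d)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n)).tocsr()
    return RelationshipMatrix(ids=ped.ids.copy(), Ainv=Ainv)


def prune_to_phenotyped(ped: Pedigree, ids: Iterable) -> Pedigree:
    """Sub-pedigree of ``ids`` plus all their ancestors, order preserved.

    Idempotent and monotone in ``ids``.
    """
    ids = list(ids)
    keep_idx = set(ped.index_of(ids))
    stack = list(keep_idx)
    while stack:
        i = stack.pop()
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN and p not in keep_idx:
                keep_idx.add(p)
                stack.append(p)
    sel = sorted(keep_idx)
    old_to_new = {o: nnew for nnew, o in enumerate(sel)}

    def remap(par):
        return np.array([
            UNKNOWN if par[o] == UNKNOWN else old_to_new[par[o]] for o in sel])

    return Pedigree(
        ids=ped.ids[sel].copy(),
        sire=remap(ped.sire),
        dam=remap(ped.dam),
        sex=ped.sex[sel].copy(),
        generation=ped.generation[sel].copy(),
        line=ped.line[sel].copy(),
        input_order=ped.input_order[sel].copy(),
    )
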