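"""Pedigree container and relationship algebra.

Provides the parentage structure used throughout the screen: maternal-grandsire
lookup for the mating-based depletion test, Meuwissen & Luo inbreeding
coefficients, and the sparse inverse of the numerator relationship matrix A
(Henderson's rules, optionally with the Quaas adjustment for inbred parents)
needed by the liability threshold model.

Unknown parents are treated as unrelated base-population founders with F = 0;
no unknown-parent groups are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = "0"

_UNKNOWN_TOKENS = {"", "0", ".", "NA", "nan", "None"}


def _norm_id(x) -> str:
    """Normalise an animal id to a string; unknown markers collapse to UNKNOWN."""
    if x is None:
        return UNKNOWN
    s = str(x).strip()
    if s in _UNKNOWN_TOKENS:
        return UNKNOWN
    # pandas may read integer ids as floats ("123.0")
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


class PedigreeError(ValueError):
    """Raised for cyclic, duplicated or otherwise invalid pedigrees."""


@dataclass
class RelationshipFactors:
    """Inbreeding and sparse A-inverse for a pedigree.

    Attributes
    ----------
    ids : list of animal ids in the order used for matrix indices.
    inbreeding : F per animal, same order.
    a_inverse : scipy CSR matrix, symmetric positive definite.
    mendelian_variance : the d_i (Mendelian sampling variance) per animal.
    """

    ids: list
    inbreeding: np.ndarray
    a_inverse: sparse.csr_matrix
    mendelian_variance: np.ndarray

    def to_triplets(self) -> pd.DataFrame:
        coo = self.a_inverse.tocoo()
        return pd.DataFrame(
            {
                "row": [self.ids[i] for i in coo.row],
                "col": [self.ids[j] for j in coo.col],
                "value": coo.data,
            }
        )


class Pedigree:
    """Ordered pedigree with opaque string ids.

    Records are stored topologically (parents precede offspring); parents named
    but not given as records are auto-inserted as founder stubs. Metadata
    columns (sex, birth_year, season, herd, cg, ...) ride along in ``meta``.
    """

    def __init__(
        self,
        animal: Sequence,
        sire: Sequence,
        dam: Sequence,
        meta: pd.DataFrame | None = None,
    ):
        animal = [_norm_id(a) for a in animal]
        sire = [_norm_id(s) for s in sire]
        dam = [_norm_id(d) for d in dam]
        if len(set(animal)) != len(animal):
            dupes = pd.Series(animal).value_counts()
            raise PedigreeError(
                f"duplicate animal ids: {list(dupes[dupes > 1].index[:5])}"
            )
        if UNKNOWN in set(animal):
            raise PedigreeError("an animal id equals the unknown-parent marker")

        known = set(animal)
        stubs = [p for p in set(sire) | set(dam) if p != UNKNOWN and p not in known]
        # founder stubs first, in deterministic order
        animal = sorted(stubs) + animal
        sire = [UNKNOWN] * len(stubs) + sire
        dam = [UNKNOWN] * len(stubs) + dam

        order = self._topological_order(animal, sire, dam)
        self.ids: list[str] = [animal[i] for i in order]
        self._index = {a: i for i, a in enumerate(self.ids)}
        self.sire_idx = np.array(
            [self._index.get(sire[i], -1) for i in order], dtype=np.int64
        )
        self.dam_idx = np.array(
            [self._index.get(dam[i], -1) for i in order], dtype=np.int64
        )
        if meta is not None:
            meta = meta.copy()
            meta.index = pd.Index([_norm_id(a) for a in meta.index])
            self.meta = meta.reindex(self.ids)
        else:
            self.meta = pd.DataFrame(index=pd.Index(self.ids))

    # -- construction -----------------------------------------------------

    @staticmethod
    def _topological_order(animal, sire, dam) -> list[int]:
        index = {a: i for i, a in enumerate(animal)}
        n = len(animal)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i in range(n):
            for p in (sire[i], dam[i]):
                if p != UNKNOWN:
                    children[index[p]].append(i)
                    indeg[i] += 1
        # Kahn's algorithm, stable in input order
        queue = [i for i in range(n) if indeg[i] == 0]
        out: list[int] = []
        head = 0
        while head < len(queue):
            i = queue[head]
            head += 1
            out.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(out) != n:
            raise PedigreeError("pedigree contains a cycle")
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        cols = {c.lower(): c for c in df.columns}
        for req in ("animal", "sire", "dam"):
            if req not in cols:
                raise PedigreeError(f"pedigree table lacks column '{req}'")
        meta_cols = [c for c in df.columns if c.lower() not in ("animal", "sire", "dam")]
        meta = df[meta_cols].copy() if meta_cols else None
        if meta is not None:
            meta.index = df[cols["animal"]].map(_norm_id)
        return cls(df[cols["animal"]], df[cols["sire"]], df[cols["dam"]], meta)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [self.ids[s] if s >= 0 else UNKNOWN for s in self.sire_idx],
                "dam": [self.ids[d] if d >= 0 else UNKNOWN for d in self.dam_idx],
            }
        )
        if len(self.meta.columns):
            out = out.join(self.meta.reset_index(drop=True))
        return out

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, animal) -> bool:
        return _norm_id(animal) in self._index

    def index_of(self, animal) -> int:
        key = _norm_id(animal)
        if key not in self._index:
            raise KeyError(f"animal {animal!r} not in pedigree")
        return self._index[key]

    def sire_of(self, animal) -> str:
        s = self.sire_idx[self.index_of(animal)]
        return self.ids[s] if s >= 0 else UNKNOWN

    def dam_of(self, animal) -> str:
        d = self.dam_idx[self.index_of(animal)]
        return self.ids[d] if d >= 0 else UNKNOWN

    def maternal_grandsire(self, animal) -> str:
        """Sire of the animal's dam; UNKNOWN if dam or dam's sire is unknown.

        The maternal grandsire stands proxy for the (ungenotyped) dam in the
        mating-based depletion test: granddam and grandsire allele frequencies
        are assumed equal.
        """
        d = self.dam_idx[self.index_of(animal)]
        if d < 0:
            return UNKNOWN
        s = self.sire_idx[d]
        return self.ids[s] if s >= 0 else UNKNOWN

    def maternal_grandsire_indices(self) -> np.ndarray:
        """Vectorised MGS index per animal (-1 = unknown)."""
        mgs = np.full(len(self.ids), -1, dtype=np.int64)
        has_dam = self.dam_idx >= 0
        mgs[has_dam] = self.sire_idx[self.dam_idx[has_dam]]
        return mgs

    # -- relationship algebra ---------------------------------------------

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients by the Meuwissen & Luo (1992) algorithm.

        Founders (and unknown parents) have F = 0. O(n * pedigree depth^2)
        in the worst case; fast for livestock-shaped pedigrees.
        """
        return _meuwissen_luo(self.sire_idx, self.dam_idx)

    def relationship_factors(self, use_inbreeding: bool = True) -> RelationshipFactors:
        """Sparse A-inverse by Henderson's rules.

        With ``use_inbreeding`` the Mendelian sampling variances d_i use parent
        inbreeding coefficients (Quaas adjustment); otherwise parents are taken
        as non-inbred (d in {1, 0.75, 0.5}).
        """
        n = len(self.ids)
        F = self.inbreeding() if use_inbreeding else np.zeros(n)
        s_idx, d_idx = self.sire_idx, self.dam_idx
        Fs = np.where(s_idx >= 0, F[np.maximum(s_idx, 0)], 0.0)
        Fd = np.where(d_idx >= 0, F[np.maximum(d_idx, 0)], 0.0)
        # d_i = 1 - 0.25(1+F_s) - 0.25(1+F_d); an unknown parent contributes 0
        d = 1.0 - 0.25 * np.where(s_idx >= 0, 1.0 + Fs, 0.0) - 0.25 * np.where(
            d_idx >= 0, 1.0 + Fd, 0.0
        )
        b = 1.0 / d

        rows, cols, vals = [], [], []

        def add(i, j, v):
            rows.append(i)
            cols.append(j)
            vals.append(v)

        for i in range(n):
            bi = b[i]
            add(i, i, bi)
            for p in (s_idx[i], d_idx[i]):
                if p >= 0:
                    add(i, p, -bi / 2)
                    add(p, i, -bi / 2)
            for p in (s_idx[i], d_idx[i]):
                if p >= 0:
                    for q in (s_idx[i], d_idx[i]):
                        if q >= 0:
                            add(p, q, bi / 4)
        ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        ainv.sum_duplicates()
        return RelationshipFactors(
            ids=list(self.ids), inbreeding=F, a_inverse=ainv, mendelian_variance=d
        )

    def tabular_a(self) -> np.ndarray:
        """Dense numerator relationship matrix by the tabular method.

        O(n^2) memory — intended as the small-pedigree oracle for A-inverse
        and inbreeding, and for parent-average reliability bookkeeping.
        """
        n = len(self.ids)
        A = np.zeros((n, n))
        for i in range(n):
            s, d = self.sire_idx[i], self.dam_idx[i]
            asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
            A[i, i] = 1.0 + 0.5 * asd
            for j in range(i):
                aij = 0.0
                if s >= 0:
                    aij += 0.5 * A[j, s]
                if d >= 0:
                    aij += 0.5 * A[j, d]
                A[i, j] = A[j, i] = aij
        return A


def _meuwissen_luo(sire_idx: np.ndarray, dam_idx: np.ndarray) -> np.ndarray:
    """F per animal: a_ii - 1 accumulated over the ancestor path sums L.

    For each animal the ancestor tree is walked youngest-first (indices are
    topological, so ``max`` over the open-ancestor dict is the youngest);
    a_ii = sum_j L_j^2 d_j with d_j the Mendelian sampling variance of
    ancestor j given its parents' (already final) inbreeding.
    """
    n = len(sire_idx)
    F = np.zeros(n)
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        if s < 0 or d < 0:
            F[i] = 0.0  # unknown parent => treated as unrelated founder
            continue
        L = {i: 1.0}
        aii = 0.0
        while L:
            j = max(L)
            lj = L.pop(j)
            sj, dj = sire_idx[j], dam_idx[j]
            if sj >= 0:
                L[sj] = L.get(sj, 0.0) + 0.5 * lj
            if dj >= 0:
                L[dj] = L.get(dj, 0.0) + 0.5 * lj
            dvar = 0.5 - 0.25 * (
                (F[sj] if sj >= 0 else -1.0) + (F[dj] if dj >= 0 else -1.0)
            )
            aii += lj * lj * dvar
        F[i] = aii - 1.0
    return F
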