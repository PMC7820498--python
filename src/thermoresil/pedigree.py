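"""Pedigree handling and the inverse numerator relationship matrix.

The additive (numerator) relationship matrix ``A`` encodes the expected
proportion of alleles shared identical-by-descent between every pair of
animals in a pedigree.  Animal-model REML never needs ``A`` itself, only
its sparse inverse, which Henderson's rules assemble directly from the
pedigree in linear time once each animal's inbreeding coefficient is
known.  Inbreeding coefficients are computed with the Meuwissen & Luo
algorithm (tracing the ``L`` factor of ``A = L D L'`` one animal at a
time), so the Mendelian-sampling variances on the diagonal of ``D`` are
exact for arbitrarily inbred pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["Pedigree", "PedigreeError", "build_a_inverse"]

UNKNOWN = -1


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, unknown parents...)."""


@dataclass
class Pedigree:
    """A sorted pedigree: parents always precede their offspring.

    Attributes
    ----------
    ids : list
        Original animal identifiers, in sorted (parents-first) order.
    sire, dam : ndarray of int
        Positional parent indices into ``ids``; ``-1`` marks an unknown parent.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)
    _inbreeding: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal) -> int:
        return self._index[animal]

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from an iterable of ``(animal, sire, dam)`` triples.

        ``0``, ``None``, ``NaN`` and the empty string denote an unknown
        parent.  Records need not be sorted; a topological sort places
        parents before offspring.  A parent that never appears as an
        animal is added as a founder.  Cycles raise :class:`PedigreeError`.
        """

        def _missing(x) -> bool:
            if x is None:
                return True
            if isinstance(x, float) and np.isnan(x):
                return True
            return x in (0, "0", "")

        trios = [(a, None if _missing(s) else s, None if _missing(d) else d)
                 for a, s, d in records]
        seen = {a for a, _, _ in trios}
        if len(seen) != len(trios):
            dup = [a for a, _, _ in trios if sum(x[0] == a for x in trios) > 1]
            raise PedigreeError(f"duplicate animal entries: {sorted(set(dup))[:5]}")
        parents_of = {a: (s, d) for a, s, d in trios}
        # implicit founders: parents never listed as animals themselves
        for _, s, d in trios:
            for p in (s, d):
                if p is not None and p not in parents_of:
                    parents_of[p] = (None, None)

        order: list = []
        state: dict = {}  # 0 = visiting, 1 = done

        for root in parents_of:
            if root in state:
                continue
            stack = [(root, False)]
            while stack:
                node, expanded = stack.pop()
                if expanded:
                    state[node] = 1
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    raise PedigreeError(f"pedigree cycle involving animal {node!r}")
                state[node] = 0
                stack.append((node, True))
                for p in parents_of[node]:
                    if p is not None and state.get(p) != 1:
                        if state.get(p) == 0:
                            raise PedigreeError(
                                f"pedigree cycle involving animal {p!r}")
                        stack.append((p, False))

        index = {a: i for i, a in enumerate(order)}
        n = len(order)
        sire = np.full(n, UNKNOWN, dtype=np.int64)
        dam = np.full(n, UNKNOWN, dtype=np.int64)
        for a, (s, d) in parents_of.items():
            i = index[a]
            if s is not None:
                sire[i] = index[s]
            if d is not None:
                dam[i] = index[d]
        return cls(ids=order, sire=sire, dam=dam)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from a 3-column frame ``animal, sire, dam``."""
        cols = list(df.columns[:3])
        return cls.from_records(df[cols].itertuples(index=False, name=None))

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         keep_default_na=False)
        return cls.from_dataframe(df)

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F by the Meuwissen–Luo algorithm.

        For each animal the algorithm traces back the nonzero entries of
        its row of L (the unit-triangular factor of A = LDL'), so
        F_i = sum_j L_ij^2 d_j - 1.  Cached after the first call.
        """
        if self._inbreeding is not None:
            return self._inbreeding
        n = len(self)
        sire, dam = self.sire, self.dam
        F = np.zeros(n)
        d = np.zeros(n)  # Mendelian sampling variances, filled in order
        for i in range(n):
            s, dd = sire[i], dam[i]
            fs = F[s] if s != UNKNOWN else -1.0
            fd = F[dd] if dd != UNKNOWN else -1.0
            d[i] = 0.5 - 0.25 * (fs + fd)
            if s == UNKNOWN and dd == UNKNOWN:
                F[i] = 0.0
                continue
            # accumulate L-row of animal i sparsely, walking ancestors
            row = {i: 1.0}
            aii = 0.0
            for j in range(i, -1, -1):
                lij = row.pop(j, 0.0)
                if lij == 0.0:
                    continue
                aii += lij * lij * d[j]
                for p in (sire[j], dam[j]):
                    if p != UNKNOWN:
                        row[p] = row.get(p, 0.0) + 0.5 * lij
            F[i] = aii - 1.0
        self._inbreeding = F
        self._mendelian = d
        return F

    def mendelian_variances(self) -> np.ndarray:
        """Diagonal D of A = LDL' (within-family sampling variances)."""
        self.inbreeding()
        return self._mendelian

    def log_det_a(self) -> float:
        """log|A| = sum(log d_i) since |L| = 1."""
        return float(np.log(self.mendelian_variances()).sum())


def build_a_inverse(pedigree: Pedigree) -> sp.csr_matrix:
    """Assemble the sparse inverse of A by Henderson's rules.

    Each animal contributes ``alpha = 1/d_i`` (the reciprocal of its
    inbreeding-adjusted Mendelian-sampling variance) to at most nine
    entries linking it with its known parents.  The result is symmetric
    positive definite for any acyclic pedigree.
    """
    n = len(pedigree)
    d = pedigree.mendelian_variances()
    rows, cols, vals = [], [], []
    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [p for p in (pedigree.sire[i], pedigree.dam[i]) if p != UNKNOWN]
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in parents:
            rows += [i, p]; cols += [p, i]; vals += [-0.5 * alpha] * 2
        for p in parents:
            for q in parents:
                rows.append(p); cols.append(q); vals.append(0.25 * alpha)
    ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    ainv.sum_duplicates()
    return ainv
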