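"""Queen-contiguity spatial weights.

The spatial weight matrix W encodes which counties are neighbours. Under the
Queen criterion two polygons are contiguous if their boundaries share at
least one point (so on a square lattice each interior cell has the eight
Moore neighbours). Row standardization replaces each binary row by
1/|N(i)|, giving the "average of the neighbours" operator used by the
spatial lag, error and combined panel models.
"""

from __future__ import annotations

import csv
import warnings

import numpy as np
import scipy.sparse as sp
from shapely.strtree import STRtree

from .lattice import LatticeGeometry

__all__ = [
    "SpatialWeights",
    "queen_contiguity",
    "row_standardize",
    "spatial_lag",
]


class SpatialWeights:
    """Sparse spatial weights over an ordered set of units.

    Parameters
    ----------
    ids : sequence of str
        Ordered unit identifiers; defines row/column order of W.
    neighbors : dict
        Maps each id to an ordered list of neighbouring ids. The contiguity
        relation must be symmetric and irreflexive; isolated units map to
        an empty list.
    weights : dict, optional
        Maps each id to nonnegative weights aligned with its neighbour
        list. Defaults to binary (all ones).
    standardized : bool
        True when each non-isolated row sums to one.
    """

    def __init__(self, ids, neighbors, weights=None, standardized=False):
        self.ids = [str(i) for i in ids]
        self._index = {cid: k for k, cid in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate unit ids")
        self.neighbors = {}
        self.weights = {}
        for cid in self.ids:
            nb = [str(j) for j in neighbors.get(cid, [])]
            if cid in nb:
                raise ValueError(f"unit {cid!r} lists itself as a neighbour")
            self.neighbors[cid] = nb
            if weights is None:
                self.weights[cid] = [1.0] * len(nb)
            else:
                wv = [float(v) for v in weights[cid]]
                if len(wv) != len(nb):
                    raise ValueError(f"weights misaligned for unit {cid!r}")
                if any(v < 0 for v in wv):
                    raise ValueError("weights must be nonnegative")
                self.weights[cid] = wv
        for cid in self.ids:
            for j in self.neighbors[cid]:
                if cid not in self.neighbors.get(j, []):
                    raise ValueError(f"contiguity not symmetric: {cid!r} -> {j!r}")
        self.standardized = bool(standardized)

    # -- basic queries ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def cardinalities(self) -> dict[str, int]:
        return {cid: len(nb) for cid, nb in self.neighbors.items()}

    @property
    def islands(self) -> list[str]:
        return [cid for cid, nb in self.neighbors.items() if not nb]

    def sparse(self) -> sp.csr_matrix:
        """W as an (n, n) CSR matrix in id order."""
        rows, cols, vals = [], [], []
        for cid in self.ids:
            i = self._index[cid]
            for j, v in zip(self.neighbors[cid], self.weights[cid]):
                rows.append(i)
                cols.append(self._index[j])
                vals.append(v)
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def dense(self) -> np.ndarray:
        return self.sparse().toarray()

    # -- operations -------------------------------------------------------
    def row_standardize(self) -> "SpatialWeights":
        """Return a copy whose non-isolated rows sum to one (idempotent)."""
        new_w = {}
        for cid in self.ids:
            wv = np.asarray(self.weights[cid], dtype=float)
            s = wv.sum()
            new_w[cid] = list(wv / s) if s > 0 else []
        return SpatialWeights(self.ids, self.neighbors, new_w, standardized=True)

    def lag(self, values) -> np.ndarray:
        """Spatial lag ``(Wv)_i = sum_j w_ij v_j``; 0 for isolated units."""
        values = np.asarray(values, dtype=float)
        if values.shape[0] != self.n:
            raise ValueError(
                f"values length {values.shape[0]} != number of units {self.n}"
            )
        return self.sparse() @ values

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of W, exact for row-standardized symmetric contiguity.

        A row-standardized W = D^{-1} C with C symmetric is similar to the
        symmetric matrix D^{-1/2} C D^{-1/2}, so its spectrum is real and
        lies in [-1, 1]. Isolated units contribute zero eigenvalues.
        """
        W = self.sparse().toarray()
        if self.standardized:
            C = np.zeros_like(W)
            deg = np.array([len(self.neighbors[cid]) for cid in self.ids], float)
            live = deg > 0
            C[np.ix_(live, live)] = W[np.ix_(live, live)] * deg[live][:, None]
            d_isqrt = np.zeros(self.n)
            d_isqrt[live] = 1.0 / np.sqrt(deg[live])
            S = d_isqrt[:, None] * C * d_isqrt[None, :]
            if np.allclose(S, S.T, atol=1e-10):
                return np.linalg.eigvalsh(S)
        ev = np.linalg.eigvals(W)
        if np.max(np.abs(ev.imag)) > 1e-8:
            warnings.warn("complex eigenvalues in weight matrix; using real parts")
        return np.sort(ev.real)

    # -- serialization ----------------------------------------------------
    def to_gal(self, path) -> None:
        """Write GAL-style text: header line 'n', then id/degree + neighbour lines."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{self.n}\n")
            for cid in self.ids:
                nb = self.neighbors[cid]
                fh.write(f"{cid} {len(nb)}\n")
                fh.write(" ".join(nb) + "\n")

    @classmethod
    def from_gal(cls, path) -> "SpatialWeights":
        with open(path, encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        n = int(lines[0].split()[0])
        ids, neighbors = [], {}
        k = 1
        for _ in range(n):
            cid, deg = lines[k].split()
            nb = lines[k + 1].split() if int(deg) > 0 else []
            if int(deg) > 0:
                k += 2
            else:
                # degree-0 rows may or may not carry an (empty) neighbour line
                k += 2 if k + 1 < len(lines) and lines[k + 1].strip() == "" else 1
            ids.append(cid)
            neighbors[cid] = nb
        return cls(ids, neighbors)

    def to_triplets(self, path) -> None:
        """Write sparse triplet CSV with columns i, j, w (ids, not indexes)."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            wr = csv.writer(fh)
            wr.writerow(["i", "j", "w"])
            for cid in self.ids:
                for j, v in zip(self.neighbors[cid], self.weights[cid]):
                    wr.writerow([cid, j, repr(v)])

    @classmethod
    def from_triplets(cls, path, ids=None) -> "SpatialWeights":
        neighbors: dict[str, list] = {}
        weights: dict[str, list] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            rd = csv.DictReader(fh)
            for row in rd:
                neighbors.setdefault(row["i"], []).append(row["j"])
                weights.setdefault(row["i"], []).append(float(row["w"]))
        if ids is None:
            ids = sorted(set(neighbors) | {j for nb in neighbors.values() for j in nb})
        for cid in ids:
            neighbors.setdefault(cid, [])
            weights.setdefault(cid, [])
        row_sums = [sum(weights[c]) for c in ids if weights[c]]
        standardized = bool(row_sums) and all(abs(s - 1) < 1e-9 for s in row_sums)
        return cls(ids, neighbors, weights, standardized=standardized)


def queen_contiguity(geometry) -> SpatialWeights:
    """Binary Queen-contiguity weights from polygons.

    Two units are neighbours iff their polygon boundaries share at least one
    point (a shared corner suffices). Accepts a :class:`LatticeGeometry` or
    any object with ``county_ids`` and ``polygons`` attributes. A snap
    tolerance of 1e-9 of the typical cell size absorbs floating-point
    boundary coordinates from round-tripped files.
    """
    ids = [str(c) for c in geometry.county_ids]
    polys = list(geometry.polygons)
    if len(ids) != len(polys):
        raise ValueError("ids and polygons length mismatch")
    for p in polys:
        if p is None or p.is_empty or not p.is_valid:
            raise ValueError("invalid or empty polygon in geometry")
    scale = float(np.median([np.sqrt(p.area) for p in polys])) or 1.0
    tol = 1e-9 * scale
    tree = STRtree(polys)
    neighbors: dict[str, set] = {cid: set() for cid in ids}
    for i, poly in enumerate(polys):
        for j in tree.query(poly.buffer(tol)):
            j = int(j)
            if j == i:
                continue
            if poly.distance(polys[j]) <= tol:
                neighbors[ids[i]].add(ids[j])
                neighbors[ids[j]].add(ids[i])
    ordered = {cid: sorted(nb) for cid, nb in neighbors.items()}
    if all(not nb for nb in ordered.values()):
        warnings.warn("fully disconnected geometry: every unit is an island")
    return SpatialWeights(ids, ordered, standardized=False)


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Functional alias for :meth:`SpatialWeights.row_standardize`."""
    return w.row_standardize()


def spatial_lag(w: SpatialWeights, values) -> np.ndarray:
    """Functional alias for :meth:`SpatialWeights.lag`."""
    return w.lag(values)


def lattice_queen(geometry: LatticeGeometry) -> SpatialWeights:
    """Queen weights on a lattice from grid arithmetic (Moore 8-neighbourhood).

    Equivalent to :func:`queen_contiguity` on the lattice polygons but O(n);
    used as the fast path for large synthetic grids.
    """
    nr, nc = geometry.n_rows, geometry.n_cols
    ids = geometry.county_ids
    neighbors = {}
    for r in range(nr):
        for c in range(nc):
            nb = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc:
                        nb.append(ids[rr * nc + cc])
            neighbors[ids[r * nc + c]] = sorted(nb)
    return SpatialWeights(ids, neighbors, standardized=False)
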