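"""Unit-cell metrics and space-group symmetry for reflection data.

A small, explicit operator table (packaged as JSON) covers the space groups
commonly met in macromolecular work with small-wedge serial data.  Symmetry
is used for three things only: mapping Miller indices to a canonical
asymmetric-unit representative, deciding systematic absences, and counting
the unique reflections expected in a resolution window (the completeness
denominator).  Translation parts are stored in twelfths so every operator
is exact integer arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from importlib import resources
from math import cos, pi, sin, sqrt

import numpy as np

from .exceptions import SxmergeError, UnsupportedSpaceGroupError

__all__ = [
    "UnitCell",
    "SpaceGroupInfo",
    "get_spacegroup",
    "resolution_d",
    "map_to_asu",
    "is_absent",
    "count_unique",
    "enumerate_asu",
]


@dataclass(frozen=True)
class UnitCell:
    """Six lattice constants: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        ca, cb, cg = (cos(x * pi / 180.0) for x in (self.alpha, self.beta, self.gamma))
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if disc <= 0.0:
            raise ValueError("cell angles do not define a positive-definite metric")

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        ca, cb, cg = (cos(x * pi / 180.0) for x in (self.alpha, self.beta, self.gamma))
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * sqrt(disc)

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (Å²)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (cos(x * pi / 180.0) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal metric tensor G* (Å⁻²); h·G*·h = 1/d²."""
        return np.linalg.inv(self.metric_tensor())

    def orthogonalization_b(self) -> np.ndarray:
        """Matrix B with B·(h,k,l) = reciprocal-lattice vector in Cartesian Å⁻¹.

        Any matrix satisfying BᵀB = G* works for geometry; the Cholesky
        factor of G* is used (upper triangular, a* along x).
        """
        gstar = self.reciprocal_metric_tensor()
        return np.linalg.cholesky(gstar).T

    def isclose(self, other: "UnitCell", rtol: float = 1e-6) -> bool:
        return all(
            abs(p - q) <= rtol * max(abs(p), abs(q), 1.0)
            for p, q in zip(self.parameters, other.parameters)
        )


def _parse_triplet(triplet: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse "x,y+1/2,-z" into (3×3 integer rotation, translation in twelfths)."""
    rot = np.zeros((3, 3), dtype=np.int64)
    trans = np.zeros(3, dtype=np.int64)
    parts = triplet.replace(" ", "").lower().split(",")
    if len(parts) != 3:
        raise SxmergeError(f"malformed symop triplet: {triplet!r}")
    for i, part in enumerate(parts):
        # tokenize into signed terms: letters x/y/z or fractions n/m
        term = ""
        terms = []
        for ch in part:
            if ch in "+-" and term:
                terms.append(term)
                term = ch
            else:
                term += ch
        terms.append(term)
        for t in terms:
            sign = -1 if t.startswith("-") else 1
            t = t.lstrip("+-")
            if t in ("x", "y", "z"):
                rot[i, "xyz".index(t)] += sign
            elif t:
                frac = Fraction(t)
                tw = frac * 12
                if tw.denominator != 1:
                    raise SxmergeError(f"translation not a multiple of 1/12: {triplet!r}")
                trans[i] += sign * int(tw)
    return rot, trans % 12


_CENTERING_TRANSLATIONS = {
    "P": [(0, 0, 0)],
    "A": [(0, 0, 0), (0, 6, 6)],
    "B": [(0, 0, 0), (6, 0, 6)],
    "C": [(0, 0, 0), (6, 6, 0)],
    "I": [(0, 0, 0), (6, 6, 6)],
    "F": [(0, 0, 0), (0, 6, 6), (6, 0, 6), (6, 6, 0)],
}


@dataclass(frozen=True)
class SpaceGroupInfo:
    """Operator table of one space group.

    ``symops`` hold the representative coset operations (rotation, translation
    in twelfths); the full operation list is their product with the centering
    translations.  ``laue_ops`` are the distinct rotation parts, used for
    asymmetric-unit reduction of Miller indices.
    """

    number: int
    symbol: str
    centering: str
    symops: tuple[tuple[np.ndarray, np.ndarray], ...]
    laue_ops: np.ndarray = field(repr=False)  # (n, 3, 3) int

    @property
    def n_symops(self) -> int:
        return len(self.symops) * len(_CENTERING_TRANSLATIONS[self.centering])

    def all_ops(self):
        """Yield every (rotation, translation/12) including centering copies."""
        for rot, trans in self.symops:
            for cen in _CENTERING_TRANSLATIONS[self.centering]:
                yield rot, (trans + np.array(cen, dtype=np.int64)) % 12


@lru_cache(maxsize=None)
def _spacegroup_table() -> dict[int, dict]:
    text = resources.files("sxmerge.data").joinpath("spacegroups.json").read_text()
    return {int(k): v for k, v in json.loads(text).items()}


@lru_cache(maxsize=None)
def get_spacegroup(number: int) -> SpaceGroupInfo:
    table = _spacegroup_table()
    if number not in table:
        raise UnsupportedSpaceGroupError(
            f"space group {number} is not in the bundled table "
            f"(available: {sorted(table)})"
        )
    rec = table[number]
    symops = tuple(_parse_triplet(t) for t in rec["symops"])
    # identity must be present; closure of the bundled groups is covered by tests
    if not any((r == np.eye(3, dtype=np.int64)).all() and (t == 0).all() for r, t in symops):
        raise SxmergeError(f"space group {number}: identity operator missing")
    seen: list[np.ndarray] = []
    for rot, _ in symops:
        if not any((rot == s).all() for s in seen):
            seen.append(rot)
    return SpaceGroupInfo(
        number=number,
        symbol=rec["symbol"],
        centering=rec["centering"],
        symops=symops,
        laue_ops=np.stack(seen),
    )


def resolution_d(cell: UnitCell, hkl) -> np.ndarray | float:
    """Resolution d (Å) of one Miller index or an (n, 3) array of them."""
    h = np.asarray(hkl, dtype=float)
    scalar = h.ndim == 1
    h = np.atleast_2d(h)
    if np.any(np.all(h == 0, axis=1)):
        raise ValueError("resolution of (0,0,0) is undefined")
    gstar = cell.reciprocal_metric_tensor()
    inv_d2 = np.einsum("ni,ij,nj->n", h, gstar, h)
    d = 1.0 / np.sqrt(inv_d2)
    return float(d[0]) if scalar else d


def _miller_images(hkl: np.ndarray, sg: SpaceGroupInfo, anomalous: bool) -> np.ndarray:
    """All point-group images of (n, 3) indices, shape (m, n, 3).

    Miller indices transform as row vectors: h' = h·R.
    """
    imgs = np.einsum("nj,rjk->rnk", hkl, sg.laue_ops)
    if not anomalous:
        imgs = np.concatenate([imgs, -imgs], axis=0)
    return imgs


def map_to_asu(hkl, sg: SpaceGroupInfo, anomalous: bool = False) -> np.ndarray:
    """Canonical asymmetric-unit representative of Miller indices.

    The representative is the lexicographically greatest (h, k, l) tuple over
    all point-group images (and Friedel mates unless ``anomalous``).  Any
    fixed convention works because downstream code only compares
    representatives for equality.  Accepts a single index or an (n, 3) array.
    """
    h = np.asarray(hkl, dtype=np.int64)
    scalar = h.ndim == 1
    h = np.atleast_2d(h)
    imgs = _miller_images(h, sg, anomalous)  # (m, n, 3)
    # lexicographic max via a scalar key; |index| < 2**20 in practice
    key = (imgs[..., 0].astype(np.int64) << 42) + (imgs[..., 1] << 21) + imgs[..., 2]
    best = np.argmax(key, axis=0)
    out = imgs[best, np.arange(h.shape[0])]
    return out[0] if scalar else out


def is_absent(hkl, sg: SpaceGroupInfo) -> np.ndarray | bool:
    """Systematic absence test: some operation fixes h with a nonzero phase shift."""
    h = np.asarray(hkl, dtype=np.int64)
    scalar = h.ndim == 1
    h = np.atleast_2d(h)
    absent = np.zeros(h.shape[0], dtype=bool)
    for rot, trans in sg.all_ops():
        fixed = np.all(h @ rot == h, axis=1)
        shift = (h @ trans) % 12
        absent |= fixed & (shift != 0)
    return bool(absent[0]) if scalar else absent


def _hkl_box(cell: UnitCell, d_min: float) -> np.ndarray:
    """All nonzero integer indices possibly at d ≥ d_min.

    Exact per-axis bound: the reciprocal vector's projection on direct axis a
    is h/a, so 1/d ≥ |h|/a, i.e. |h| ≤ a/d_min (likewise k, l).
    """
    hmax = int(cell.a / d_min)
    kmax = int(cell.b / d_min)
    lmax = int(cell.c / d_min)
    hs, ks, ls = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    box = np.stack([hs.ravel(), ks.ravel(), ls.ravel()], axis=1)
    return box[np.any(box != 0, axis=1)]


def enumerate_asu(
    cell: UnitCell,
    sg: SpaceGroupInfo,
    d_min: float,
    d_max: float = float("inf"),
    anomalous: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Unique, non-absent ASU representatives with d_min ≤ d < d_max.

    Returns (indices (n, 3), d (n,)), sorted by decreasing resolution d.
    """
    if not d_min < d_max:
        raise ValueError("need d_min < d_max")
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    box = _hkl_box(cell, d_min)
    d = resolution_d(cell, box)
    keep = (d >= d_min) & (d < d_max)
    box, d = box[keep], d[keep]
    if len(box) == 0:
        return box.reshape(0, 3), d
    reps = map_to_asu(box, sg, anomalous)
    uniq, idx = np.unique(reps, axis=0, return_index=True)
    d_uniq = d[idx]
    keep = ~is_absent(uniq, sg)
    uniq, d_uniq = uniq[keep], d_uniq[keep]
    order = np.argsort(-d_uniq, kind="stable")
    return uniq[order], d_uniq[order]


def count_unique(
    cell: UnitCell,
    sg: SpaceGroupInfo,
    d_max: float,
    d_min: float,
    anomalous: bool = False,
) -> int:
    """Number of unique non-absent reflections expected in [d_min, d_max)."""
    reps, _ = enumerate_asu(cell, sg, d_min, d_max, anomalous)
    return len(reps)
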