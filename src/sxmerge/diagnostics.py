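"""Preferred-orientation and anisotropy diagnostics.

With crystals mounted on a fixed target, a non-uniform distribution of
crystal orientations shows up as an asymmetric distribution of per-unique
multiplicities after merging (a roughly binomial, symmetric distribution is
expected for uniform orientations).  The anisotropy check is an internal
estimator: it bins unique reflections inside cones around each reciprocal
axis and reports where the mean I/σ falls below a threshold along a*, b*
and c*.  No equivalence with external anisotropy programs is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import skew

from .scaling import MergedReflections
from .symmetry import UnitCell

__all__ = ["OrientationReport", "AnisotropyReport", "multiplicity_report", "anisotropy_limits"]


@dataclass
class OrientationReport:
    """Multiplicity histogram with a skewness-based orientation flag."""

    histogram: dict[int, int]
    skewness: float
    skew_threshold: float
    flagged: bool

    def to_dict(self) -> dict:
        return {
            "histogram": {str(k): int(v) for k, v in sorted(self.histogram.items())},
            "skewness": float(self.skewness),
            "skew_threshold": float(self.skew_threshold),
            "flagged": bool(self.flagged),
        }


@dataclass
class AnisotropyReport:
    """Directional resolution limits along the reciprocal axes."""

    d_limits: dict[str, float | None]  # axis -> d (Å), None when undefined
    cone_deg: float
    isigi_cut: float
    curves: dict[str, list[dict]] = field(default_factory=dict)

    @property
    def anisotropy_ratio(self) -> float | None:
        vals = [v for v in self.d_limits.values() if v is not None]
        if len(vals) < 2:
            return None
        return max(vals) / min(vals)

    def to_dict(self) -> dict:
        return {
            "d_limits": {k: (None if v is None else float(v)) for k, v in self.d_limits.items()},
            "anisotropy_ratio": self.anisotropy_ratio,
            "cone_deg": float(self.cone_deg),
            "isigi_cut": float(self.isigi_cut),
            "curves": self.curves,
        }


def multiplicity_report(
    merged: MergedReflections,
    skew_threshold: float = 0.5,
    n_expected: int | None = None,
) -> OrientationReport:
    """Histogram and Fisher–Pearson skewness of per-reflection multiplicities.

    When ``n_expected`` (the symmetry-expected unique count for the covered
    resolution range) is given, reflections never observed enter the
    histogram with multiplicity 0 — persistent blind zones caused by a
    preferred orientation are part of the asymmetry being tested.
    """
    mult = merged.table["multiplicity"].to_numpy()
    if n_expected is not None and n_expected > len(mult):
        mult = np.concatenate([mult, np.zeros(n_expected - len(mult), dtype=mult.dtype)])
    if len(mult) < 50:
        raise ValueError("need at least 50 unique reflections")
    counts = np.bincount(mult.astype(int))
    hist = {int(m): int(c) for m, c in enumerate(counts) if c > 0}
    if np.ptp(mult) == 0:
        s = 0.0  # a constant distribution is perfectly symmetric
    else:
        s = float(skew(mult))
    return OrientationReport(
        histogram=hist,
        skewness=s,
        skew_threshold=skew_threshold,
        flagged=abs(s) > skew_threshold,
    )


def anisotropy_limits(
    merged: MergedReflections,
    cell: UnitCell,
    cone_deg: float = 30.0,
    isigi_cut: float = 1.5,
    n_shells: int = 5,
    min_per_cone: int = 100,
) -> AnisotropyReport:
    """Directional d-limits from cones around a*, b* and c*.

    For each reciprocal axis, unique reflections whose reciprocal-lattice
    vector lies within ``cone_deg`` of the axis (either hemisphere) are
    binned into equal-count resolution shells; the limit is the resolution
    at which the shell-mean merged I/σ first drops below ``isigi_cut``,
    linearly interpolated between shell midpoints.  If the signal never
    drops below the threshold the best shell edge is reported.
    """
    mt = merged.table
    bmat = cell.orthogonalization_b()
    vecs = (bmat @ mt[["h", "k", "l"]].to_numpy().T).T
    norms = np.linalg.norm(vecs, axis=1)
    isig = (mt["intensity"] / mt["sigma"]).to_numpy()
    d = mt["d"].to_numpy()
    cos_cut = np.cos(np.deg2rad(cone_deg))

    d_limits: dict[str, float | None] = {}
    curves: dict[str, list[dict]] = {}
    for ax_idx, ax_name in enumerate(("a*", "b*", "c*")):
        axis = bmat[:, ax_idx]
        axis = axis / np.linalg.norm(axis)
        cosang = np.abs(vecs @ axis) / np.maximum(norms, 1e-300)
        in_cone = cosang >= cos_cut - 1e-12
        if in_cone.sum() < min_per_cone:
            d_limits[ax_name] = None
            curves[ax_name] = []
            continue
        dc, ic = d[in_cone], isig[in_cone]
        order = np.argsort(-dc)
        dc, ic = dc[order], ic[order]
        nb = max(2, min(n_shells, len(dc) // 10))
        shell = (np.arange(len(dc)) * nb) // len(dc)
        mid = np.bincount(shell, weights=dc) / np.bincount(shell)
        mean_is = np.bincount(shell, weights=ic) / np.bincount(shell)
        curves[ax_name] = [
            {"d_mid": float(m), "i_over_sigma": float(v)} for m, v in zip(mid, mean_is)
        ]
        limit = float(dc.min())  # never below threshold: best shell edge
        for s in range(nb):
            if mean_is[s] < isigi_cut:
                if s == 0:
                    limit = float(mid[0])
                else:
                    d0, d1 = mid[s - 1], mid[s]
                    v0, v1 = mean_is[s - 1], mean_is[s]
                    frac = (v0 - isigi_cut) / (v0 - v1) if v0 != v1 else 0.0
                    limit = float(d0 + frac * (d1 - d0))
                break
        d_limits[ax_name] = limit
    return AnisotropyReport(
        d_limits=d_limits, cone_deg=cone_deg, isigi_cut=isigi_cut, curves=curves
    )
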