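"""Synthetic miniset ensembles with known ground truth.

Emulates serial collection of small rotation wedges (≈10–20°) from many
microcrystals: a Wilson-distributed set of true intensities per unique
reflection, per-dataset linear scale and relative B-factor, counting noise,
optional unreported multiplicative systematic error (to create low-ISa
datasets), cluster-structured non-isomorphism (log-normal perturbation of
the true intensities per cluster), unit-cell offsets and jitter, and an
optional preferred-orientation bias of the crystal orientations.

Geometry is the ideal monochromatic rotation method: spindle along the
laboratory z axis, incident beam along +x, no mosaicity or partiality.  A
reflection is observed when its Ewald-sphere crossing angle falls inside
the dataset's wedge; reflections whose reciprocal vector never crosses the
sphere (blind region near the spindle axis) are excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import pi
from pathlib import Path

import numpy as np

from .reflection_io import Miniset, write_xds_ascii
from .symmetry import SpaceGroupInfo, UnitCell, enumerate_asu, get_spacegroup

__all__ = [
    "ClusterSpec",
    "SynthConfig",
    "GroundTruth",
    "tau_for_cc",
    "generate_truth",
    "simulate_wedge",
    "generate_ensemble",
    "showcase_config",
]

_VAR_LOG_E = pi * pi / 6.0  # variance of log E, E ~ Exp(1)


def tau_for_cc(target_cc: float, var_log: float = _VAR_LOG_E) -> float:
    """Perturbation width τ giving an expected log-intensity correlation.

    For two clusters whose truths are independently perturbed by
    exp(ε), ε ~ N(0, τ²), the correlation of log intensities is
    var/(var + τ²); inverting gives τ = sqrt(var·(1/cc − 1)).
    """
    if not 0 < target_cc <= 1:
        raise ValueError("target CC must be in (0, 1]")
    return float(np.sqrt(var_log * (1.0 / target_cc - 1.0)))


@dataclass(frozen=True)
class ClusterSpec:
    """One isomorphism class: its share of datasets, the width τ of the
    log-normal perturbation applied to the true intensities, and an additive
    offset (Å / degrees) on the six cell parameters."""

    fraction: float
    tau: float = 0.0
    cell_offset: tuple[float, float, float, float, float, float] = (0, 0, 0, 0, 0, 0)


@dataclass
class SynthConfig:
    cell: UnitCell = field(default_factory=lambda: UnitCell(40.0, 50.0, 60.0))
    spacegroup_number: int = 20
    d_min: float = 3.0
    n_datasets: int = 40
    wedge_deg: float = 10.0
    phi0_deg: float = 0.0  # common spindle start angle of every wedge
    wavelength: float = 1.0
    clusters: tuple[ClusterSpec, ...] = (ClusterSpec(1.0),)
    scale_range: tuple[float, float] = (0.5, 2.0)
    b_range: tuple[float, float] = (0.0, 10.0)
    b_overall: float = 15.0
    truth_scale: float = 1000.0
    noise_gain: float = 1.0  # counts per intensity unit; larger ⇒ less noise
    noise_floor: float = 25.0  # additive variance floor
    noise: bool = True
    low_isa_fraction: float = 0.0
    sigma_sys: float = 0.5  # unreported fractional error of low-ISa datasets
    kappa: float = 0.0  # orientation concentration; 0 = uniform
    cell_jitter: float = 0.05  # σ of per-dataset jitter on lengths (Å) and angles (°)
    aniso_delta_b: float = 0.0  # extra B (Å²) along c* for anisotropy tests
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(c.fraction for c in self.clusters) - 1.0) > 1e-9:
            raise ValueError("cluster fractions must sum to 1")
        if self.wedge_deg <= 0:
            raise ValueError("wedge_deg must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be ≥ 0")


@dataclass
class GroundTruth:
    """What the generator knows: true intensities and per-dataset parameters."""

    hkl: np.ndarray  # (n, 3) canonical unique indices
    d: np.ndarray
    intensities: dict[int, np.ndarray]  # cluster index -> truth per unique
    k: dict[str, float]
    b: dict[str, float]
    cluster: dict[str, int]
    low_isa: dict[str, bool]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "n_unique": len(self.hkl),
            "k": self.k,
            "b": self.b,
            "cluster": self.cluster,
            "low_isa": self.low_isa,
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def generate_truth(
    cfg: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Canonical uniques to d_min with per-cluster true intensities.

    Truths follow the acentric Wilson model I = C·exp(−2·B·s²)·E with
    E ~ Exp(1); non-reference clusters multiply by exp(ε), ε ~ N(0, τ²),
    drawn independently per cluster.
    """
    sg = get_spacegroup(cfg.spacegroup_number)
    hkl, d = enumerate_asu(cfg.cell, sg, d_min=cfg.d_min)
    s2 = 1.0 / (4.0 * d * d)
    base = cfg.truth_scale * np.exp(-2.0 * cfg.b_overall * s2) * rng.exponential(1.0, len(d))
    truths = {}
    for ci, cl in enumerate(cfg.clusters):
        if cl.tau > 0:
            truths[ci] = base * np.exp(rng.normal(0.0, cl.tau, len(d)))
        else:
            truths[ci] = base.copy()
    return hkl, d, truths


def _rot_z(phi_deg: np.ndarray | float) -> np.ndarray:
    p = np.deg2rad(phi_deg)
    c, s = np.cos(p), np.sin(p)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def simulate_wedge(
    vectors: np.ndarray,
    phi0: float,
    wedge_deg: float,
    wavelength: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Which reciprocal vectors cross the Ewald sphere inside the wedge.

    ``vectors``: (n, 3) reciprocal-lattice vectors (Å⁻¹) in the laboratory
    frame at spindle angle zero; spindle along z, beam along +x.  The
    diffraction condition |r(φ) + s0| = 1/λ reduces to
    A·cosφ + B·sinφ = C with A = x₀, B = −y₀, C = −λ|r|²/2.  Returns a
    boolean mask of observed vectors and the first crossing angle (degrees)
    of each observed vector within the wedge.
    """
    v = np.asarray(vectors, dtype=float)
    a = v[:, 0]
    b = -v[:, 1]
    r2 = np.einsum("ni,ni->n", v, v)
    c = -0.5 * wavelength * r2
    amp = np.hypot(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(amp > 0, c / np.maximum(amp, 1e-300), 2.0)
    crossable = np.abs(ratio) <= 1.0  # otherwise blind region
    base = np.degrees(np.arctan2(b, a))
    off = np.degrees(np.arccos(np.clip(ratio, -1.0, 1.0)))
    mask = np.zeros(len(v), dtype=bool)
    phi_hit = np.full(len(v), np.nan)
    for sol in (base + off, base - off):
        rel = np.mod(sol - phi0, 360.0)
        hit = crossable & (rel <= wedge_deg)
        newly = hit & ~mask
        phi_hit[newly] = np.mod(phi0 + rel[newly], 360.0)
        mask |= hit
    return mask, phi_hit


_Z_TO_X = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])


def _sample_orientation(rng: np.random.Generator, kappa: float) -> np.ndarray:
    """Random crystal orientation; κ > 0 concentrates the crystal c* axis
    toward the laboratory x axis — the beam, i.e. the fixed-target normal —
    with a von Mises–Fisher distribution on the sphere.  The spin about the
    preferred axis stays uniform (crystals sit in random azimuth on the
    chip), as does the full orientation when κ = 0."""
    if kappa <= 0:
        w = rng.uniform(-1.0, 1.0)
    else:
        u = rng.uniform()
        w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    theta = rng.uniform(0.0, 2.0 * np.pi)
    sin_pol = np.sqrt(max(0.0, 1.0 - w * w))
    v = np.array([sin_pol * np.cos(theta), sin_pol * np.sin(theta), w])
    # rotation taking ẑ to v, composed with a uniform spin about ẑ
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(z, v)
    na = np.linalg.norm(axis)
    if na < 1e-12:
        align = np.eye(3) if w > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        axis = axis / na
        ang = np.arccos(np.clip(w, -1.0, 1.0))
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        align = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    spin = _rot_z(rng.uniform(0.0, 360.0))
    return _Z_TO_X @ align @ spin


def _expand_mates(hkl: np.ndarray, sg: SpaceGroupInfo) -> tuple[np.ndarray, np.ndarray]:
    """All distinct point-group + Friedel images of each unique, with the
    parent unique's row index."""
    ops = sg.laue_ops
    imgs = np.einsum("nj,rjk->rnk", hkl, ops)
    imgs = np.concatenate([imgs, -imgs], axis=0)  # Friedel mates
    m, n, _ = imgs.shape
    flat = imgs.reshape(m * n, 3)
    parents = np.tile(np.arange(n), m)
    # deduplicate identical (mate, parent) combinations
    _, idx = np.unique(
        np.concatenate([flat, parents[:, None]], axis=1), axis=0, return_index=True
    )
    return flat[idx], parents[idx]


def generate_ensemble(
    cfg: SynthConfig, out_dir: str | Path | None = None
) -> tuple[list[Miniset], GroundTruth]:
    """Generate the full ensemble; optionally write the files and truth JSON."""
    rng = np.random.default_rng(cfg.seed)
    sg = get_spacegroup(cfg.spacegroup_number)
    hkl, d, truths = generate_truth(cfg, rng)
    s2 = 1.0 / (4.0 * d * d)
    mates, parents = _expand_mates(hkl, sg)
    bmat = cfg.cell.orthogonalization_b()
    crystal_vecs = (bmat @ mates.T).T  # crystal-frame reciprocal vectors
    # anisotropy: direction cosine to c* in the crystal frame
    cstar = bmat[:, 2] / np.linalg.norm(bmat[:, 2])
    cos_c = np.abs(crystal_vecs @ cstar) / np.maximum(
        np.linalg.norm(crystal_vecs, axis=1), 1e-300
    )

    # per-dataset assignments
    n = cfg.n_datasets
    cluster_of = np.repeat(
        np.arange(len(cfg.clusters)),
        np.diff(np.round(np.cumsum([0.0] + [c.fraction for c in cfg.clusters]) * n).astype(int)),
    )
    if len(cluster_of) < n:  # rounding shortfall goes to the last cluster
        cluster_of = np.concatenate([cluster_of, np.full(n - len(cluster_of), len(cfg.clusters) - 1)])
    n_low = int(round(cfg.low_isa_fraction * n))
    low_flags = np.zeros(n, dtype=bool)
    if n_low:
        # draw low-ISa datasets from the majority cluster when possible, so
        # non-isomorphism and systematic error stay separable failure modes
        pool = np.flatnonzero(cluster_of == 0)
        if len(pool) < n_low:
            pool = np.arange(n)
        low_flags[rng.choice(pool, size=n_low, replace=False)] = True

    width = len(str(max(n - 1, 1)))
    minisets: list[Miniset] = []
    truth = GroundTruth(
        hkl=hkl, d=d, intensities=truths, k={}, b={}, cluster={}, low_isa={}
    )
    for j in range(n):
        ds_id = f"ds_{j:0{width}d}"
        cl = cfg.clusters[cluster_of[j]]
        k_j = rng.uniform(*cfg.scale_range)
        b_j = rng.uniform(*cfg.b_range)
        orient = _sample_orientation(rng, cfg.kappa)
        # every crystal is scanned over the same spindle range, as on a fixed
        # target; with uniform orientations the choice is statistically moot,
        # but with orientation bias it is what makes the bias observable
        phi0 = cfg.phi0_deg
        lab_vecs = (orient @ crystal_vecs.T).T
        mask, phi_hit = simulate_wedge(lab_vecs, phi0, cfg.wedge_deg, cfg.wavelength)
        if mask.sum() == 0:
            continue
        par = parents[mask]
        obs_hkl = mates[mask]
        s2_obs = s2[par]
        signal = k_j * np.exp(-2.0 * b_j * s2_obs) * truths[cluster_of[j]][par]
        if cfg.aniso_delta_b:
            signal = signal * np.exp(-2.0 * cfg.aniso_delta_b * (cos_c[mask] ** 2) * s2_obs)
        if low_flags[j] and cfg.sigma_sys > 0:
            signal = signal * (1.0 + rng.normal(0.0, cfg.sigma_sys, len(signal)))
        if cfg.noise:
            var = np.maximum(signal, 0.0) / cfg.noise_gain + cfg.noise_floor
            sig = np.sqrt(var)
            iobs = signal + rng.normal(0.0, 1.0, len(signal)) * sig
        else:
            iobs = signal
            sig = np.maximum(np.abs(signal) * 0.01, 1e-3)
        jit = rng.normal(0.0, cfg.cell_jitter, 6)
        p = np.array(cfg.cell.parameters) + np.array(cl.cell_offset) + jit
        minisets.append(
            Miniset(
                id=ds_id,
                cell=UnitCell(*p),
                spacegroup_number=cfg.spacegroup_number,
                wavelength=cfg.wavelength,
                hkl=obs_hkl,
                intensity=iobs,
                sigma=sig,
                phi=phi_hit[mask],
                source_path="",
            )
        )
        truth.k[ds_id] = float(k_j)
        truth.b[ds_id] = float(b_j)
        truth.cluster[ds_id] = int(cluster_of[j])
        truth.low_isa[ds_id] = bool(low_flags[j])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest_lines = []
        for ms in minisets:
            p = out_dir / f"{ms.id}.HKL"
            write_xds_ascii(ms, p)
            ms.source_path = str(p)
            manifest_lines.append(p.name)
        (out_dir / "manifest.txt").write_text("\n".join(manifest_lines) + "\n")
        truth.to_json(out_dir / "truth.json")
    return minisets, truth


def showcase_config(seed: int = 0, **overrides) -> SynthConfig:
    """Desk-scale recipe mirroring a serial experiment on a fixed target:
    a majority isomorphism cluster, a 20% non-isomorphous cluster
    (inter-cluster pCC ≈ 0.3) and 20% of datasets with large unreported
    systematic error (low ISa)."""
    base = dict(
        n_datasets=100,
        wedge_deg=10.0,
        clusters=(
            ClusterSpec(0.8),
            ClusterSpec(0.2, tau=2.0),
        ),
        low_isa_fraction=0.2,
        sigma_sys=0.5,
        seed=seed,
    )
    base.update(overrides)
    return SynthConfig(**base)
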