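"""Reading and writing miniset reflection files (XDS_ASCII.HKL dialect).

The dialect is plain ASCII: "!KEY= value" header lines, an ``!END_OF_HEADER``
marker, whitespace-delimited data records ``H K L IOBS SIGMA [PHI]`` and an
``!END_OF_DATA`` terminator.  Unknown header keys are ignored so files written
by other programs parse as long as they carry the cell and space-group
keywords.  Observations with σ ≤ 0 are dropped on read and counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np

from .exceptions import FormatError, MissingHeaderError
from .symmetry import UnitCell

__all__ = ["ReflectionObs", "Miniset", "read_xds_ascii", "write_xds_ascii", "read_manifest"]

_KEY_CELL = "UNIT_CELL_CONSTANTS"
_KEY_SG = "SPACE_GROUP_NUMBER"
_KEY_WAVELENGTH = "X-RAY_WAVELENGTH"
_KEY_FRIEDEL = "FRIEDEL'S_LAW"


class ReflectionObs(NamedTuple):
    """A single intensity observation of one Miller index."""

    h: int
    k: int
    l: int
    intensity: float
    sigma: float
    phi: float
    dataset_id: str


@dataclass
class Miniset:
    """One small-wedge dataset: cell, symmetry and its reflection observations.

    Observations are stored as parallel numpy arrays; iterate over
    :attr:`observations` for a record view.
    """

    id: str
    cell: UnitCell
    spacegroup_number: int
    wavelength: float
    hkl: np.ndarray  # (n, 3) int
    intensity: np.ndarray  # (n,) float
    sigma: np.ndarray  # (n,) float, all > 0
    phi: np.ndarray | None = None  # (n,) spindle angle, degrees
    friedel: bool = True  # Friedel pairs treated as equivalent
    source_path: str = ""
    n_dropped: int = 0  # records discarded on read (σ ≤ 0)

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.phi is not None:
            self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.hkl)
        if len(self.intensity) != n or len(self.sigma) != n:
            raise ValueError("hkl, intensity and sigma must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("all retained observations must have sigma > 0")
        if np.any(np.all(self.hkl == 0, axis=1)):
            raise ValueError("(0,0,0) is not a valid Miller index")

    @property
    def n_obs(self) -> int:
        return len(self.intensity)

    @property
    def observations(self) -> Iterator[ReflectionObs]:
        phi = self.phi if self.phi is not None else np.full(self.n_obs, np.nan)
        for i in range(self.n_obs):
            yield ReflectionObs(
                int(self.hkl[i, 0]),
                int(self.hkl[i, 1]),
                int(self.hkl[i, 2]),
                float(self.intensity[i]),
                float(self.sigma[i]),
                float(phi[i]),
                self.id,
            )


def _parse_header_line(line: str) -> tuple[str, str] | None:
    m = re.match(r"!\s*([^=]+?)\s*=\s*(.*)", line)
    if m is None:
        return None
    return m.group(1).strip(), m.group(2).strip()


def read_xds_ascii(path: str | Path, dataset_id: str | None = None) -> Miniset:
    """Read one reflection file; σ ≤ 0 records are dropped and counted."""
    path = Path(path)
    header: dict[str, str] = {}
    hkl, ii, ss, pp = [], [], [], []
    n_dropped = 0
    in_data = False
    has_phi = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("!"):
                if line == "!END_OF_HEADER":
                    in_data = True
                    continue
                if line == "!END_OF_DATA":
                    break
                if not in_data:
                    kv = _parse_header_line(line)
                    if kv is not None:
                        header[kv[0]] = kv[1]
                continue
            if not in_data:
                # data records before !END_OF_HEADER are not part of the dialect
                raise FormatError(f"{path}:{lineno}: data record before !END_OF_HEADER")
            fields = line.split()
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected ≥5 columns, got {len(fields)}")
            try:
                h, k, l = (int(float(x)) for x in fields[:3])
                inten, sig = float(fields[3]), float(fields[4])
                phi = float(fields[5]) if len(fields) >= 6 else None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric record field ({exc})") from None
            if sig <= 0:
                n_dropped += 1
                continue
            hkl.append((h, k, l))
            ii.append(inten)
            ss.append(sig)
            pp.append(phi if phi is not None else np.nan)
            if has_phi is None:
                has_phi = phi is not None

    for key in (_KEY_CELL, _KEY_SG):
        if key not in header:
            raise MissingHeaderError(f"{path}: mandatory header keyword !{key}= missing")
    try:
        cellvals = [float(x) for x in header[_KEY_CELL].split()[:6]]
        if len(cellvals) != 6:
            raise ValueError("need six cell constants")
        cell = UnitCell(*cellvals)
        sg_number = int(float(header[_KEY_SG]))
    except ValueError as exc:
        raise FormatError(f"{path}: bad header value ({exc})") from None
    wavelength = float(header.get(_KEY_WAVELENGTH, "0") or 0)
    friedel = header.get(_KEY_FRIEDEL, "TRUE").upper() != "FALSE"
    if not hkl:
        raise FormatError(f"{path}: no valid reflection records")
    return Miniset(
        id=dataset_id or path.stem,
        cell=cell,
        spacegroup_number=sg_number,
        wavelength=wavelength,
        hkl=np.array(hkl),
        intensity=np.array(ii),
        sigma=np.array(ss),
        phi=np.array(pp) if has_phi else None,
        friedel=friedel,
        source_path=str(path),
        n_dropped=n_dropped,
    )


def write_xds_ascii(ms: Miniset, path: str | Path) -> Path:
    """Write a Miniset so that :func:`read_xds_ascii` reproduces it."""
    if ms.n_obs == 0:
        raise ValueError("refusing to write a Miniset with no observations")
    path = Path(path)
    c = ms.cell
    with open(path, "w") as fh:
        fh.write("!FORMAT=XDS_ASCII    MERGE=FALSE\n")
        fh.write(
            f"!{_KEY_CELL}= {c.a:.4f} {c.b:.4f} {c.c:.4f}"
            f" {c.alpha:.3f} {c.beta:.3f} {c.gamma:.3f}\n"
        )
        fh.write(f"!{_KEY_SG}= {ms.spacegroup_number}\n")
        if ms.wavelength:
            fh.write(f"!{_KEY_WAVELENGTH}= {ms.wavelength:.6f}\n")
        fh.write(f"!{_KEY_FRIEDEL}= {'TRUE' if ms.friedel else 'FALSE'}\n")
        fh.write(f"!DATASET_ID= {ms.id}\n")
        fh.write("!END_OF_HEADER\n")
        phi = ms.phi
        for i in range(ms.n_obs):
            rec = (
                f"{ms.hkl[i, 0]:6d} {ms.hkl[i, 1]:6d} {ms.hkl[i, 2]:6d}"
                f" {ms.intensity[i]:.7g} {ms.sigma[i]:.7g}"
            )
            if phi is not None and np.isfinite(phi[i]):
                rec += f" {phi[i]:.4f}"
            fh.write(rec + "\n")
        fh.write("!END_OF_DATA\n")
    return path


def read_manifest(path: str | Path) -> list[Miniset]:
    """Read minisets listed one path per line ("#" starts a comment).

    Relative member paths resolve against the manifest's directory.  Ids
    default to the file stem; repeated stems get a numeric suffix ("x",
    "x-2", "x-3", ...).
    """
    path = Path(path)
    members: list[Path] = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        p = Path(line)
        members.append(p if p.is_absolute() else path.parent / p)
    if not members:
        raise FormatError(f"{path}: manifest lists no files")
    missing = [str(p) for p in members if not p.exists()]
    if missing:
        raise FormatError(f"{path}: missing member file(s): {', '.join(missing)}")
    seen: dict[str, int] = {}
    out = []
    for p in members:
        stem = p.stem
        seen[stem] = seen.get(stem, 0) + 1
        ds_id = stem if seen[stem] == 1 else f"{stem}-{seen[stem]}"
        out.append(read_xds_ascii(p, dataset_id=ds_id))
    return out


def paths_in_manifest(path: str | Path) -> list[Path]:
    """List member paths without reading them (used by the watch loop)."""
    path = Path(path)
    out = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            p = Path(line)
            out.append(p if p.is_absolute() else path.parent / p)
    return out
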