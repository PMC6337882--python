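"""Relative scaling and merging of many partial datasets.

The engine refines, for every dataset j against a fixed reference, a
multiplicative scale k_j and a relative isotropic B-factor, so that the
corrected intensity is I' = I / g_j(s²) with

    g_j(s²) = k_j · exp(−2 B_j s²),   s = 1/(2d).

Refinement alternates two exact weighted least-squares steps in log space:
(i) per-unique merged log-intensities given the current scales, and (ii)
per-dataset (ln k_j, B_j) given the merged values.  Each half-step minimises
the same weighted sum of squared log residuals, so the objective is
non-increasing — tracked in :attr:`ScalingResult.objective_history`.  Only
positive intensities inform the fit; all observations are corrected.

Merging is the usual inverse-variance weighted mean per unique reflection,
and quality statistics (R_meas, CC1/2, completeness, multiplicity, I/σ) are
reported in resolution shells holding equal numbers of unique reflections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SxmergeError, UndefinedModelError
from .reflection_io import Miniset
from .symmetry import SpaceGroupInfo, UnitCell, enumerate_asu, map_to_asu, resolution_d

__all__ = [
    "ScaleModel",
    "MergedReflections",
    "MergeStats",
    "ScalingResult",
    "observation_table",
    "wilson_b",
    "low_res_rmeas",
    "scale_datasets",
    "merge",
    "compute_stats",
]

MIN_SHARED_UNIQUES = 10  # connectivity threshold for inclusion in scaling


@dataclass(frozen=True)
class ScaleModel:
    """Fitted relative scale for one dataset; the reference is exactly (1, 0)."""

    dataset_id: str
    k: float
    b: float

    def correction(self, s2: np.ndarray) -> np.ndarray:
        return self.k * np.exp(-2.0 * self.b * np.asarray(s2))


@dataclass
class MergedReflections:
    """Unique-reflection view after merging.

    ``table`` columns: h, k, l (canonical), d, intensity, sigma,
    multiplicity, n_datasets.
    """

    table: pd.DataFrame
    anomalous: bool = False

    @property
    def n_unique(self) -> int:
        return len(self.table)

    @property
    def total_observations(self) -> int:
        return int(self.table["multiplicity"].sum())


@dataclass
class MergeStats:
    """Per-shell and overall merging statistics."""

    shells: pd.DataFrame  # d_max, d_min, n_unique, completeness, multiplicity,
    #                       r_meas, cc_half, i_over_sigma per shell (low→high res)
    overall: dict

    def to_dict(self) -> dict:
        shells = self.shells.where(pd.notna(self.shells), None)
        return {
            "overall": {k: (None if v is None or (isinstance(v, float) and np.isnan(v)) else v)
                        for k, v in self.overall.items()},
            "shells": shells.to_dict(orient="records"),
        }


@dataclass
class ScalingResult:
    models: list[ScaleModel]
    merged: MergedReflections
    table: pd.DataFrame  # per-observation table with corrected I/σ
    rejected: dict[str, str] = field(default_factory=dict)  # id -> reason
    objective_history: list[float] = field(default_factory=list)
    n_iter: int = 0
    reference_id: str = ""

    def model_for(self, dataset_id: str) -> ScaleModel:
        for m in self.models:
            if m.dataset_id == dataset_id:
                return m
        raise KeyError(dataset_id)


def _pack_key(hkl: np.ndarray) -> np.ndarray:
    return (hkl[:, 0].astype(np.int64) << 42) + (hkl[:, 1] << 21) + hkl[:, 2]


def observation_table(
    mss: list[Miniset],
    sg: SpaceGroupInfo,
    cell: UnitCell | None = None,
    anomalous: bool = False,
    d_min: float | None = None,
) -> pd.DataFrame:
    """Pool observations of several minisets into one flat table.

    Resolution is computed from a single common cell (the first miniset's
    unless given) so shell boundaries are consistent across datasets.
    """
    if not mss:
        raise ValueError("no minisets given")
    cell = cell or mss[0].cell
    frames = []
    for ms in mss:
        canon = map_to_asu(ms.hkl, sg, anomalous)
        d = resolution_d(cell, ms.hkl)
        frames.append(
            pd.DataFrame(
                {
                    "dataset": ms.id,
                    "hc": canon[:, 0],
                    "kc": canon[:, 1],
                    "lc": canon[:, 2],
                    "key": _pack_key(canon),
                    "d": d,
                    "I": ms.intensity,
                    "sigma": ms.sigma,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["s2"] = 1.0 / (4.0 * df["d"] ** 2)
    if d_min is not None:
        df = df[df["d"] >= d_min].reset_index(drop=True)
    return df


def _equal_count_shells(d_sorted_desc: np.ndarray, n_shells: int) -> np.ndarray:
    """Shell index (0 = lowest resolution) for pre-sorted descending d."""
    n = len(d_sorted_desc)
    return (np.arange(n) * n_shells) // max(n, 1)


def _shell_of(d: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Shell index per observation given inner edges (descending d)."""
    return np.searchsorted(-edges, -np.asarray(d), side="right")


def _shell_edges(d_unique: np.ndarray, n_shells: int) -> np.ndarray:
    """Inner boundaries (n_shells − 1 values, descending) of equal-count shells."""
    ds = np.sort(d_unique)[::-1]
    idx = (np.arange(1, n_shells) * len(ds)) // n_shells
    idx = np.clip(idx, 1, len(ds) - 1)
    return ds[idx]


def wilson_b(ms: Miniset, d_cut: float = 4.5, n_shells: int = 10) -> float:
    """Overall Wilson B-factor (Å²) from the slope of ln⟨I⟩ vs ⟨s²⟩.

    Uses observations at d < ``d_cut``; the fitted slope is −2B.  Raises
    :class:`UndefinedModelError` when fewer than two populated shells exist,
    in which case callers rank the dataset last as a reference candidate.
    """
    d = resolution_d(ms.cell, ms.hkl)
    sel = d < d_cut
    if sel.sum() < 40:
        raise UndefinedModelError(f"{ms.id}: too few reflections beyond {d_cut} Å")
    d = d[sel]
    inten = ms.intensity[sel]
    s2 = 1.0 / (4.0 * d * d)
    order = np.argsort(-d)
    nb = min(n_shells, len(d) // 20)
    if nb < 2:
        raise UndefinedModelError(f"{ms.id}: fewer than two Wilson shells")
    shell = _equal_count_shells(d[order], nb)
    mean_i = np.bincount(shell, weights=inten[order]) / np.bincount(shell)
    mean_s2 = np.bincount(shell, weights=s2[order]) / np.bincount(shell)
    good = mean_i > 0
    if good.sum() < 2:
        raise UndefinedModelError(f"{ms.id}: non-positive shell means in Wilson fit")
    slope = np.polyfit(mean_s2[good], np.log(mean_i[good]), 1)[0]
    return -0.5 * slope


def _rmeas(intensity: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Multiplicity-weighted merging R over groups with ≥ 2 observations."""
    n = np.bincount(codes, minlength=n_groups)
    sums = np.bincount(codes, weights=intensity, minlength=n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(n > 0, sums / np.maximum(n, 1), 0.0)
    absdev = np.bincount(codes, weights=np.abs(intensity - means[codes]), minlength=n_groups)
    multi = n >= 2
    if not multi.any():
        return float("nan")
    num = float(np.sum(np.sqrt(n[multi] / (n[multi] - 1.0)) * absdev[multi]))
    den = float(np.sum(sums[multi]))
    return num / den if den > 0 else float("nan")


def low_res_rmeas(ms: Miniset, sg: SpaceGroupInfo, n_shells: int = 10) -> float:
    """Mean internal R_meas over the three lowest-resolution shells.

    Shells hold equal numbers of the dataset's own unique reflections.
    Datasets without any repeated unique in those shells get +inf and are
    ranked last.
    """
    canon = map_to_asu(ms.hkl, sg, anomalous=not ms.friedel)
    key = _pack_key(canon)
    d = resolution_d(ms.cell, ms.hkl)
    uniq, codes = np.unique(key, return_inverse=True)
    # unique d = mean over its observations
    d_uniq = np.bincount(codes, weights=d) / np.bincount(codes)
    order = np.argsort(-d_uniq)
    shell_of_unique = np.empty(len(uniq), dtype=np.int64)
    shell_of_unique[order] = _equal_count_shells(d_uniq[order], n_shells)
    vals = []
    for s in range(min(3, n_shells)):
        in_shell = shell_of_unique[codes] == s
        if not in_shell.any():
            continue
        sub_codes, inv = np.unique(codes[in_shell], return_inverse=True)
        r = _rmeas(ms.intensity[in_shell], inv, len(sub_codes))
        if np.isfinite(r):
            vals.append(r)
    return float(np.mean(vals)) if vals else float("inf")


def scale_datasets(
    mss: list[Miniset],
    sg: SpaceGroupInfo,
    reference_id: str | None = None,
    cell: UnitCell | None = None,
    anomalous: bool = False,
    d_min: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> ScalingResult:
    """Refine per-dataset (k, B) against a common reference and merge.

    Alternating weighted least squares in log space typically needs a few
    tens of sweeps to push the relative scale change below ``tol``; each
    sweep is cheap, so the iteration cap is generous.

    Datasets sharing fewer than ``MIN_SHARED_UNIQUES`` unique reflections
    with the rest of the ensemble are excluded and reported as
    ``unconnected`` rather than failing the run.
    """
    if len(mss) < 2:
        raise SxmergeError("scaling needs at least two datasets")
    ids = [ms.id for ms in mss]
    reference_id = reference_id or ids[0]
    if reference_id not in ids:
        raise SxmergeError(f"reference dataset {reference_id!r} not among inputs")
    df = observation_table(mss, sg, cell=cell, anomalous=anomalous, d_min=d_min)

    # connectivity: uniques seen by ≥2 datasets
    per = df.drop_duplicates(["dataset", "key"])
    counts = per.groupby("key")["dataset"].size()
    shared_keys = set(counts.index[counts >= 2])
    rejected: dict[str, str] = {}
    for ds in ids:
        keys = set(per.loc[per["dataset"] == ds, "key"])
        n_shared = len(keys & shared_keys)
        n_pos = int(((df["dataset"] == ds) & (df["I"] > 0)).sum())
        if n_shared < MIN_SHARED_UNIQUES or n_pos < 3:
            rejected[ds] = "unconnected"
    if reference_id in rejected:
        raise SxmergeError(f"reference dataset {reference_id!r} is unconnected")
    kept = [i for i in ids if i not in rejected]
    if len(kept) < 2:
        raise SxmergeError("fewer than two connected datasets")
    df = df[df["dataset"].isin(kept)].reset_index(drop=True)

    ds_codes, ds_index = pd.factorize(df["dataset"], sort=False)
    ref_code = list(ds_index).index(reference_id)
    key_codes, _ = pd.factorize(df["key"], sort=True)
    n_ds, n_key = len(ds_index), key_codes.max() + 1

    pos = (df["I"].to_numpy() > 0)
    y = np.where(pos, np.log(np.where(pos, df["I"].to_numpy(), 1.0)), 0.0)
    s2 = df["s2"].to_numpy()
    with np.errstate(divide="ignore"):
        w = np.where(pos, (df["I"].to_numpy() / df["sigma"].to_numpy()) ** 2, 0.0)
    w = np.minimum(w, 1e6)

    lnk = np.zeros(n_ds)
    bfac = np.zeros(n_ds)
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        corr = y - (lnk[ds_codes] - 2.0 * bfac[ds_codes] * s2)
        wsum = np.bincount(key_codes, weights=w, minlength=n_key)
        msum = np.bincount(key_codes, weights=w * corr, minlength=n_key)
        with np.errstate(invalid="ignore"):
            m = np.where(wsum > 0, msum / np.maximum(wsum, 1e-300), 0.0)
        resid = corr - m[key_codes]
        history.append(float(np.sum(w * resid * resid)))

        new_lnk, new_b = lnk.copy(), bfac.copy()
        target = y - m[key_codes]
        for j in range(n_ds):
            if j == ref_code:
                continue
            sel = (ds_codes == j) & pos & (wsum[key_codes] > 0)
            if sel.sum() < 3:
                continue
            wj, xj, tj = w[sel], s2[sel], target[sel]
            # weighted LS of t = lnk − 2 B s²
            sw, sx = wj.sum(), np.sum(wj * xj)
            sxx, st, sxt = np.sum(wj * xj * xj), np.sum(wj * tj), np.sum(wj * xj * tj)
            det = sw * sxx - sx * sx
            if det <= 0:
                continue
            alpha = (sxx * st - sx * sxt) / det
            beta = (sw * sxt - sx * st) / det
            new_lnk[j], new_b[j] = alpha, -0.5 * beta
        delta = np.max(np.abs(np.expm1(new_lnk - lnk)))
        lnk, bfac = new_lnk, new_b
        if delta < tol:
            break

    models = [
        ScaleModel(ds_index[j], float(np.exp(lnk[j])), float(bfac[j])) for j in range(n_ds)
    ]
    g = np.exp(lnk[ds_codes] - 2.0 * bfac[ds_codes] * s2)
    df = df.assign(I_corr=df["I"] / g, sigma_corr=df["sigma"] / g)
    merged = merge(df, anomalous=anomalous)
    return ScalingResult(
        models=models,
        merged=merged,
        table=df,
        rejected=rejected,
        objective_history=history,
        n_iter=n_iter,
        reference_id=reference_id,
    )


def merge(table: pd.DataFrame, anomalous: bool = False) -> MergedReflections:
    """Inverse-variance weighted merge of corrected observations per unique."""
    icol = "I_corr" if "I_corr" in table else "I"
    scol = "sigma_corr" if "sigma_corr" in table else "sigma"
    w = 1.0 / table[scol] ** 2
    tmp = table.assign(_w=w, _wi=w * table[icol])
    grp = tmp.groupby("key", sort=True)
    agg = grp.agg(
        hc=("hc", "first"),
        kc=("kc", "first"),
        lc=("lc", "first"),
        d=("d", "mean"),
        wsum=("_w", "sum"),
        wisum=("_wi", "sum"),
        multiplicity=("key", "size"),
        n_datasets=("dataset", "nunique"),
    )
    out = pd.DataFrame(
        {
            "h": agg["hc"],
            "k": agg["kc"],
            "l": agg["lc"],
            "d": agg["d"],
            "intensity": agg["wisum"] / agg["wsum"],
            "sigma": 1.0 / np.sqrt(agg["wsum"]),
            "multiplicity": agg["multiplicity"],
            "n_datasets": agg["n_datasets"],
        }
    ).reset_index()
    return MergedReflections(table=out, anomalous=anomalous)


def compute_stats(
    merged: MergedReflections,
    table: pd.DataFrame,
    cell: UnitCell,
    sg: SpaceGroupInfo,
    n_shells: int = 10,
    seed: int = 13,
    anomalous: bool = False,
    d_min: float | None = None,
    d_max: float | None = None,
) -> MergeStats:
    """Shelled merging statistics for a scaled ensemble.

    Shells hold equal numbers of observed unique reflections.  CC1/2 uses a
    seeded random half-split of each unique's observations (the extra
    observation of an odd multiplicity goes to half A); shells with fewer
    than 3 splittable uniques report CC1/2 as undefined.  Completeness
    counts expected unique reflections from the cell and symmetry between
    the data's resolution limits (or the given ``d_min``/``d_max``).
    """
    mt = merged.table
    if len(mt) == 0:
        raise SxmergeError("no merged reflections")
    nsh = max(1, min(n_shells, len(mt) // 3 or 1))
    edges = _shell_edges(mt["d"].to_numpy(), nsh)
    shell_m = _shell_of(mt["d"].to_numpy(), edges)

    lo = d_min if d_min is not None else float(mt["d"].min())
    hi = d_max if d_max is not None else float(mt["d"].max())
    _, d_theory = enumerate_asu(cell, sg, d_min=lo, d_max=hi * (1 + 1e-9), anomalous=anomalous)
    shell_t = _shell_of(d_theory, edges)
    n_theory = np.bincount(shell_t, minlength=nsh).astype(float)

    icol = "I_corr" if "I_corr" in table else "I"
    key_codes, key_index = pd.factorize(table["key"], sort=True)
    n_key = len(key_index)
    key_to_row = pd.Series(np.arange(len(mt)), index=mt["key"]).reindex(key_index).to_numpy()
    shell_obs = shell_m[key_to_row][key_codes]
    inten = table[icol].to_numpy()

    # seeded half-split per unique
    rng = np.random.default_rng(seed)
    r = rng.random(len(table))
    order = np.lexsort((r, key_codes))
    pos_in_group = np.arange(len(table)) - np.searchsorted(key_codes[order], key_codes[order])
    group_sizes = np.bincount(key_codes, minlength=n_key)
    half_a_sorted = pos_in_group < np.ceil(group_sizes[key_codes[order]] / 2.0)
    half_a = np.empty(len(table), dtype=bool)
    half_a[order] = half_a_sorted

    sum_a = np.bincount(key_codes[half_a], weights=inten[half_a], minlength=n_key)
    cnt_a = np.bincount(key_codes[half_a], minlength=n_key)
    sum_b = np.bincount(key_codes[~half_a], weights=inten[~half_a], minlength=n_key)
    cnt_b = np.bincount(key_codes[~half_a], minlength=n_key)
    splittable = (cnt_a > 0) & (cnt_b > 0)
    with np.errstate(invalid="ignore"):
        mean_a = np.where(splittable, sum_a / np.maximum(cnt_a, 1), np.nan)
        mean_b = np.where(splittable, sum_b / np.maximum(cnt_b, 1), np.nan)
    shell_key = shell_m[key_to_row]

    def _cc(sel: np.ndarray) -> float:
        sel = sel & splittable
        if sel.sum() < 3:
            return float("nan")
        a, b = mean_a[sel], mean_b[sel]
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    rows = []
    for s in range(nsh):
        in_shell_obs = shell_obs == s
        sub_codes, inv = np.unique(key_codes[in_shell_obs], return_inverse=True)
        r_meas = (
            _rmeas(inten[in_shell_obs], inv, len(sub_codes)) if in_shell_obs.any() else np.nan
        )
        in_shell_m = shell_m == s
        msub = mt[in_shell_m]
        rows.append(
            {
                "shell": s,
                "d_max": float(msub["d"].max()) if in_shell_m.any() else np.nan,
                "d_min": float(msub["d"].min()) if in_shell_m.any() else np.nan,
                "n_unique": int(in_shell_m.sum()),
                "completeness": float(in_shell_m.sum() / n_theory[s]) if n_theory[s] > 0 else np.nan,
                "multiplicity": float(msub["multiplicity"].mean()) if in_shell_m.any() else np.nan,
                "r_meas": r_meas,
                "cc_half": _cc(shell_key == s),
                "i_over_sigma": float((msub["intensity"] / msub["sigma"]).mean())
                if in_shell_m.any()
                else np.nan,
            }
        )
    shells = pd.DataFrame(rows)
    overall = {
        "n_unique": int(len(mt)),
        "n_observations": int(len(table)),
        "completeness": float(len(mt) / n_theory.sum()) if n_theory.sum() > 0 else np.nan,
        "multiplicity": float(mt["multiplicity"].mean()),
        "r_meas": _rmeas(inten, key_codes, n_key),
        "cc_half": _cc(np.ones(n_key, dtype=bool)),
        "i_over_sigma": float((mt["intensity"] / mt["sigma"]).mean()),
        "d_min": float(mt["d"].min()),
        "d_max": float(mt["d"].max()),
    }
    return MergeStats(shells=shells, overall=overall)
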