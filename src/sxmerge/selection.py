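"""Dataset selection stages for multi-crystal merging.

Four filters run in cascade on an ensemble of minisets: indexing
consistency against a reference cell and space group; ISa-based rejection
of datasets with large systematic error; hierarchical clustering of
unit-cell shape; and hierarchical clustering of pairwise intensity
correlations (pCC) restricted to the medium-resolution 4–8 Å window, where
correlations discriminate isomorphism best.  Cell and pCC selection both
branch from the ISa-selected set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, pi, sqrt

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .error_model import ErrorModel
from .exceptions import UndefinedModelError
from .reflection_io import Miniset
from .scaling import low_res_rmeas, wilson_b
from .symmetry import SpaceGroupInfo, UnitCell

__all__ = [
    "StageReport",
    "SelectionReport",
    "LinkageResult",
    "check_indexing_consistency",
    "choose_reference",
    "rank_by_rmeas",
    "isa_select",
    "cell_resultant_point",
    "cell_cluster_select",
    "pairwise_cc_matrix",
    "pcc_cluster_select",
]

# machine-readable rejection reasons
BAD_CELL = "bad_cell"
BAD_SPACEGROUP = "bad_spacegroup"
LOW_ISA = "low_isa"
CELL_OUTLIER = "cell_outlier"
PCC_OUTLIER = "pcc_outlier"
UNCONNECTED = "unconnected"


@dataclass
class StageReport:
    """Accept/reject ledger of one selection stage."""

    name: str
    accepted: list[str]
    rejected: dict[str, str] = field(default_factory=dict)  # id -> reason code
    info: dict = field(default_factory=dict)
    failed: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "accepted": list(self.accepted),
            "rejected": dict(sorted(self.rejected.items())),
            "info": self.info,
            "failed": self.failed,
        }


@dataclass
class SelectionReport:
    """Ordered collection of stage reports for one pipeline run."""

    stages: list[StageReport] = field(default_factory=list)

    def add(self, stage: StageReport) -> StageReport:
        self.stages.append(stage)
        return stage

    def stage(self, name: str) -> StageReport:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {"stages": [s.to_dict() for s in self.stages]}


@dataclass
class LinkageResult:
    """Agglomerative merge tree plus the flat cut used for selection."""

    merge_tree: np.ndarray  # scipy linkage matrix, (n−1, 4)
    labels: list[str]
    cut_height: float
    clusters: dict[str, int]  # label -> cluster id (1-based)
    selected: list[str]

    def to_dict(self) -> dict:
        return {
            "merge_tree": [[float(x) for x in row] for row in self.merge_tree],
            "labels": list(self.labels),
            "cut_height": float(self.cut_height),
            "clusters": {k: int(v) for k, v in self.clusters.items()},
            "selected": list(self.selected),
        }


def check_indexing_consistency(
    mss: list[Miniset], reference: Miniset | None = None, tol: float = 0.05
) -> StageReport:
    """Reject datasets whose cell deviates > ``tol`` (relative, any of the six
    parameters) from the reference, or whose space group differs.

    The reference defaults to the first dataset of the list.
    """
    if not mss:
        raise ValueError("no datasets")
    ref = reference or mss[0]
    accepted, rejected = [], {}
    for ms in mss:
        if ms.spacegroup_number != ref.spacegroup_number:
            rejected[ms.id] = BAD_SPACEGROUP
            continue
        rel = [
            abs(p - q) / q for p, q in zip(ms.cell.parameters, ref.cell.parameters)
        ]
        if max(rel) > tol:
            rejected[ms.id] = BAD_CELL
        else:
            accepted.append(ms.id)
    return StageReport(
        "indexing", accepted, rejected, info={"reference": ref.id, "tolerance": tol}
    )


def choose_reference(mss: list[Miniset], sg: SpaceGroupInfo | None = None) -> str:
    """Dataset with the lowest Wilson B-factor (ties: smaller id).

    If no dataset has a defined Wilson B, fall back to the best (lowest)
    low-resolution R_meas ranking.
    """
    if not mss:
        raise ValueError("no datasets")
    best_id, best_b = None, np.inf
    for ms in mss:
        try:
            b = wilson_b(ms)
        except UndefinedModelError:
            continue
        if b < best_b or (b == best_b and (best_id is None or ms.id < best_id)):
            best_id, best_b = ms.id, b
    if best_id is not None:
        return best_id
    if sg is not None:
        return rank_by_rmeas(mss, sg)[0]
    return mss[0].id


def rank_by_rmeas(mss: list[Miniset], sg: SpaceGroupInfo) -> list[str]:
    """Ids in ascending order of low-resolution internal R_meas (stable)."""
    vals = [(low_res_rmeas(ms, sg), i, ms.id) for i, ms in enumerate(mss)]
    vals.sort(key=lambda t: (t[0], t[1]))
    return [v[2] for v in vals]


def isa_select(models: list[ErrorModel], isa_cutoff: float = 3.0) -> StageReport:
    """Keep datasets with fitted ISa ≥ cutoff; undefined models are rejected."""
    accepted, rejected = [], {}
    isa_table = {}
    for m in models:
        isa_table[m.dataset_id] = None if not m.defined else m.isa
        if m.defined and m.isa >= isa_cutoff:
            accepted.append(m.dataset_id)
        else:
            rejected[m.dataset_id] = LOW_ISA
    report = StageReport(
        "isa", accepted, rejected, info={"cutoff": isa_cutoff, "isa": isa_table}
    )
    if not accepted:
        report.failed = True
    return report


def cell_resultant_point(cell: UnitCell) -> np.ndarray:
    """Diagonal lengths of the ab, bc and ca cell faces.

    This three-dimensional summary of the six cell parameters
    (|a+b|, |b+c|, |c+a|) is what the cell-clustering distance operates on.
    """
    a, b, c, al, be, ga = cell.parameters
    return np.array(
        [
            sqrt(a * a + b * b + 2 * a * b * cos(ga * pi / 180.0)),
            sqrt(b * b + c * c + 2 * b * c * cos(al * pi / 180.0)),
            sqrt(c * c + a * a + 2 * c * a * cos(be * pi / 180.0)),
        ]
    )


def _most_populated(
    labels: list[str], assignment: np.ndarray, reference_id: str | None
) -> tuple[int, list[str]]:
    """Largest cluster; ties prefer the reference's cluster, then the cluster
    whose lexicographically smallest member is smallest."""
    ids = np.asarray(labels)
    sizes: dict[int, int] = {}
    for c in assignment:
        sizes[int(c)] = sizes.get(int(c), 0) + 1
    best = None
    for c, size in sizes.items():
        members = sorted(ids[assignment == c])
        has_ref = reference_id is not None and reference_id in members
        cand = (-size, 0 if has_ref else 1, members[0])
        if best is None or cand < best[0]:
            best = (cand, c, members)
    return best[1], best[2]


def cell_cluster_select(
    mss: list[Miniset],
    reference_id: str | None = None,
    rms_cutoff: float = 2.0,
    big_n: int = 200,
    sigma_win: float = 1.5,
) -> tuple[LinkageResult | None, StageReport]:
    """Select the dominant unit-cell cluster.

    Below ``big_n`` datasets: Ward linkage on Euclidean distances between
    cell resultant points, tree cut at ``rms_cutoff`` (Å), most populated
    cluster kept.  At ``big_n`` or more: per-parameter Gaussian filter
    keeping datasets with all six cell parameters within mean ± sigma_win·σ.
    """
    ids = [ms.id for ms in mss]
    if len(mss) == 1:
        return None, StageReport("cell", ids, info={"method": "trivial"})
    if len(mss) < big_n:
        pts = np.array([cell_resultant_point(ms.cell) for ms in mss])
        if np.allclose(pts, pts[0]):
            return (
                None,
                StageReport("cell", ids, info={"method": "ward", "note": "identical cells"}),
            )
        tree = linkage(pts, method="ward")
        assignment = fcluster(tree, t=rms_cutoff, criterion="distance")
        _, selected = _most_populated(ids, assignment, reference_id)
        result = LinkageResult(
            merge_tree=tree,
            labels=ids,
            cut_height=rms_cutoff,
            clusters={i: int(c) for i, c in zip(ids, assignment)},
            selected=selected,
        )
        rejected = {i: CELL_OUTLIER for i in ids if i not in selected}
        return result, StageReport("cell", selected, rejected, info={"method": "ward"})
    params = np.array([ms.cell.parameters for ms in mss])
    mean = params.mean(axis=0)
    sd = params.std(axis=0, ddof=1)
    ok = np.all(np.abs(params - mean) <= sigma_win * np.maximum(sd, 1e-12), axis=1)
    accepted = [i for i, good in zip(ids, ok) if good]
    rejected = {i: CELL_OUTLIER for i, good in zip(ids, ok) if not good}
    return None, StageReport(
        "cell",
        accepted,
        rejected,
        info={"method": "gaussian", "mean": mean.tolist(), "sigma": sd.tolist()},
    )


def pairwise_cc_matrix(
    table: pd.DataFrame,
    d_max: float = 8.0,
    d_min: float = 4.0,
    min_common: int = 3,
) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Pairwise Pearson correlations of common unique intensities.

    ``table`` is an observation table (see ``scaling.observation_table``),
    ideally with scaled intensities.  Each dataset is reduced to its mean
    intensity per unique reflection within the [d_min, d_max] window; entry
    (i, j) correlates the uniques common to both.  Pairs with fewer than
    ``min_common`` common uniques get CC 0 and are returned as flagged.
    """
    icol = "I_corr" if "I_corr" in table else "I"
    win = table[(table["d"] >= d_min) & (table["d"] <= d_max)]
    ids = sorted(table["dataset"].unique())
    means = {
        ds: sub.groupby("key")[icol].mean()
        for ds, sub in win.groupby("dataset")
    }
    n = len(ids)
    cc = np.eye(n)
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            a = means.get(ids[i])
            b = means.get(ids[j])
            val = 0.0
            if a is not None and b is not None:
                common = a.index.intersection(b.index)
                if len(common) >= min_common:
                    x, y = a[common].to_numpy(), b[common].to_numpy()
                    if np.std(x) > 0 and np.std(y) > 0:
                        val = float(np.corrcoef(x, y)[0, 1])
                    else:
                        flagged.append((ids[i], ids[j]))
                else:
                    flagged.append((ids[i], ids[j]))
            else:
                flagged.append((ids[i], ids[j]))
            cc[i, j] = cc[j, i] = val
    return cc, ids, flagged


def pcc_cluster_select(
    matrix: np.ndarray,
    labels: list[str],
    cut: float = 0.8,
    metric: str = "rows",
    reference_id: str | None = None,
) -> tuple[LinkageResult, StageReport]:
    """Average-linkage clustering of the pairwise-CC matrix; keep the most
    populated cluster below the ``cut`` dissimilarity height.

    ``metric='rows'`` (default): each dataset's dissimilarity is one minus
    the Pearson correlation between its row of the CC matrix and the other
    dataset's row.  ``metric='sqrt1mcc2'``: dissimilarity sqrt(1 − CC²)
    directly from each pairwise CC.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix/label size mismatch")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("CC matrix must be symmetric")
    if metric == "rows":
        # correlate CC-profile rows, leaving out the two self entries so the
        # unit diagonal cannot anti-correlate otherwise identical profiles
        diss = np.zeros((n, n))
        cols = np.arange(n)
        if n == 2:  # no off-pair columns left to correlate
            diss[0, 1] = diss[1, 0] = 1.0 - matrix[0, 1]
        for i in range(n if n > 2 else 0):
            for j in range(i + 1, n):
                keep = (cols != i) & (cols != j)
                x, y = matrix[i, keep], matrix[j, keep]
                sx_, sy_ = np.std(x), np.std(y)
                if sx_ > 0 and sy_ > 0:
                    r = float(np.corrcoef(x, y)[0, 1])
                elif np.allclose(x, y):
                    r = 1.0
                else:
                    r = 0.0
                diss[i, j] = diss[j, i] = 1.0 - r
    elif metric == "sqrt1mcc2":
        diss = np.sqrt(np.maximum(0.0, 1.0 - matrix**2))
    else:
        raise ValueError(f"unknown pCC metric {metric!r}")
    np.fill_diagonal(diss, 0.0)
    diss = np.maximum(diss, 0.0)
    condensed = squareform((diss + diss.T) / 2.0, checks=False)
    tree = linkage(condensed, method="average")
    assignment = fcluster(tree, t=cut, criterion="distance")
    _, selected = _most_populated(labels, assignment, reference_id)
    result = LinkageResult(
        merge_tree=tree,
        labels=list(labels),
        cut_height=cut,
        clusters={lab: int(c) for lab, c in zip(labels, assignment)},
        selected=selected,
    )
    rejected = {lab: PCC_OUTLIER for lab in labels if lab not in selected}
    return result, StageReport("pcc", selected, rejected, info={"metric": metric, "cut": cut})
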