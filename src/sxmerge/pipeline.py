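"""Cascade orchestration: read → consistency → scale → select → report.

One run executes, in order: indexing-consistency filtering, reference
choice (lowest Wilson B) and R_meas ranking, a no-selection scaling round
(noSelect), error-model fitting and the ISa filter with re-scaling
(ISa_Select), then — in parallel from the ISa-selected set — unit-cell
cluster selection (Cell_Select) and pairwise-CC cluster selection
(pCC_Select), plus orientation/anisotropy diagnostics of every scaled set.
All four merged reflection files are always written; picking between them
is left to the experimenter.  A failed stage is logged and marked in the
report, and downstream stages continue from the last successful set.

Incremental ("watch") mode counts minisets as they appear and re-runs the
cascade at a fixed trigger schedule of counts (10, 20, …, 100, 120, …,
200, 250, …, 800), persisting its state after every update so an
interrupted session resumes where it stopped.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag
from . import selection as sel
from .error_model import ErrorModel, fit_error_model
from .exceptions import SxmergeError
from .reflection_io import Miniset, read_manifest, read_xds_ascii, write_xds_ascii
from .scaling import MergeStats, ScalingResult, compute_stats, scale_datasets
from .symmetry import UnitCell, get_spacegroup

logger = logging.getLogger("sxmerge")

__all__ = [
    "PipelineConfig",
    "RunState",
    "PipelineResult",
    "run_pipeline",
    "should_trigger",
    "watch_once",
    "watch_and_merge",
    "DEFAULT_TRIGGER_SCHEDULE",
]

DEFAULT_TRIGGER_SCHEDULE: tuple[int, ...] = tuple(
    list(range(10, 101, 10)) + list(range(120, 201, 20)) + list(range(250, 801, 50))
)


@dataclass
class PipelineConfig:
    """All knobs of one merging run; YAML-serialisable."""

    manifest: str = ""
    merge_id: str = "merge"
    out_dir: str = "sxmerge_out"
    d_min: float | None = None
    isa_cutoff: float = 3.0
    reference: str | None = None
    cell_tol: float = 0.05
    pcc_d_min: float = 4.0
    pcc_d_max: float = 8.0
    pcc_cut: float = 0.8
    pcc_metric: str = "rows"
    cell_rms_cutoff: float = 2.0
    big_n: int = 200
    sigma_win: float = 1.5
    n_shells: int = 10
    anomalous: bool = False
    seed: int = 13
    trigger_schedule: tuple[int, ...] = DEFAULT_TRIGGER_SCHEDULE

    def __post_init__(self) -> None:
        if self.d_min is not None and self.d_min <= 0:
            raise ValueError("d_min must be positive")
        for name in ("isa_cutoff", "cell_tol", "pcc_cut", "cell_rms_cutoff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "trigger_schedule" in data:
            data["trigger_schedule"] = tuple(data["trigger_schedule"])
        return cls(**data)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items()}
        out["trigger_schedule"] = list(self.trigger_schedule)
        return out


@dataclass
class RunState:
    """Persistent counters of the incremental mode (write-through JSON)."""

    merge_id: str = "merge"
    minisets_seen: int = 0
    last_triggered_count: int = 0
    seen_paths: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path, merge_id: str = "merge") -> "RunState":
        path = Path(path)
        if not path.exists():
            return cls(merge_id=merge_id)
        try:
            data = json.loads(path.read_text())
            return cls(**data)
        except Exception:
            logger.warning("corrupted state file %s — starting fresh", path)
            return cls(merge_id=merge_id)


@dataclass
class PipelineResult:
    report: sel.SelectionReport
    stats: dict[str, MergeStats]
    scaling: dict[str, ScalingResult]
    error_models: list[ErrorModel]
    reference_id: str | None
    artifacts: dict[str, str]

    def accepted(self, stage: str) -> list[str]:
        return self.report.stage(stage).accepted


def should_trigger(n_seen: int, schedule: tuple[int, ...] = DEFAULT_TRIGGER_SCHEDULE) -> bool:
    """True when the running miniset count sits on the merge schedule."""
    return n_seen in schedule


def _json_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) or np.isinf(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _json_ready(obj.tolist())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _merged_to_miniset(result: ScalingResult, merge_id: str, stage: str,
                       cell: UnitCell, sg_number: int, wavelength: float) -> Miniset:
    mt = result.merged.table
    return Miniset(
        id=f"{merge_id}_{stage}",
        cell=cell,
        spacegroup_number=sg_number,
        wavelength=wavelength,
        hkl=mt[["h", "k", "l"]].to_numpy(),
        intensity=mt["intensity"].to_numpy(),
        sigma=mt["sigma"].to_numpy(),
    )


_STAGE_FILES = {
    "noSelect": "noSelect.HKL",
    "ISa_Select": "ISa_Select.HKL",
    "Cell_Select": "Cell_Select.HKL",
    "pCC_Select": "pCC_Select.HKL",
}


def run_pipeline(
    cfg: PipelineConfig, minisets: list[Miniset] | None = None
) -> PipelineResult:
    """Execute the full selection/scaling cascade and write all artifacts."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if minisets is None:
        minisets = read_manifest(cfg.manifest)
    if len(minisets) < 2:
        raise SxmergeError("pipeline needs at least two minisets")
    by_id = {ms.id: ms for ms in minisets}
    report = sel.SelectionReport()
    stats: dict[str, MergeStats] = {}
    scaling: dict[str, ScalingResult] = {}
    artifacts: dict[str, str] = {}

    # indexing consistency against the configured or first dataset
    idx_reference = by_id.get(cfg.reference) if cfg.reference else None
    stage = report.add(
        sel.check_indexing_consistency(minisets, idx_reference, tol=cfg.cell_tol)
    )
    consistent = [by_id[i] for i in stage.accepted]
    if len(consistent) < 2:
        raise SxmergeError("fewer than two indexing-consistent minisets")
    sg = get_spacegroup(consistent[0].spacegroup_number)
    cell = consistent[0].cell

    # reference choice (lowest Wilson B) and R_meas ranking
    reference_id = sel.choose_reference(consistent, sg)
    order = sel.rank_by_rmeas(consistent, sg)
    rank = {ds: i for i, ds in enumerate(order)}
    consistent.sort(key=lambda ms: rank[ms.id])
    report.add(
        sel.StageReport(
            "ranking",
            order,
            info={"reference": reference_id, "order": order},
        )
    )
    for ms in consistent:
        logger.info("ranked %s (reference=%s)", ms.id, reference_id)

    def scale_stage(stage_name: str, members: list[Miniset]) -> ScalingResult:
        result = scale_datasets(
            members,
            sg,
            reference_id=reference_id if reference_id in {m.id for m in members} else None,
            cell=cell,
            anomalous=cfg.anomalous,
            d_min=cfg.d_min,
        )
        st = compute_stats(
            result.merged,
            result.table,
            cell,
            sg,
            n_shells=cfg.n_shells,
            seed=cfg.seed,
            anomalous=cfg.anomalous,
            d_min=cfg.d_min,
        )
        stats[stage_name] = st
        scaling[stage_name] = result
        ms = _merged_to_miniset(result, cfg.merge_id, stage_name, cell, sg.number,
                                members[0].wavelength)
        path = out_dir / _STAGE_FILES[stage_name]
        write_xds_ascii(ms, path)
        artifacts[stage_name] = str(path)
        (out_dir / f"{stage_name}_stats.json").write_text(
            json.dumps(_json_ready(st.to_dict()), indent=1, sort_keys=True)
        )
        return result

    # no-selection scaling
    no_select = scale_stage("noSelect", consistent)
    if no_select.rejected:
        rep = report.stage("ranking")
        rep.rejected.update(no_select.rejected)
        rep.accepted = [i for i in rep.accepted if i not in no_select.rejected]
    current = [by_id[i] for i in report.stage("ranking").accepted]

    # error-model fit per dataset against the pooled merged means
    table = no_select.table
    key_codes, _ = pd.factorize(table["key"], sort=True)
    sizes = np.bincount(key_codes)
    sums = np.bincount(key_codes, weights=table["I_corr"].to_numpy())
    means = sums / np.maximum(sizes, 1)
    models = []
    for ms in current:
        mask = (table["dataset"] == ms.id).to_numpy()
        models.append(
            fit_error_model(
                table["I_corr"].to_numpy()[mask],
                table["sigma_corr"].to_numpy()[mask],
                key_codes[mask],
                dataset_id=ms.id,
                group_means=means,
                group_sizes=sizes,
            )
        )
    isa_stage = sel.isa_select(models, isa_cutoff=cfg.isa_cutoff)
    report.add(isa_stage)
    if isa_stage.failed or len(isa_stage.accepted) < 2:
        logger.warning("ISa stage rejected (almost) everything — continuing unfiltered")
        isa_stage.failed = True
        isa_members = current
    else:
        isa_members = [by_id[i] for i in isa_stage.accepted]
    isa_result = scale_stage("ISa_Select", isa_members)

    # cell selection and pCC selection, both from the ISa-selected set
    try:
        cell_link, cell_stage = sel.cell_cluster_select(
            isa_members,
            reference_id=reference_id,
            rms_cutoff=cfg.cell_rms_cutoff,
            big_n=cfg.big_n,
            sigma_win=cfg.sigma_win,
        )
        report.add(cell_stage)
        if cell_link is not None:
            (out_dir / "cell_dendrogram.json").write_text(
                json.dumps(_json_ready(cell_link.to_dict()), indent=1, sort_keys=True)
            )
        if len(cell_stage.accepted) >= 2:
            scale_stage("Cell_Select", [by_id[i] for i in cell_stage.accepted])
    except Exception as exc:  # degrade gracefully, keep the cascade running
        logger.exception("cell-selection stage failed: %s", exc)
        report.add(sel.StageReport("cell", [m.id for m in isa_members], failed=True))

    try:
        cc, cc_ids, flagged = sel.pairwise_cc_matrix(
            isa_result.table, d_max=cfg.pcc_d_max, d_min=cfg.pcc_d_min
        )
        pcc_link, pcc_stage = sel.pcc_cluster_select(
            cc, cc_ids, cut=cfg.pcc_cut, metric=cfg.pcc_metric, reference_id=reference_id
        )
        pcc_stage.info["n_flagged_pairs"] = len(flagged)
        report.add(pcc_stage)
        (out_dir / "pcc_dendrogram.json").write_text(
            json.dumps(_json_ready(pcc_link.to_dict()), indent=1, sort_keys=True)
        )
        if len(pcc_stage.accepted) >= 2:
            scale_stage("pCC_Select", [by_id[i] for i in pcc_stage.accepted])
    except Exception as exc:
        logger.exception("pCC-selection stage failed: %s", exc)
        report.add(sel.StageReport("pcc", [m.id for m in isa_members], failed=True))

    # diagnostics of every scaled set
    diagnostics_block: dict[str, dict] = {}
    for stage_name, result in scaling.items():
        entry: dict = {}
        try:
            from .symmetry import count_unique

            mt = result.merged.table
            n_exp = count_unique(
                cell, sg,
                d_max=float(mt["d"].max()) * (1 + 1e-9),
                d_min=float(mt["d"].min()),
            )
            orient = diag.multiplicity_report(result.merged, n_expected=n_exp)
            entry["orientation"] = orient.to_dict()
            hist_lines = ["multiplicity\tcount"] + [
                f"{m}\t{c}" for m, c in sorted(orient.histogram.items())
            ]
            (out_dir / f"{stage_name}_multiplicity.tsv").write_text(
                "\n".join(hist_lines) + "\n"
            )
        except ValueError as exc:
            entry["orientation"] = {"error": str(exc)}
        try:
            entry["anisotropy"] = diag.anisotropy_limits(result.merged, cell).to_dict()
        except Exception as exc:
            entry["anisotropy"] = {"error": str(exc)}
        diagnostics_block[stage_name] = entry

    payload = {
        "merge_id": cfg.merge_id,
        "config": _json_ready(cfg.to_dict()),
        "n_input": len(minisets),
        "reference": reference_id,
        "stages": _json_ready(report.to_dict()["stages"]),
        "scale_models": {
            name: {
                m.dataset_id: {"k": m.k, "b": m.b} for m in result.models
            }
            for name, result in scaling.items()
        },
        "error_models": {
            m.dataset_id: (
                {"a": m.a, "b": m.b, "isa": m.isa, "n_groups": m.n_groups_used}
                if m.defined
                else {"undefined": m.reason}
            )
            for m in models
        },
        "stats": {name: st.to_dict() for name, st in stats.items()},
        "diagnostics": diagnostics_block,
        "artifacts": artifacts,
    }
    (out_dir / "report.json").write_text(
        json.dumps(_json_ready(payload), indent=1, sort_keys=True)
    )
    artifacts["report"] = str(out_dir / "report.json")
    return PipelineResult(
        report=report,
        stats=stats,
        scaling=scaling,
        error_models=models,
        reference_id=reference_id,
        artifacts=artifacts,
    )


def _list_member_paths(cfg: PipelineConfig) -> list[Path]:
    src = Path(cfg.manifest)
    if src.is_dir():
        return sorted(src.glob("*.HKL"))
    from .reflection_io import paths_in_manifest

    return paths_in_manifest(src)


def watch_once(cfg: PipelineConfig, state: RunState, state_path: str | Path) -> int:
    """One poll of the incremental mode; returns the number of merges run.

    New files are counted one at a time; the state file is rewritten after
    every counter change, so a crash resumes without re-triggering merges.
    """
    n_runs = 0
    known = set(state.seen_paths)
    for p in _list_member_paths(cfg):
        sp = str(p)
        if sp in known:
            continue
        state.seen_paths.append(sp)
        state.minisets_seen += 1
        known.add(sp)
        state.save(state_path)
        if (
            should_trigger(state.minisets_seen, cfg.trigger_schedule)
            and state.minisets_seen > state.last_triggered_count
        ):
            minisets = [read_xds_ascii(Path(q)) for q in state.seen_paths]
            run_cfg = replace(
                cfg, out_dir=str(Path(cfg.out_dir) / f"n{state.minisets_seen:04d}")
            )
            logger.info("trigger at %d minisets", state.minisets_seen)
            run_pipeline(run_cfg, minisets=minisets)
            state.last_triggered_count = state.minisets_seen
            state.save(state_path)
            n_runs += 1
    return n_runs


def watch_and_merge(
    cfg: PipelineConfig,
    state_path: str | Path | None = None,
    poll_interval: float = 5.0,
    max_polls: int | None = None,
) -> RunState:
    """Poll for new minisets and merge on schedule until ``max_polls`` is
    exhausted (or forever when None)."""
    state_path = Path(state_path or Path(cfg.out_dir) / "run_state.json")
    state_path.parent.mkdir(parents=True, exist_ok=True)
    state = RunState.load(state_path, merge_id=cfg.merge_id)
    polls = 0
    while True:
        watch_once(cfg, state, state_path)
        polls += 1
        if max_polls is not None and polls >= max_polls:
            return state
        time.sleep(poll_interval)
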