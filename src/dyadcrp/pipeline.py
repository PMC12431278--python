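"""End-to-end orchestration: data → indices → day prep → plots → SOM → regression.

The pipeline reproduces the full analysis on either ingested CSV data or a
simulated cohort: artifact-gated HRV indices on a 60 s grid, 22:00-aligned
day segments (fill / normalize / discretize), recurrence and
cross-recurrence plots per dyad-day, one SOM per plot family × index, and
the nine PSI regressions with a ranked comparison.

Every random stage consumes a seed derived deterministically from the
top-level seed by hashing the stage name, so re-running an identical
config reproduces the report bit-for-bit while stages stay independent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .dayprep import DaySegment, Rejection, prepare_days, segment_days
from .hrv import INDEX_KINDS, clean_rr, sliding_indices
from .recurrence import RecurrenceConfig, build_crp, build_rp, to_image
from .regression import RegressionResult, compare_models, fit_psi_model
from .simulate import CohortSimConfig, simulate_cohort
from .som import SOMFeatureExtractor

log = logging.getLogger("dyadcrp")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "stage_seed"]

PLOT_FAMILIES = ("rp_mother", "rp_child", "crp")


def stage_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived by hashing the stage name."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; every analysis constant is a named key."""

    mode: str = "simulate"  # simulate | index-csv | rr-csv
    # ingest paths (index-csv / rr-csv modes)
    mother_csv: str | None = None
    child_csv: str | None = None
    psi_csv: str | None = None  # columns dyad_id,psi
    recording_start: str = "2023-01-01T20:00:00"
    # simulate mode
    n_dyads: int = 24
    days_per_dyad: int = 2
    kinds: tuple[str, ...] = INDEX_KINDS
    # HRV windowing
    window_s: float = 300.0
    step_s: float = 60.0
    artifact_gate: float = 0.05
    # day prep
    day_start_hour: int = 22
    max_missing: float = 0.20
    # recurrence
    epsilon: float = 0.0
    image_factor: int = 10
    # SOM
    som_epochs: int = 100
    som_restarts: int = 25
    # regression
    regression_unit: str = "day"  # day | subject
    # run control
    seed: int = 0
    out_dir: str | None = None
    save_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):  # sectioned files flatten one level
                flat.update(val)
            else:
                flat[key] = val
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "kinds" in flat:
            flat["kinds"] = tuple(flat["kinds"])
        return cls(**flat)


@dataclass
class PipelineReport:
    """Run summary: bookkeeping counts, nine model entries, ranked comparison."""

    n_dyads: int
    days_segmented: int  # member-days per kind entering day prep
    days_kept: int
    days_rejected: int
    rejections: list[dict]
    models: list[dict]  # one entry per (family, kind), fitted or failed
    comparison: list[dict]
    best: str | None
    dyad_days_kept: int = 0  # distinct (dyad, day) with complete plots on all kinds
    artifacts: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.days_kept + self.days_rejected != self.days_segmented:
            raise AssertionError("day bookkeeping does not reconcile")

    def metrics_dict(self) -> dict:
        """The deterministic part of the report (no paths), for comparisons."""
        return {
            "n_dyads": self.n_dyads,
            "days_segmented": self.days_segmented,
            "days_kept": self.days_kept,
            "days_rejected": self.days_rejected,
            "dyad_days_kept": self.dyad_days_kept,
            "models": self.models,
            "comparison": self.comparison,
            "best": self.best,
        }

    def to_json(self, path: str | Path) -> None:
        payload = {**self.metrics_dict(), "rejections": self.rejections,
                   "artifacts": self.artifacts}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------


def _collect_cohort(cfg: PipelineConfig):
    """Return (mother segments, child segments, psi) in raw day-segment form.

    Segments come back as dict[(dyad_id, kind)] -> list of raw DaySegment
    for each member; psi maps dyad_id -> total score.
    """
    if cfg.mode == "simulate":
        sim_cfg = CohortSimConfig(
            n_dyads=cfg.n_dyads,
            days_per_dyad=cfg.days_per_dyad,
            kinds=tuple(cfg.kinds),
            seed=stage_seed(cfg.seed, "simulate"),
        )
        bundle = simulate_cohort(sim_cfg)
        mothers = {
            (d, k): segs
            for d, by_kind in bundle.mother_days.items()
            for k, segs in by_kind.items()
        }
        children = {
            (d, k): segs
            for d, by_kind in bundle.child_days.items()
            for k, segs in by_kind.items()
        }
        return mothers, children, bundle.psi

    if cfg.mode in ("index-csv", "rr-csv"):
        from datetime import datetime, time

        if not (cfg.mother_csv and cfg.child_csv and cfg.psi_csv):
            raise ValueError(f"{cfg.mode} mode requires mother_csv, child_csv, psi_csv")
        start = datetime.fromisoformat(cfg.recording_start)
        day_start = time(cfg.day_start_hour, 0)

        def load(path: str):
            if cfg.mode == "index-csv":
                return dio.read_index_csv(path)
            series = []
            for rr in dio.read_rr_csv(path):
                nn = clean_rr(rr)
                if nn.flagged:
                    log.warning(
                        "subject %s exceeds 5%% artifact gate (%.1f%%); excluded",
                        rr.subject_id, 100 * nn.artifact_fraction,
                    )
                    continue
                series.extend(sliding_indices(nn, cfg.window_s, cfg.step_s).values())
            return series

        psi_df = pd.read_csv(cfg.psi_csv)
        psi = dict(zip(psi_df["dyad_id"].astype(str), psi_df["psi"].astype(int)))
        mothers: dict = {}
        children: dict = {}
        for target, path in ((mothers, cfg.mother_csv), (children, cfg.child_csv)):
            for s in load(path):
                # subject ids are "<dyad_id>-m" / "<dyad_id>-c"
                dyad_id = s.subject_id.rsplit("-", 1)[0]
                target[(dyad_id, s.kind)] = segment_days(s, start, day_start)
        return mothers, children, psi

    raise ValueError(f"unknown mode {cfg.mode!r}")


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute the full analysis and return (and optionally write) the report."""
    t0 = _time.monotonic()
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    mothers_raw, children_raw, psi = _collect_cohort(cfg)
    dyad_ids = sorted({d for d, _ in mothers_raw} | {d for d, _ in children_raw})
    days_segmented = sum(len(v) for v in mothers_raw.values()) + sum(
        len(v) for v in children_raw.values()
    )
    log.info("segmented %d member-days across %d dyads", days_segmented, len(dyad_ids))

    kept_m, rej_m = prepare_days(mothers_raw.values(), cfg.max_missing)
    kept_c, rej_c = prepare_days(children_raw.values(), cfg.max_missing)
    rejections = rej_m + rej_c
    for r in rejections:
        log.warning("rejected %s/%s day %d: %s", r.subject_id, r.kind, r.day_index, r.reason)
    days_kept = len(kept_m) + len(kept_c)

    def seg_index(segs: Iterable[DaySegment]) -> dict:
        return {(s.subject_id, s.kind, s.day_index): s for s in segs}

    m_idx, c_idx = seg_index(kept_m), seg_index(kept_c)

    rcfg = RecurrenceConfig(epsilon=cfg.epsilon)
    # images[family][kind] -> (plot ids, list of flattened images, psi values, dyads)
    images: dict[str, dict[str, list]] = {
        fam: {k: [] for k in cfg.kinds} for fam in PLOT_FAMILIES
    }
    meta: dict[str, dict[str, list]] = {
        fam: {k: [] for k in cfg.kinds} for fam in PLOT_FAMILIES
    }
    complete_dyad_days: set[tuple[str, int]] = set()
    for dyad in dyad_ids:
        for kind in cfg.kinds:
            m_days = {s.day_index: s for (sid, k, d), s in m_idx.items()
                      if sid == f"{dyad}-m" and k == kind}
            c_days = {s.day_index: s for (sid, k, d), s in c_idx.items()
                      if sid == f"{dyad}-c" and k == kind}
            for day in sorted(set(m_days) & set(c_days)):
                complete_dyad_days.add((dyad, day))
                mseg, cseg = m_days[day], c_days[day]
                plots = {
                    "rp_mother": build_rp(mseg, rcfg),
                    "rp_child": build_rp(cseg, rcfg),
                    "crp": build_crp(mseg, cseg, rcfg),
                }
                for fam, mat in plots.items():
                    img = to_image(mat, cfg.image_factor)
                    images[fam][kind].append(img)
                    meta[fam][kind].append((f"{dyad}:{kind}:{day}:{fam}", dyad))
                    if out_dir and cfg.save_plots:
                        dio.matrix_to_png(
                            out_dir / f"{fam}_{kind}_{dyad}_day{day}.png", img
                        )

    model_entries: list[dict] = []
    results: list[RegressionResult] = []
    for fam in PLOT_FAMILIES:
        for kind in cfg.kinds:
            label = f"{fam}:{kind}"
            imgs = images[fam][kind]
            entry: dict = {"label": label, "n_plots": len(imgs)}
            try:
                som = SOMFeatureExtractor(
                    n_epochs=cfg.som_epochs,
                    n_restarts=cfg.som_restarts,
                    random_state=stage_seed(cfg.seed, f"som:{label}"),
                ).fit(imgs)
                acts = som.transform(imgs)
                dyads = [d for _, d in meta[fam][kind]]
                y = np.array([psi[d] for d in dyads], dtype=float)
                res = fit_psi_model(
                    acts, y, label=label,
                    subject_ids=np.array(dyads), unit=cfg.regression_unit,
                )
                results.append(res)
                entry.update(
                    status="ok", n_obs=res.n_obs, adj_r2=res.adj_r2,
                    f_pvalue=res.f_pvalue, rmse=res.rmse, mae=res.mae,
                    significant=bool(res.significant),
                )
                if out_dir:
                    ids = [pid for pid, _ in meta[fam][kind]]
                    dio.write_features_csv(
                        out_dir / f"features_{fam}_{kind}.csv", ids, acts
                    )
            except ValueError as exc:
                entry.update(status=f"failed: {exc}")
            model_entries.append(entry)
            log.info("model %s: %s", label, entry.get("status"))

    comparison: list[dict] = []
    best = None
    if len(results) >= 2:
        table = compare_models(results)
        comparison = table.to_dict(orient="records")
        best = str(table.loc[0, "label"])

    report = PipelineReport(
        n_dyads=len(dyad_ids),
        days_segmented=days_segmented,
        days_kept=days_kept,
        days_rejected=len(rejections),
        dyad_days_kept=len(complete_dyad_days),
        rejections=[asdict(r) for r in rejections],
        models=model_entries,
        comparison=comparison,
        best=best,
    )
    if out_dir:
        dio.write_rejections_csv(out_dir / "rejections.csv", rejections)
        report.artifacts["out_dir"] = str(out_dir)
        report.to_json(out_dir / "report.json")
    log.info("pipeline finished in %.1f s", _time.monotonic() - t0)
    return report
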