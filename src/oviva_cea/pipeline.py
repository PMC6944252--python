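"""End-to-end pipeline: raw (or synthetic) tables to incremental results.

Stage order mirrors the analysis plan: costing → utility scoring → imputation
→ incremental analysis → bootstrap uncertainty → sensitivity scenarios.  Every
run writes a machine-readable manifest (seed, config hash, package version) so
a results bundle can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import costing, imputation, inference, synth

log = logging.getLogger("oviva_cea")

DEFAULT_CEAC_THRESHOLDS = tuple(float(x) for x in range(0, 50_001, 2_500))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    input_dir: str | None = None         # five input tables; None = synthesize
    output_dir: str = "results"
    seed: int = 0
    n_per_arm: int = 527                 # used only when synthesizing
    unit_cost_file: str | None = None
    drug_price_file: str | None = None
    inflation_multiplier: float = 1.0
    scenarios: tuple[str, ...] = inference.SCENARIOS
    m_imputations: int = 20
    mice_cycles: int = 10
    bootstrap_iterations: int = 1000
    threshold: float = inference.DEFAULT_THRESHOLD
    ceac_thresholds: tuple[float, ...] = DEFAULT_CEAC_THRESHOLDS
    death_interpolation: str = "death_day"
    figure_format: str = "png"

    def unit_costs(self) -> costing.UnitCostTable:
        if self.unit_cost_file is not None:
            return costing.UnitCostTable.from_csv(
                self.unit_cost_file, self.drug_price_file,
                inflation_multiplier=self.inflation_multiplier)
        return synth.default_unit_costs(self.inflation_multiplier)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kw)
            except Exception as exc:  # surface the failing stage by name
                raise StageError(name, exc) from exc
            log.info("stage %-12s %6.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("load")
def _load(config: RunConfig) -> synth.TrialDataset:
    if config.input_dir is not None:
        data = synth.TrialDataset.from_csv(config.input_dir)
    else:
        data = synth.generate_trial(
            synth.SynthConfig.oviva(n_per_arm=config.n_per_arm,
                                    seed=config.seed))
    data.validate()
    return data


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the results bundle.

    Returns a dict of the in-memory results (summary frames, incremental
    results, bootstrap cloud, CEAC) and writes CSVs, the CE-plane figure and
    ``manifest.json`` to ``config.output_dir``.  Idempotent given the seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    costs = config.unit_costs()
    data = _load(config)

    resource_summary = _stage("resources")(inference.summarize_resources)(data)
    cost_table = _stage("costing")(inference.cost_dataset)(data, costs)
    frame = _stage("assemble")(inference.assemble_analysis_frame)(data, costs)

    imp_spec = imputation.ImputationSpec(
        m=config.m_imputations, cycles=config.mice_cycles, seed=config.seed)
    incremental = _stage("scenarios")(inference.run_sensitivity)(
        data, scenarios=config.scenarios, costs=costs, imp_spec=imp_spec)
    incremental_df = pd.DataFrame([r.as_row() for r in incremental])

    # bootstrap on the unadjusted, non-imputed (complete-case) data
    cc = frame.dropna(subset=[c for c in frame.columns if c.startswith("u_")]
                      + ["total_cost"]).copy()
    cc["total_qaly"] = _complete_case_qalys(cc, config.death_interpolation)
    cloud = _stage("bootstrap")(inference.bootstrap_ce)(
        cc, B=config.bootstrap_iterations, seed=config.seed,
        threshold=config.threshold)
    ceac = inference.ceac_nmb(cloud, config.ceac_thresholds)

    resource_summary.to_csv(out / "resource_summary.csv", index=False)
    cost_table.to_csv(out / "cost_breakdown.csv", index=False)
    _qaly_table(frame, cc).to_csv(out / "qaly_summary.csv", index=False)
    incremental_df.to_csv(out / "incremental_results.csv", index=False)
    pd.DataFrame({"delta_qaly": cloud.delta_qaly,
                  "delta_cost": cloud.delta_cost}
                 ).to_csv(out / "bootstrap_cloud.csv", index=False)
    ceac.to_csv(out / "ceac.csv", index=False)
    figure_path = out / f"ce_plane.{config.figure_format}"
    render_ce_plane(cloud, config.threshold, figure_path)

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "config_digest": config.digest(),
        "package_version": _version(),
        "n_participants": int(len(data.participants)),
        "p_cost_saving": cloud.p_cost_saving,
        "p_qaly_gain": cloud.p_qaly_gain,
        "outputs": sorted({p.name for p in out.iterdir() if p.is_file()}
                          | {"manifest.json"}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"data": data, "resource_summary": resource_summary,
            "cost_table": cost_table, "incremental": incremental,
            "incremental_df": incremental_df, "cloud": cloud, "ceac": ceac,
            "manifest": manifest}


def _complete_case_qalys(cc: pd.DataFrame, death_interpolation: str) -> list:
    from . import qaly as q

    totals = []
    for idx in cc.index:
        utilities = {d: float(cc.at[idx, f"u_{d}"]) for d in q.VISIT_DAYS}
        dd = cc.at[idx, "death_day"]
        dd = None if pd.isna(dd) else int(dd)
        traj = q.build_trajectory(utilities, death_day=dd)
        totals.append(q.compute_qalys(
            traj, death_interpolation=death_interpolation).total_qaly)
    return totals


def _qaly_table(frame: pd.DataFrame, cc: pd.DataFrame) -> pd.DataFrame:
    """Per-visit complete-case utility means by arm plus total QALYs."""
    from . import qaly as q

    rows = []
    for day in q.VISIT_DAYS:
        col = f"u_{day}"
        row = {"measure": f"utility_day_{day}"}
        for arm in inference.ARMS:
            v = frame.loc[frame["arm"] == arm, col].dropna()
            row[f"{arm}_mean"] = v.mean()
            row[f"{arm}_sd"] = v.std(ddof=1)
            row[f"{arm}_n"] = len(v)
        rows.append(row)
    row = {"measure": "total_qaly_complete_case"}
    for arm in inference.ARMS:
        v = cc.loc[cc["arm"] == arm, "total_qaly"]
        row[f"{arm}_mean"] = v.mean()
        row[f"{arm}_sd"] = v.std(ddof=1)
        row[f"{arm}_n"] = len(v)
    rows.append(row)
    return pd.DataFrame(rows)


def render_ce_plane(cloud: inference.BootstrapCloud, threshold: float,
                    path: str | Path) -> Path:
    """Cost-effectiveness plane: bootstrap scatter, point estimate, 95%
    confidence ellipse and the willingness-to-pay threshold line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if cloud.B == 0:
        raise ValueError("empty bootstrap cloud")
    fig, ax = plt.subplots(figsize=(7, 5.5))
    ax.scatter(cloud.delta_qaly, cloud.delta_cost, s=8, alpha=0.35,
               color="#33689e", label=f"{cloud.B} bootstrap resamples")
    ax.scatter(*cloud.center, color="#c23b22", zorder=5, s=45, marker="D",
               label="point estimate")
    try:
        ellipse = cloud.ellipse(0.95)
        ax.plot(ellipse[:, 0], ellipse[:, 1], color="#c23b22", lw=1.2,
                label="95% confidence ellipse")
    except (ValueError, np.linalg.LinAlgError):
        log.warning("degenerate bootstrap cloud: ellipse suppressed")
    span = max(abs(cloud.delta_qaly).max() * 1.4, 1e-4)
    xs = np.linspace(-span, span, 2)
    ax.plot(xs, threshold * xs, color="grey", ls="--", lw=1,
            label=f"£{threshold:,.0f}/QALY threshold")
    ax.axhline(0, color="black", lw=0.6)
    ax.axvline(0, color="black", lw=0.6)
    ax.set_xlabel("Incremental QALYs (oral − IV)")
    ax.set_ylabel("Incremental cost, GBP (oral − IV)")
    ax.set_title("Cost-effectiveness plane")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("oviva-cea")
    except Exception:
        return "unknown"
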