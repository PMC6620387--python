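"""Pipeline orchestration: simulate -> parse -> classify -> summarize.

``run_pipeline`` drives a full session analysis (from a simulation config or
a saved HDF5 session), writes the trial / unit / laterality / identification
CSVs plus a machine-readable manifest, and returns the results object
together with a per-group report.  ``group_compare`` (re-exported from
:mod:`lateralize.stats`) runs the named standard test on group data.
"""
from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .io import _to_plain, load_session, save_config_yaml, save_session
from .model import AnalysisParams, SessionAnalysis, SessionAnalysisResults
from .simulate import SimConfig, simulate_session
from .stats import group_compare  # noqa: F401  (public pipeline surface)


@dataclass
class PipelineConfig:
    """What to analyze and where to put the artifacts."""

    sim: Optional[SimConfig] = None
    input_path: Optional[str] = None
    output_dir: str = "lateralize_out"
    seed: Optional[int] = None  # overrides sim.seed when given
    save_hdf5: bool = False
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def validate(self) -> None:
        if (self.sim is None) == (self.input_path is None):
            raise ValueError("provide exactly one of sim= or input_path=")


def group_report(units_df: pd.DataFrame) -> pd.DataFrame:
    """Per area x condition x cell-class report: counts, Hold/Go and
    side-category proportions, laterality summaries."""
    if units_df.empty:
        return pd.DataFrame()
    df = units_df.reset_index()
    rows = []
    for (area, cond, cls), g in df.groupby(["area", "condition", "cell_class"]):
        task = g[g["task_related"] == True]  # noqa: E712
        typed = task[task["functional_type"].isin(["Go", "Hold"])]
        n_typed = max(len(typed), 1)
        row = dict(area=area, condition=cond, cell_class=cls,
                   n_units=len(g), n_task_related=len(task))
        for t in ("Go", "Hold"):
            row[f"prop_{t.lower()}"] = float(
                (typed["functional_type"] == t).sum()) / n_typed
        n_task = max(len(task), 1)
        for cat in ("contralateral", "ipsilateral", "bilateral"):
            row[f"prop_{cat}"] = float((task["side_category"] == cat).sum()) / n_task
        lat = g["laterality_index"].dropna()
        row["laterality_mean"] = float(lat.mean()) if len(lat) else np.nan
        row["laterality_sem"] = (float(lat.std(ddof=1) / np.sqrt(len(lat)))
                                 if len(lat) > 1 else np.nan)
        row["n_laterality"] = int(len(lat))
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig
                 ) -> tuple[SessionAnalysisResults, pd.DataFrame, dict]:
    """Run the full pipeline; returns (results, group_report, manifest).

    All randomness derives from the configured seed, so a rerun with the
    same manifest reproduces every CSV byte for byte.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.sim is not None:
        sim = config.sim
        if config.seed is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
        session, truth = simulate_session(sim)
        save_config_yaml(sim, out / "sim_config.yaml")
        if config.save_hdf5:
            save_session(session, out / "session.h5")
    else:
        session = load_session(config.input_path)

    results = SessionAnalysis(session, config.params).fit()

    results.trials.to_csv(out / "trials.csv", index=False)
    results.units.to_csv(out / "units.csv")
    lat = results.laterality_table()
    lat.to_csv(out / "laterality_summary.csv", index=False)
    proj_rows = [dict(unit_id=uid, projection_class=pa.projection_class,
                      conflict=pa.conflict)
                 for uid, pa in results.projections.items()]
    pd.DataFrame(proj_rows).to_csv(out / "projection_id.csv", index=False)
    if truth is not None:
        from .io import save_ground_truth

        save_ground_truth(truth, out)

    report = group_report(results.units)
    report.to_csv(out / "group_report.csv", index=False)

    manifest = dict(
        package="lateralize",
        version=__version__,
        python=platform.python_version(),
        numpy=np.__version__,
        seed=(config.seed if config.seed is not None
              else (config.sim.seed if config.sim else None)),
        config=_to_plain(config.sim) if config.sim else dict(
            input_path=config.input_path),
        params=_to_plain(config.params),
        stages=dict(
            behavior=True,
            units=not results.units.empty,
            emg=bool(session.emg),
            lfp=bool(session.lfp),
            stimulation=bool(session.stim),
        ),
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(out / "summary.txt", "w") as fh:
        fh.write(results.summary() + "\n")
    return results, report, manifest
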