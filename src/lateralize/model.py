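"""Session-level analysis model and results.

``SessionAnalysis`` is built from a :class:`~lateralize.core.SessionData`
(optionally straight from a simulation config); ``fit()`` runs behavior
parsing, per-unit metrics, task-relevance / Hold-Go classification, the
laterality index and projection identification, and returns a
``SessionAnalysisResults`` carrying the trial and unit tables plus a
``summary()`` report.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior, classify, collision, laterality, units as unit_ops
from .core import SessionData, UnitRecord, opposite


@dataclass
class AnalysisParams:
    """Analysis thresholds, all defaulting to the published values."""

    task_p_threshold: float = classify.TASK_P_THRESHOLD
    slope_threshold: float = classify.SLOPE_THRESHOLD
    rs_duration_ms: float = unit_ops.RS_DURATION_MS
    min_trials: int = classify.MIN_TRIALS
    min_spikes: int = classify.MIN_SPIKES
    poststim_blank_s: float = 1.0
    chi2_alpha: float = collision.CHI2_ALPHA
    jitter_max_ms: float = collision.JITTER_MAX_MS


class SessionAnalysis:
    """Full analysis of one pedal-task session.

    Parameters
    ----------
    session : SessionData
        Traces, units and stimulation logs for one recording.
    params : AnalysisParams, optional
        Threshold overrides; defaults are the published analysis settings.
    """

    def __init__(self, session: SessionData,
                 params: Optional[AnalysisParams] = None):
        self.session = session
        self.params = params or AnalysisParams()

    @classmethod
    def from_simulation(cls, config, params: Optional[AnalysisParams] = None):
        """Simulate a session from a ``SimConfig`` and wrap it for analysis."""
        from .simulate import simulate_session

        session, truth = simulate_session(config)
        model = cls(session, params)
        model.ground_truth = truth
        return model

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "SessionAnalysisResults":
        sess = self.session
        trials = behavior.classify_trials(sess.pedal, sess.blocks)
        performance = behavior.performance_summary(trials)
        completed = [t for t in trials if t.outcome != "immature"
                     and t.chosen_side in ("right", "left")]
        onsets_all = np.array([t.release_onset_time for t in completed])

        projections = collision.identify_units(sess.stim)

        unit_rows = []
        for unit in sess.units:
            unit_rows.append(self._fit_unit(unit, completed, onsets_all,
                                            projections))
        units_df = pd.DataFrame(unit_rows).set_index("unit_id") if unit_rows \
            else pd.DataFrame()

        trials_df = pd.DataFrame([dict(
            block_side=t.block_side, chosen_side=t.chosen_side,
            outcome=t.outcome, hold_start=t.hold_start_time,
            holding_duration=t.holding_duration,
            release_event=t.release_event_time,
            release_onset=t.release_onset_time,
            within_hold_movement=t.within_hold_movement,
        ) for t in trials])

        return SessionAnalysisResults(
            session=sess, params=self.params, trials=trials_df,
            trial_records=trials, units=units_df, performance=performance,
            projections=projections,
        )

    def _fit_unit(self, unit: UnitRecord, completed, onsets_all,
                  projections) -> dict:
        p = self.params
        stim_times = np.sort(np.concatenate(
            [ev.stim_times for ev in self.session.stim.get(unit.unit_id, [])]
        )) if unit.unit_id in self.session.stim else np.empty(0)
        spikes = unit_ops.remove_poststim_spikes(unit.spike_times, stim_times,
                                                 blank=p.poststim_blank_s)
        row: dict = dict(unit_id=unit.unit_id, area=unit.area,
                         condition=unit.condition, n_spikes=spikes.size)

        if unit.waveform is not None:
            try:
                wf = unit_ops.waveform_metrics(unit.waveform,
                                               unit.waveform_sampling_rate)
                row.update(duration_ms=wf.duration, width_ms=wf.width,
                           cell_class=wf.cell_class)
            except ValueError:
                row.update(duration_ms=np.nan, width_ms=np.nan,
                           cell_class="unknown")
        else:
            row.update(duration_ms=np.nan, width_ms=np.nan, cell_class="unknown")

        try:
            row["ongoing_rate"] = unit_ops.ongoing_rate(
                spikes, onsets_all, self.session.span)
        except ValueError:
            row["ongoing_rate"] = np.nan
        row["isi_cv"] = unit_ops.isi_cv(spikes)

        contra_side = unit.contra_side()
        contra = [t for t in completed if t.chosen_side == contra_side]
        ipsi = [t for t in completed if t.chosen_side == opposite(contra_side)]
        c_on = [t.release_onset_time for t in contra]
        i_on = [t.release_onset_time for t in ipsi]
        c_hold = [t.holding_duration for t in contra]
        i_hold = [t.holding_duration for t in ipsi]

        tr = classify.classify_unit(spikes, c_on, i_on, c_hold, i_hold,
                                    threshold=p.task_p_threshold)
        row.update(p_contra=tr.p_contra, p_ipsi=tr.p_ipsi,
                   task_related=tr.task_related, side_category=tr.side_cat,
                   preferred_side=tr.preferred_side,
                   functional_type=tr.functional_type, slope=tr.slope,
                   peak_time=tr.peak_time,
                   classification_reason=tr.exclusion_reason)

        if tr.functional_type == "Go":
            lat = laterality.unit_laterality(spikes, c_on, i_on)
            row.update(c=lat.c, i=lat.i, laterality_index=lat.index,
                       fr_peak_contra=lat.fr_peak_contra,
                       fr_peak_ipsi=lat.fr_peak_ipsi,
                       laterality_reason=lat.exclusion_reason)
        else:
            row.update(c=np.nan, i=np.nan, laterality_index=np.nan,
                       fr_peak_contra=np.nan, fr_peak_ipsi=np.nan,
                       laterality_reason=None)

        pa = projections.get(unit.unit_id)
        row["projection_class"] = pa.projection_class if pa else "untested"
        if pa and pa.results:
            best = next((r for r in pa.results if r.passed), pa.results[0])
            row.update(antidromic_latency=best.latency,
                       antidromic_jitter=best.jitter,
                       collision_chi2_p=best.chi2_p)
        else:
            row.update(antidromic_latency=np.nan, antidromic_jitter=np.nan,
                       collision_chi2_p=np.nan)
        return row


@dataclass
class SessionAnalysisResults:
    """Estimates, classifications and diagnostics for one session."""

    session: SessionData
    params: AnalysisParams
    trials: pd.DataFrame
    trial_records: list
    units: pd.DataFrame
    performance: dict
    projections: dict

    def laterality_table(self) -> pd.DataFrame:
        """Per-group laterality summary (area x condition x cell class)."""
        if self.units.empty:
            return pd.DataFrame()
        return laterality.laterality_summary(self.units.reset_index())

    def peth(self, unit_id: str, side: str = "contra") -> unit_ops.Peth:
        """Release-onset-aligned PETH for one unit and movement side."""
        unit = self.session.unit(unit_id)
        contra_side = unit.contra_side()
        want = contra_side if side == "contra" else opposite(contra_side)
        onsets = [t.release_onset_time for t in self.trial_records
                  if t.outcome != "immature" and t.chosen_side == want]
        return unit_ops.build_peth(unit.spike_times, onsets)

    def plot_peth(self, unit_id: str, ax=None):
        """Contra (red) and ipsi (blue) PETHs for one unit."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for side, color in (("contra", "crimson"), ("ipsi", "royalblue")):
            p = self.peth(unit_id, side)
            ax.step(p.bin_centers, p.rate, where="mid", color=color, label=side)
        ax.axvline(0.0, color="k", lw=0.6)
        ax.set_xlabel("time re release onset (s)")
        ax.set_ylabel("rate (Hz)")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        """Human-readable session report."""
        perf = self.performance
        u = self.units
        lines = [
            "Session analysis summary",
            "========================",
            f"area/condition: {self.session.metadata.get('area', '?')}"
            f"/{self.session.metadata.get('condition', '?')}",
            f"trials: {perf['total_trials']} total, "
            f"{perf['completed_trials']} completed, "
            f"correct rate {perf['correct_rate']:.1f}%",
            f"right bias: {perf['right_bias']:+.1f}%",
            f"units: {len(u)}",
        ]
        if not u.empty:
            n_task = int(u["task_related"].sum())
            lines.append(f"task-related: {n_task} "
                         f"(Go {int((u['functional_type'] == 'Go').sum())}, "
                         f"Hold {int((u['functional_type'] == 'Hold').sum())})")
            for cls in ("RS", "FS"):
                n = int((u["cell_class"] == cls).sum())
                lines.append(f"{cls} units: {n}")
            lat = u["laterality_index"].dropna()
            if len(lat):
                lines.append(f"laterality index (Go): mean {lat.mean():+.3f} "
                             f"(n={len(lat)})")
            proj = u["projection_class"].value_counts().to_dict()
            ids = {k: v for k, v in proj.items() if k in ("IT", "PT")}
            if ids:
                lines.append("identified projections: "
                             + ", ".join(f"{k} {v}" for k, v in sorted(ids.items())))
        return "\n".join(lines)
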