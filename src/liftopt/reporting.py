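"""Case orchestration, reports and comparison tables.

`run_case` solves one exoskeleton configuration of the packaged lifting
task and writes a diffable artifact directory (trajectory.csv,
summary.json, snapshots/); `compare_cases` assembles the peak-torque /
mechanical-energy comparison table with percent reductions against the
unassisted baseline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CASES, load_config
from .optimization import LiftingOptimization, LiftingResults, percent_reduction

REPORT_JOINTS = ("spine", "shoulder", "knee")


def _task_hash(cfg: dict) -> str:
    payload = json.dumps(
        {"subject": cfg.get("subject"), "task": cfg.get("task")},
        sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CaseReport:
    case: str
    task_hash: str
    objective: float
    status: str
    max_violation: float
    peak_torques: dict
    mechanical_energy: float
    exo_peaks: dict

    def to_dict(self) -> dict:
        return {
            "case": self.case,
            "task_hash": self.task_hash,
            "objective": self.objective,
            "status": self.status,
            "max_violation": self.max_violation,
            "peak_torques_Nm": self.peak_torques,
            "mechanical_energy_J": self.mechanical_energy,
            "exo_peak_torques_Nm": self.exo_peaks,
        }

    @classmethod
    def from_result(cls, case: str, task_hash: str,
                    result: LiftingResults) -> "CaseReport":
        exo_peaks = {}
        for k, exo in enumerate(result.problem.exos):
            exo_peaks[exo.name] = float(np.max(np.abs(result.tau_e[:, k])))
        return cls(case=case, task_hash=task_hash,
                   objective=float(result.objective), status=result.status,
                   max_violation=float(result.max_violation),
                   peak_torques={k: round(v, 10) for k, v in
                                 result.peak_torques().items()},
                   mechanical_energy=float(result.mechanical_energy()),
                   exo_peaks=exo_peaks)

    @classmethod
    def load(cls, directory) -> "CaseReport":
        payload = json.loads((Path(directory) / "summary.json").read_text())
        return cls(case=payload["case"], task_hash=payload["task_hash"],
                   objective=payload["objective"], status=payload["status"],
                   max_violation=payload["max_violation"],
                   peak_torques=payload["peak_torques_Nm"],
                   mechanical_energy=payload["mechanical_energy_J"],
                   exo_peaks=payload["exo_peak_torques_Nm"])


def run_case(config, case: str, out_dir=None, snapshots: bool = True,
             fit_options: dict | None = None
             ) -> tuple[CaseReport, LiftingResults]:
    """Build, solve and (optionally) persist one case.

    Deterministic given the config: the solver is seedless (fixed starts)
    and the summary JSON contains no timestamps.
    """
    cfg = load_config(config)
    if case not in CASES:
        raise ValueError(f"unknown case {case!r}; expected one of {CASES}")
    problem = LiftingOptimization.from_config(cfg, case=case)
    result = problem.fit(**(fit_options or {}))
    report = CaseReport.from_result(case, _task_hash(cfg), result)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.trajectory_frame().to_csv(out / "trajectory.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
        if snapshots:
            from .plotting import plot_snapshots
            snap = out / "snapshots"
            snap.mkdir(exist_ok=True)
            plot_snapshots(result, path=snap / "lifting_motion.png")
    return report, result


def compare_cases(baseline: CaseReport, assisted) -> pd.DataFrame:
    """Table-style comparison of peaks/energies with percent reductions
    relative to the baseline case."""
    reports = [baseline, *assisted]
    for r in reports[1:]:
        if r.task_hash != baseline.task_hash:
            raise ValueError(
                f"case {r.case!r} was solved for a different subject/task "
                f"(hash {r.task_hash} != baseline {baseline.task_hash})")
    rows = []
    for r in reports:
        row = {"case": r.case, "objective": r.objective,
               "mechanical_energy_J": r.mechanical_energy}
        for j in REPORT_JOINTS:
            row[f"peak_{j}_Nm"] = r.peak_torques[j]
            row[f"reduction_{j}_pct"] = percent_reduction(
                baseline.peak_torques[j], r.peak_torques[j])
        rows.append(row)
    return pd.DataFrame(rows).set_index("case")
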