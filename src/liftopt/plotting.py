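"""Stick-figure snapshots of the predicted lifting motion."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .body import (ANKLE, ELBOW, GR1, HIP, KNEE, SHOULDER, SPINE, SUBTALAR,
                   HumanModel)
from .kinematics import forward_kinematics, hand_local_coords


def skeleton_points(model: HumanModel, q) -> dict:
    """Named global (y, z) points of the stick figure at configuration q."""
    A = forward_kinematics(model, q)
    pts = {
        "pelvis": A[GR1][:3, 3],
        "shoulder": A[SPINE][:3, 3],
        "elbow": A[SHOULDER][:3, 3],
        "wrist": A[ELBOW][:3, 3],
        "hand": (A[ELBOW] @ hand_local_coords(model))[:3],
        "knee": A[HIP][:3, 3],
        "ankle": A[KNEE][:3, 3],
        "ball": A[ANKLE][:3, 3],
        "toe": A[SUBTALAR][:3, 3],
    }
    ankle = pts["ankle"]
    pts["heel"] = np.array([0.0, ankle[1], ankle[2] - model.heel_back])
    return pts

SEGMENT_PAIRS = [
    ("pelvis", "shoulder"), ("shoulder", "elbow"), ("elbow", "wrist"),
    ("pelvis", "knee"), ("knee", "ankle"), ("ankle", "ball"),
    ("ball", "toe"), ("heel", "ankle"),
]

EXO_JOINT_POINT = {SPINE: "pelvis", SHOULDER: "shoulder", ELBOW: "elbow",
                   HIP: "pelvis", KNEE: "knee", ANKLE: "ankle"}


def plot_snapshots(result, times=(0.0, 0.25, 0.5, 0.75, 1.0), path=None,
                   box_size=0.15):
    """Sagittal stick-figure frames at fractions of the lifting cycle.

    `result` is a LiftingResults; assisted joints are marked with open
    circles and the carried box is drawn at the hand.  Returns the figure
    (and saves to `path` when given).
    """
    problem = result.problem
    model = problem.model
    n = len(times)
    fig, axes = plt.subplots(1, n, figsize=(2.6 * n, 4.2), sharey=True)
    axes = np.atleast_1d(axes)
    t_grid = problem.t_grid
    for ax, frac in zip(axes, times):
        t = frac * problem.task.duration
        idx = int(np.argmin(np.abs(t_grid - t)))
        q = result.Q[idx]
        pts = skeleton_points(model, q)
        for a, b in SEGMENT_PAIRS:
            ax.plot([pts[a][2], pts[b][2]], [pts[a][1], pts[b][1]],
                    "-", color="0.2", lw=2.5, solid_capstyle="round")
        hand = pts["hand"]
        ax.add_patch(plt.Rectangle(
            (hand[2] - box_size / 2, hand[1] - box_size / 2), box_size,
            box_size, fill=True, color="peru", alpha=0.7, zorder=0))
        for exo in problem.exos:
            name = EXO_JOINT_POINT.get(exo.joint_index)
            if name:
                p = pts[name]
                ax.plot(p[2], p[1], "o", mfc="none", mec="tab:orange",
                        mew=2.5, ms=11)
        ax.axhline(0.0, color="0.6", lw=1)
        ax.set_title(f"{100 * frac:.0f}%")
        ax.set_aspect("equal")
        ax.set_xlim(-0.6, 0.9)
        ax.set_ylim(-0.1, 1.8)
        ax.set_xlabel("z (m)")
    axes[0].set_ylabel("y (m)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
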