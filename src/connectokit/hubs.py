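"""Hub identification and the hub disruption index.

Hubs are the nodes whose group-mean degree lies strictly more than one
standard deviation above the mean of the group-mean degrees, the
spread being taken across nodes (sample SD, ddof=1).

The hub disruption index kappa of a subject, for a given nodal metric,
is the ordinary-least-squares slope of (subject profile - reference
profile) against the reference profile across nodes, where the
reference is the control-group mean profile.  kappa = 0 means no
reorganization; kappa < 0 means nodes that score high in controls are
preferentially reduced in the subject.  Controls are scored against
the leave-one-out control mean so a subject never appears in its own
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CohortError, DegenerateStatisticError
from .metrics import MetricsTable

__all__ = ["HubSet", "KappaResult", "identify_hubs",
           "hub_disruption_index", "cohort_kappa"]


@dataclass
class HubSet:
    group: str
    mean_profile: np.ndarray
    mean: float
    sd: float
    threshold: float
    hubs: np.ndarray               # node indices, strictly above threshold

    @property
    def n_hubs(self) -> int:
        return len(self.hubs)


@dataclass
class KappaResult:
    subject_id: str
    group: str
    metric: str
    kappa: float
    intercept: float
    reference: np.ndarray = field(repr=False, default=None)


def identify_hubs(table: MetricsTable, group: str,
                  metric: str = "degree") -> HubSet:
    """Nodes of a group whose mean metric exceeds mean + 1 SD across nodes."""
    ids = table.subjects_in(group)
    if not ids:
        raise CohortError(f"no subjects in group {group!r}")
    profile = table.group_mean_profile(metric, group)
    mean = float(profile.mean())
    sd = float(profile.std(ddof=1)) if len(profile) > 1 else 0.0
    threshold = mean + sd
    hubs = np.flatnonzero(profile > threshold)
    return HubSet(group, profile, mean, sd, threshold, hubs)


def hub_disruption_index(subject_profile, reference_profile, *,
                         subject_id: str = "", group: str = "",
                         metric: str = "") -> KappaResult:
    """OLS slope of (subject - reference) on reference, across nodes."""
    subj = np.asarray(subject_profile, dtype=float)
    ref = np.asarray(reference_profile, dtype=float)
    if subj.shape != ref.shape or subj.ndim != 1:
        raise ValueError(
            f"profiles must be 1-D and equal length, got {subj.shape} vs {ref.shape}")
    if len(ref) < 3:
        raise ValueError(f"need >= 3 nodes to fit a line, got {len(ref)}")
    if np.ptp(ref) == 0:
        raise DegenerateStatisticError(
            "reference profile is constant; hub-disruption slope undefined")
    x = ref - ref.mean()
    y = subj - ref
    slope = float(np.dot(x, y - y.mean()) / np.dot(x, x))
    intercept = float(y.mean() - slope * ref.mean())
    return KappaResult(subject_id, group, metric, slope, intercept, ref)


def cohort_kappa(table: MetricsTable, metric: str = "degree"
                 ) -> tuple[list[KappaResult], dict]:
    """Hub-disruption index for every subject, plus the group comparison.

    Patients are scored against the control mean profile; each control
    against the leave-one-out mean of the remaining controls.  Groups
    are compared with a two-sided rank-sum test at p < 0.05.
    """
    patients = table.subjects_in("patient")
    controls = table.subjects_in("control")
    if not patients or not controls:
        raise CohortError("both groups are required for cohort kappa")
    if len(controls) < 2:
        raise CohortError(
            "leave-one-out control reference needs >= 2 controls")
    vals = table.nodal[metric]
    ctrl = vals.loc[controls].to_numpy()
    ctrl_mean = ctrl.mean(axis=0)
    results = []
    for sid in patients:
        results.append(hub_disruption_index(
            vals.loc[sid].to_numpy(), ctrl_mean,
            subject_id=sid, group="patient", metric=metric))
    nc = len(controls)
    for k, sid in enumerate(controls):
        loo = (ctrl_mean * nc - ctrl[k]) / (nc - 1)
        results.append(hub_disruption_index(
            ctrl[k], loo, subject_id=sid, group="control", metric=metric))
    from .stats import rank_sum_test

    kp = [r.kappa for r in results if r.group == "patient"]
    kc = [r.kappa for r in results if r.group == "control"]
    stat, p = rank_sum_test(kp, kc)
    comparison = {
        "metric": metric,
        "patient_mean_kappa": float(np.mean(kp)),
        "control_mean_kappa": float(np.mean(kc)),
        "statistic": float(stat),
        "p_value": float(p),
        "significant": bool(p < 0.05),
        "control_reference": "leave-one-out",
    }
    return results, comparison
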