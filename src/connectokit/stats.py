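"""The study's statistical layer.

Group comparisons use unpaired two-sided Mann-Whitney rank-sum tests
(exact for small samples, tie-corrected normal approximation
otherwise).  Nodal comparisons are reported against two thresholds: a
Bonferroni cutoff alpha/n and an exploratory cutoff 1/n (0.0003 and
0.006 at n = 164 regions).  Clinical correlations use Spearman rank
correlation, judged at 0.0125 for global metrics and 0.004 for nodal
metrics.  Demographics are compared with Kruskal-Wallis (continuous)
and chi-squared without Yates correction (categorical) — the
uncorrected chi-squared reproduces the conventional reporting for 2x2
cohort tables of this size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CohortError, DegenerateStatisticError
from .io import ClinicalRecord
from .metrics import MetricsTable

__all__ = ["ThresholdScheme", "ClinicalRecord", "progression_rate",
           "rank_sum_test", "spearman_correlation",
           "global_group_comparison", "nodal_group_comparison",
           "demographics_comparison"]


@dataclass(frozen=True)
class ThresholdScheme:
    """Nodal significance thresholds: Bonferroni alpha/n and exploratory 1/n."""

    alpha: float = 0.05
    n_tests: int = 164
    global_corr_alpha: float = 0.0125
    local_corr_alpha: float = 0.004

    @property
    def bonferroni(self) -> float:
        return self.alpha / self.n_tests

    @property
    def exploratory(self) -> float:
        return 1.0 / self.n_tests


def progression_rate(record: ClinicalRecord | None = None, *,
                     alsfrs_r: float | None = None,
                     duration_months: float | None = None) -> float:
    """Disease progression rate (48 - ALSFRS-R) / duration, per month."""
    if record is None:
        record = ClinicalRecord(alsfrs_r, duration_months)
    return record.progression_rate


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test with tie correction.

    Exact null distribution for small untied samples, tie-corrected
    normal approximation otherwise (scipy's ``method='auto'``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise CohortError(f"each sample needs >= 2 values, got {len(x)}, {len(y)}")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise DegenerateStatisticError(
            "all values tied across both samples; rank-sum test undefined")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie handling, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"paired samples required, got {len(x)} vs {len(y)}")
    if len(x) < 4:
        raise CohortError(f"need >= 4 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticError(
            "constant input; Spearman correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def global_group_comparison(table: MetricsTable) -> pd.DataFrame:
    """Group means +/- SD and rank-sum p for the global measures.

    Rows: Eglob, mean degree, and the per-subject node-averages of
    Eloc and BC when those metrics were computed.
    """
    pat = table.subjects_in("patient")
    ctrl = table.subjects_in("control")
    if len(pat) < 2 or len(ctrl) < 2:
        raise CohortError("global comparison needs >= 2 subjects per group")
    series = {"eglob": table.scalars["eglob"],
              "mean_degree": table.scalars["mean_degree"]}
    for m in ("eloc", "bc"):
        if m in table.nodal:
            series[f"mean_{m}"] = table.nodal[m].mean(axis=1)
    rows = []
    for name, s in series.items():
        xp, xc = s.loc[pat].to_numpy(), s.loc[ctrl].to_numpy()
        try:
            stat, p = rank_sum_test(xp, xc)
        except DegenerateStatisticError:
            stat, p = np.nan, np.nan
        rows.append({"measure": name,
                     "patient_mean": xp.mean(), "patient_sd": xp.std(ddof=1),
                     "control_mean": xc.mean(), "control_sd": xc.std(ddof=1),
                     "statistic": stat, "p_value": p,
                     "significant_0.05": bool(p < 0.05) if np.isfinite(p) else False})
    return pd.DataFrame(rows)


def nodal_group_comparison(table: MetricsTable,
                           scheme: ThresholdScheme | None = None,
                           metrics: tuple[str, ...] | None = None
                           ) -> pd.DataFrame:
    """Per-node, per-metric group comparison with two-tier flags.

    Returns one row per (metric, node) with group means +/- SD, the
    rank-sum p-value, and boolean flags at the Bonferroni and
    exploratory thresholds.  Degenerate nodes (all values tied) get
    NaN p and are not flagged rather than aborting the table.
    """
    if scheme is None:
        scheme = ThresholdScheme(n_tests=len(table.node_ids) or 164)
    if metrics is None:
        metrics = tuple(table.nodal.keys())
    pat = table.subjects_in("patient")
    ctrl = table.subjects_in("control")
    if len(pat) < 2 or len(ctrl) < 2:
        raise CohortError("nodal comparison needs >= 2 subjects per group")
    frames = []
    for metric in metrics:
        xp = table.nodal[metric].loc[pat].to_numpy()
        xc = table.nodal[metric].loc[ctrl].to_numpy()
        n_nodes = xp.shape[1]
        pvals = np.full(n_nodes, np.nan)
        stats_ = np.full(n_nodes, np.nan)
        pooled_range = np.ptp(np.vstack([xp, xc]), axis=0)
        ok = pooled_range > 0
        if ok.any():
            res = sps.mannwhitneyu(xp[:, ok], xc[:, ok], alternative="two-sided",
                                   method="asymptotic", axis=0)
            pvals[ok] = res.pvalue
            stats_[ok] = res.statistic
        frames.append(pd.DataFrame({
            "metric": metric,
            "node": np.arange(n_nodes),
            "region": (table.node_ids if len(table.node_ids) == n_nodes
                       else np.arange(n_nodes)),
            "patient_mean": xp.mean(axis=0),
            "patient_sd": xp.std(axis=0, ddof=1),
            "control_mean": xc.mean(axis=0),
            "control_sd": xc.std(axis=0, ddof=1),
            "statistic": stats_,
            "p_value": pvals,
            "flag_bonferroni": np.where(np.isfinite(pvals),
                                        pvals < scheme.bonferroni, False),
            "flag_exploratory": np.where(np.isfinite(pvals),
                                         pvals < scheme.exploratory, False),
        }))
    return pd.concat(frames, ignore_index=True)


def demographics_comparison(demographics: pd.DataFrame,
                            group_col: str = "group",
                            continuous: tuple[str, ...] = ("age",),
                            categorical: tuple[str, ...] = ("sex",)
                            ) -> pd.DataFrame:
    """Kruskal-Wallis for continuous and chi-squared (no Yates
    correction) for categorical demographic variables."""
    groups = demographics[group_col].unique()
    if len(groups) < 2:
        raise CohortError("demographics comparison needs >= 2 groups")
    rows = []
    for var in continuous:
        if var not in demographics.columns:
            continue
        samples = [demographics.loc[demographics[group_col] == g, var].dropna()
                   for g in groups]
        stat, p = sps.kruskal(*samples)
        rows.append({"variable": var, "test": "kruskal-wallis",
                     "statistic": float(stat), "p_value": float(p)})
    for var in categorical:
        if var not in demographics.columns:
            continue
        tab = pd.crosstab(demographics[group_col], demographics[var])
        res = sps.chi2_contingency(tab.to_numpy(), correction=False)
        if (res.expected_freq == 0).any():
            raise DegenerateStatisticError(
                f"{var}: a cell has expected count 0; use an exact test")
        rows.append({"variable": var, "test": "chi-squared",
                     "statistic": float(res.statistic),
                     "p_value": float(res.pvalue)})
    return pd.DataFrame(rows)
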