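"""One-command orchestration of the full connectome group analysis.

:class:`ConnectomeGroupStudy` is the model object: built from a cohort
(loaded from files or generated synthetically), its :meth:`fit` runs
every stage — metrics, global and nodal group comparisons, hub sets,
hub-disruption indices, NBS, clinical correlations, demographics — and
returns a :class:`StudyResults` carrying the tables, a ``summary()``
and writers.  Every number in a saved report is recomputable from the
embedded configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConnectokitError
from .hubs import cohort_kappa, identify_hubs
from .io import Cohort, _plain, load_cohort
from .metrics import NODAL_METRICS, MetricsTable, compute_metrics_table
from .nbs import NBSConfig, NBSResult, NetworkBasedStatistic
from .simulate import SimulationConfig, generate_cohort
from .stats import (ThresholdScheme, demographics_comparison,
                    global_group_comparison, nodal_group_comparison,
                    rank_sum_test, spearman_correlation)

__all__ = ["ConnectomeGroupStudy", "StudyResults", "run_full_analysis"]


def _config_hash(payload: dict) -> str:
    blob = json.dumps(_plain(payload), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyResults:
    """Fitted results of a full connectome group analysis."""

    provenance: dict
    metrics: MetricsTable
    global_comparison: pd.DataFrame
    nodal_comparison: pd.DataFrame
    hub_sets: dict
    hub_overlap: dict
    kappa: dict
    nbs: NBSResult | None
    correlations: pd.DataFrame
    demographics: pd.DataFrame | None
    stages: list = field(default_factory=list)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Connectome group analysis",
            "=" * 60,
            f"config hash {self.provenance['config_hash']}, "
            f"seed {self.provenance['seed']}, "
            f"{self.provenance['n_patients']} patients vs "
            f"{self.provenance['n_controls']} controls, "
            f"{self.provenance['n_nodes']} nodes "
            f"({self.provenance['mode']} mode)",
            "",
            "Global metrics (patients vs controls, rank-sum):",
        ]
        for _, r in self.global_comparison.iterrows():
            lines.append(
                f"  {r['measure']:<12} {r['patient_mean']:.4f} vs "
                f"{r['control_mean']:.4f}   p = {r['p_value']:.4f}")
        deg = self.nodal_comparison[self.nodal_comparison["metric"] == "degree"]
        nb = int(deg["flag_bonferroni"].sum())
        ne = int(deg["flag_exploratory"].sum())
        lines += ["", f"Nodal degree: {nb} node(s) below the Bonferroni "
                      f"threshold, {ne} below the exploratory threshold"]
        for g, hs in self.hub_sets.items():
            lines.append(f"Hubs ({g}): {hs.n_hubs} of {len(hs.mean_profile)} "
                         f"nodes (threshold {hs.threshold:.2f})")
        if self.hub_overlap:
            lines.append(f"  shared hubs: {len(self.hub_overlap['shared'])}; "
                         f"control-only: {len(self.hub_overlap['control_only'])}; "
                         f"patient-only: {len(self.hub_overlap['patient_only'])}")
        for metric, (results, cmp_) in self.kappa.items():
            lines.append(
                f"kappa-{metric}: patients {cmp_['patient_mean_kappa']:+.3f}, "
                f"controls {cmp_['control_mean_kappa']:+.3f}, "
                f"p = {cmp_['p_value']:.4f}")
        if self.nbs is not None:
            lines += ["", self.nbs.summary()]
        if len(self.correlations):
            lines += ["", "Clinical correlations (patients):"]
            for _, r in self.correlations.iterrows():
                flag = "*" if r["significant"] else " "
                lines.append(f"  {flag} {r['metric']} ~ {r['clinical']}: "
                             f"rho = {r['rho']:+.4f}, p = {r['p_value']:.4f}")
        return "\n".join(lines)

    def report_dict(self) -> dict:
        """JSON-serializable report; deterministic for a fixed seed."""
        rep = {
            "provenance": self.provenance,
            "global_comparison": self.global_comparison.to_dict("records"),
            "nodal_flags": {
                metric: {
                    "bonferroni": df[df["flag_bonferroni"]]["node"].tolist(),
                    "exploratory": df[df["flag_exploratory"]]["node"].tolist(),
                }
                for metric, df in self.nodal_comparison.groupby("metric")
            },
            "hubs": {g: {"n_hubs": hs.n_hubs,
                         "threshold": hs.threshold,
                         "nodes": hs.hubs.tolist()}
                     for g, hs in self.hub_sets.items()},
            "hub_overlap": self.hub_overlap,
            "kappa": {m: cmp_ for m, (_, cmp_) in self.kappa.items()},
            "correlations": self.correlations.to_dict("records"),
            "stages": self.stages,
        }
        if self.nbs is not None:
            rep["nbs"] = {
                "components": [
                    {"nodes": list(c.nodes), "edges": [list(e) for e in c.edges],
                     "extent": c.extent, "p_fwer": p, "significant": s}
                    for c, p, s in zip(self.nbs.components, self.nbs.p_fwer,
                                       self.nbs.significant)
                ],
                "n_permutations": len(self.nbs.null_max_extent),
                "fa_sum_comparison": self._fa_sum_comparison(),
            }
        if self.demographics is not None:
            rep["demographics"] = self.demographics.to_dict("records")
        return _plain(rep)

    def _fa_sum_comparison(self) -> list:
        out = []
        if self.nbs is None or self.nbs.fa_sums is None:
            return out
        for comp, df in self.nbs.fa_sums.groupby("component"):
            xp = df[df["group"] == "patient"]["nbs_fa_sum"].to_numpy()
            xc = df[df["group"] == "control"]["nbs_fa_sum"].to_numpy()
            stat, p = rank_sum_test(xp, xc)
            out.append({"component": int(comp),
                        "patient_mean": float(xp.mean()),
                        "control_mean": float(xc.mean()),
                        "statistic": stat, "p_value": p})
        return out

    def save(self, outdir) -> None:
        """Write report.json plus the CSV tables; byte-stable per seed."""
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(str(outdir), "report.json"), "w") as fh:
            json.dump(self.report_dict(), fh, sort_keys=True, indent=2)
            fh.write("\n")
        self.global_comparison.to_csv(
            os.path.join(str(outdir), "global_comparison.csv"), index=False)
        self.nodal_comparison.to_csv(
            os.path.join(str(outdir), "nodal_comparison.csv"), index=False)
        self.correlations.to_csv(
            os.path.join(str(outdir), "correlations.csv"), index=False)
        kap = pd.DataFrame(
            [{"subject_id": r.subject_id, "group": r.group, "metric": r.metric,
              "kappa": r.kappa, "intercept": r.intercept}
             for results, _ in self.kappa.values() for r in results])
        kap.to_csv(os.path.join(str(outdir), "kappa.csv"), index=False)
        if self.demographics is not None:
            self.demographics.to_csv(
                os.path.join(str(outdir), "demographics.csv"), index=False)
        if self.nbs is not None and self.nbs.fa_sums is not None:
            self.nbs.fa_sums.to_csv(
                os.path.join(str(outdir), "nbs_fa_sums.csv"), index=False)

    # -- plots --------------------------------------------------------------

    def plot_kappa(self, ax=None):
        """Box plot of per-subject hub-disruption indices by metric and group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data, labels = [], []
        for metric, (results, _) in self.kappa.items():
            for grp in ("patient", "control"):
                data.append([r.kappa for r in results if r.group == grp])
                labels.append(f"{metric}\n{grp}")
        ax.boxplot(data, tick_labels=labels)
        ax.axhline(0.0, color="gray", lw=0.8)
        ax.set_ylabel("hub disruption index")
        return ax

    def plot_hub_profiles(self, ax=None):
        """Group-mean degree per node, ordered by the control profile."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ctrl = self.hub_sets["control"].mean_profile
        order = np.argsort(ctrl)
        for g, hs in self.hub_sets.items():
            ax.plot(hs.mean_profile[order], label=g, lw=0.9)
            ax.axhline(hs.threshold, ls="--", lw=0.7)
        ax.set_xlabel("node (sorted by control mean degree)")
        ax.set_ylabel("group mean degree")
        ax.legend()
        return ax


class ConnectomeGroupStudy:
    """Model object for the whole-cohort structural connectome analysis."""

    def __init__(self, cohort: Cohort, *, mode: str = "weighted",
                 nbs_config: NBSConfig | None = None,
                 scheme: ThresholdScheme | None = None,
                 metrics: tuple[str, ...] = NODAL_METRICS,
                 seed: int = 0, config_payload: dict | None = None):
        self.cohort = cohort
        self.mode = mode
        self.metrics = tuple(metrics)
        self.nbs_config = nbs_config or NBSConfig(seed=seed)
        self.scheme = scheme or ThresholdScheme(n_tests=cohort.n_nodes)
        self.seed = seed
        self.config_payload = config_payload or {}

    @classmethod
    def from_synthetic(cls, sim_config: SimulationConfig | None = None,
                       seed: int | None = None, **kwargs
                       ) -> "ConnectomeGroupStudy":
        synth = generate_cohort(sim_config, seed=seed)
        payload = {"synthetic": asdict(synth.config)}
        return cls(synth.cohort, seed=synth.config.seed,
                   config_payload=payload, **kwargs)

    @classmethod
    def from_files(cls, manifest_path, matrix_dir, labels_path=None,
                   **kwargs) -> "ConnectomeGroupStudy":
        cohort = load_cohort(manifest_path, matrix_dir, labels_path)
        payload = {"cohort": {"manifest": str(manifest_path),
                              "matrix_dir": str(matrix_dir)}}
        return cls(cohort, config_payload=payload, **kwargs)

    def fit(self, run_nbs: bool = True) -> StudyResults:
        cohort = self.cohort
        stages: list[dict] = []

        def stage(name, fn, default=None):
            try:
                out = fn()
                stages.append({"stage": name, "status": "ok"})
                return out
            except ConnectokitError as exc:
                stages.append({"stage": name, "status": "failed",
                               "error": str(exc)})
                return default

        table = compute_metrics_table(cohort, self.mode, self.metrics)
        stages.append({"stage": "metrics", "status": "ok"})
        global_cmp = stage("global_comparison",
                           lambda: global_group_comparison(table),
                           pd.DataFrame())
        nodal_cmp = stage("nodal_comparison",
                          lambda: nodal_group_comparison(table, self.scheme),
                          pd.DataFrame())
        hub_sets = stage("hubs", lambda: {
            g: identify_hubs(table, g) for g in ("patient", "control")}, {})
        overlap = {}
        if hub_sets:
            hp = set(hub_sets["patient"].hubs.tolist())
            hc = set(hub_sets["control"].hubs.tolist())
            overlap = {"shared": sorted(hp & hc),
                       "patient_only": sorted(hp - hc),
                       "control_only": sorted(hc - hp)}
        kappa = stage("kappa", lambda: {
            m: cohort_kappa(table, m) for m in table.nodal.keys()}, {})
        nbs_result = None
        if run_nbs:
            nbs_result = stage(
                "nbs", lambda: NetworkBasedStatistic(cohort, self.nbs_config).fit())
        correlations = stage("correlations",
                             lambda: self._correlations(table, nodal_cmp),
                             pd.DataFrame())
        demo = None
        if cohort.demographics is not None:
            demo = stage("demographics",
                         lambda: demographics_comparison(cohort.demographics))

        provenance = {
            "package_version": __version__,
            "seed": self.seed,
            "mode": self.mode,
            "n_nodes": cohort.n_nodes,
            "n_patients": len(cohort.patients),
            "n_controls": len(cohort.controls),
            "nbs_config": asdict(self.nbs_config),
            "scheme": asdict(self.scheme),
            "config": _plain(self.config_payload),
        }
        provenance["config_hash"] = _config_hash(provenance)
        return StudyResults(provenance, table, global_cmp, nodal_cmp,
                            hub_sets, overlap, kappa, nbs_result,
                            correlations, demo, stages)

    def _correlations(self, table: MetricsTable,
                      nodal_cmp: pd.DataFrame) -> pd.DataFrame:
        """Spearman correlations of clinical scores with (a) the global
        metrics and (b) degree at the exploratory-flagged nodes."""
        clin = self.cohort.clinical_frame()
        if clin.empty or len(clin) < 4:
            return pd.DataFrame(columns=["metric", "clinical", "rho",
                                         "p_value", "alpha", "significant"])
        clin = clin.set_index("subject_id")
        pats = [s for s in clin.index if s in table.scalars.index]
        rows = []

        def add(metric_name, values, alpha):
            for cname in ("alsfrs_r", "progression_rate"):
                try:
                    rho, p = spearman_correlation(values,
                                                  clin.loc[pats, cname])
                except ConnectokitError:
                    continue
                rows.append({"metric": metric_name, "clinical": cname,
                             "rho": rho, "p_value": p, "alpha": alpha,
                             "significant": bool(p < alpha)})

        for gname in ("eglob", "mean_degree"):
            add(gname, table.scalars.loc[pats, gname],
                self.scheme.global_corr_alpha)
        if len(nodal_cmp):
            deg = nodal_cmp[(nodal_cmp["metric"] == "degree")
                            & nodal_cmp["flag_exploratory"]]
            for node in deg["node"].tolist():
                add(f"degree[node {node}]",
                    table.nodal["degree"].loc[pats, node],
                    self.scheme.local_corr_alpha)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config-file driven entry point


def run_full_analysis(config, out=None) -> StudyResults:
    """Run the full pipeline from a YAML config path or a dict.

    The config holds either a ``synthetic`` block (SimulationConfig
    fields) or a ``cohort`` block (``manifest``, ``matrix_dir``,
    optional ``labels``), plus optional ``mode``, ``metrics``, ``nbs``
    (NBSConfig fields), ``scheme`` (ThresholdScheme fields) and a
    top-level ``seed`` that feeds both the generator and NBS.
    """
    if not isinstance(config, dict):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config or {})
    seed = int(cfg.get("seed", 0))
    mode = cfg.get("mode", "weighted")
    metrics = tuple(cfg.get("metrics", NODAL_METRICS))
    nbs_kwargs = dict(cfg.get("nbs", {}))
    nbs_kwargs.setdefault("seed", seed)
    nbs_config = NBSConfig(**nbs_kwargs)
    scheme = ThresholdScheme(**cfg.get("scheme", {})) if "scheme" in cfg else None
    common = dict(mode=mode, metrics=metrics, nbs_config=nbs_config,
                  scheme=scheme)
    if "cohort" in cfg:
        c = cfg["cohort"]
        study = ConnectomeGroupStudy.from_files(
            c["manifest"], c["matrix_dir"], c.get("labels"), **common)
    else:
        sim_kwargs = dict(cfg.get("synthetic", {}))
        sim_kwargs["seed"] = seed
        study = ConnectomeGroupStudy.from_synthetic(
            SimulationConfig(**sim_kwargs), **common)
    results = study.fit(run_nbs=bool(cfg.get("run_nbs", True)))
    if out is not None:
        results.save(out)
    return results
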