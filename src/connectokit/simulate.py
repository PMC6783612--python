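"""Synthetic FA-weighted connectome cohorts with planted group effects.

The generator emulates the study conditions of a two-group structural
connectome comparison: ~25 patients and ~26 controls, 164-node
symmetric FA-weighted matrices, dense graphs with mean nodal degree
around 110, a planted low-FA subnetwork (10 edges spanning 11 nodes),
planted degree deficits at 6 nodes, an optional planted hub-disruption
slope, and clinical covariates (ALSFRS-R, disease duration) coupled to
a chosen nodal metric through a Gaussian copula on the disease
progression rate (48 - ALSFRS-R) / duration.

Model
-----
Each cohort has one *backbone* graph shared by all subjects: a
maximum-entropy ("beta-model") random graph fitted to a heterogeneous
target degree profile drawn from Normal(base_density * (N-1),
degree_sd).  The across-node spread of expected degrees is what real
connectomes show (group degree SD of order 29 at mean 110) and is what
makes the hub rule and the hub-disruption regression meaningful.
Subjects are the backbone plus independent per-subject edge noise
(each backbone edge dropped with probability ``subject_edge_noise``,
each non-edge added with the density-balancing probability), with
i.i.d. near-Gaussian FA weights per present edge.

Patient effects are applied to each patient's own draw: planted-edge
FA reduced by ``fa_effect``; edges incident to deficit nodes deleted
with ``edge_removal_prob``; and, when ``kappa_target`` is set, the
patient adjacency is redrawn from a beta-model whose expected degree
profile is the backbone profile linearly rescaled so the expected
hub-disruption slope equals the target (an expected-value
construction).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import ndtri

from .errors import CohortError, ConfigurationError
from .io import ClinicalRecord, Cohort, ConnectivityMatrix, Subject

__all__ = [
    "SimulationConfig", "SyntheticCohort", "generate_cohort",
    "generate_control_connectome", "apply_patient_effects",
    "generate_clinical",
]

_AUTO = "auto"

# duration marginal: lognormal matched to 18 +/- 15 months, range [5, 61]
_DUR_MU, _DUR_SIGMA = 2.6266, 0.7260
# progression-rate marginal: lognormal matched to 0.9 +/- 0.9 per month
_RATE_MU, _RATE_SIGMA = -0.4520, 0.8326


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the emulated study: 164 Destrieux-like nodes,
    25 patients vs 26 controls, mean nodal degree ~111 with
    across-node spread ~29, FA weights near 0.35, a 10-edge star
    subnetwork with FA reduced by 0.15 in patients, 6 degree-deficit
    nodes losing ~10% of their edges, and a clinical Spearman
    correlation of -0.54 between the deficit-node degree and the
    progression rate.
    """

    n_nodes: int = 164
    n_patients: int = 25
    n_controls: int = 26
    base_density: float = 0.6838          # mean degree 111.5 at N=164
    degree_sd: float = 29.0               # across-node spread of expected degree
    fa_mean: float = 0.35
    fa_sd: float = 0.08
    planted_component: Sequence[tuple[int, int]] | str = _AUTO
    fa_effect: float = 0.15
    degree_deficit_nodes: Sequence[int] | str = _AUTO
    edge_removal_prob: float = 0.10
    kappa_target: float | None = None
    clinical_rho: float = -0.54
    clinical_node: int | str = _AUTO
    clinical_metric: str = "degree"
    subject_edge_noise: float = 0.03
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- resolved defaults --------------------------------------------------

    @property
    def planted_edges(self) -> list[tuple[int, int]]:
        if self.planted_component == _AUTO:
            if self.n_nodes >= 111:
                # star of 10 edges spanning 11 nodes
                return [(100, j) for j in range(101, 111)]
            return []
        return [tuple(int(v) for v in e) for e in self.planted_component]

    @property
    def deficit_nodes(self) -> list[int]:
        if self.degree_deficit_nodes == _AUTO:
            return list(range(10, 16)) if self.n_nodes >= 16 else []
        return [int(v) for v in self.degree_deficit_nodes]

    @property
    def clinical_node_index(self) -> int:
        if self.clinical_node == _AUTO:
            nodes = self.deficit_nodes
            return nodes[0] if nodes else 0
        return int(self.clinical_node)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ConfigurationError("n_nodes", f"need >= 2 nodes, got {self.n_nodes}")
        if self.n_patients < 0 or self.n_controls < 0:
            raise ConfigurationError("n_patients", "group sizes must be >= 0")
        if not 0.0 <= self.base_density <= 1.0:
            raise ConfigurationError("base_density",
                                     f"must lie in [0, 1], got {self.base_density}")
        if self.degree_sd < 0:
            raise ConfigurationError("degree_sd", "must be >= 0")
        if not 0.0 < self.fa_mean < 1.0:
            raise ConfigurationError("fa_mean",
                                     f"must lie in (0, 1), got {self.fa_mean}")
        if self.fa_sd < 0:
            raise ConfigurationError("fa_sd", "must be >= 0")
        if not 0.0 <= self.fa_effect < 1.0:
            raise ConfigurationError("fa_effect", "must lie in [0, 1)")
        if not 0.0 <= self.edge_removal_prob <= 1.0:
            raise ConfigurationError("edge_removal_prob", "must lie in [0, 1]")
        if not 0.0 <= self.subject_edge_noise <= 1.0:
            raise ConfigurationError("subject_edge_noise", "must lie in [0, 1]")
        if self.kappa_target is not None and not -1.0 <= self.kappa_target <= 1.0:
            raise ConfigurationError("kappa_target",
                                     f"must lie in [-1, 1], got {self.kappa_target}")
        if not -1.0 < self.clinical_rho < 1.0:
            raise ConfigurationError("clinical_rho",
                                     f"must lie in (-1, 1), got {self.clinical_rho}")
        for i, j in self.planted_edges:
            if i == j:
                raise ConfigurationError("planted_component",
                                         f"self-pair ({i}, {j}) not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ConfigurationError(
                    "planted_component",
                    f"edge ({i}, {j}) out of range for {self.n_nodes} nodes")
        for v in self.deficit_nodes:
            if not 0 <= v < self.n_nodes:
                raise ConfigurationError("degree_deficit_nodes",
                                         f"node {v} out of range")
        if not 0 <= self.clinical_node_index < self.n_nodes:
            raise ConfigurationError("clinical_node",
                                     f"node {self.clinical_node} out of range")

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """A cohort with every planted effect switched off."""
        base = dict(planted_component=[], fa_effect=0.0,
                    degree_deficit_nodes=[], edge_removal_prob=0.0,
                    kappa_target=None, clinical_rho=0.0)
        base.update(overrides)
        return cls(**base)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground-truth record of planted effects."""

    cohort: Cohort
    truth: dict
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def matrices(self) -> dict[str, ConnectivityMatrix]:
        return {s.subject_id: s.matrix for s in self.cohort.subjects}

    @property
    def groups(self) -> dict[str, str]:
        return {s.subject_id: s.group for s in self.cohort.subjects}

    @property
    def clinical(self) -> dict[str, tuple[float, float]]:
        return {s.subject_id: (s.clinical.alsfrs_r, s.clinical.duration_months)
                for s in self.cohort.subjects if s.clinical is not None}


# ---------------------------------------------------------------------------
# seeded substreams: one global seed expands into stable per-purpose and
# per-subject streams keyed by CRC32 of the subject id, so changing cohort
# size never reshuffles existing subjects.

_STREAM_STRUCTURE = 11
_STREAM_SUBJECT = 101
_STREAM_DEMOGRAPHICS = 301
_STREAM_CLINICAL = 401


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    return _rng(seed, _STREAM_SUBJECT, zlib.crc32(subject_id.encode()))


# ---------------------------------------------------------------------------
# structural model


def _target_degrees(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Heterogeneous expected-degree profile with exact mean base_density*(N-1)."""
    n = config.n_nodes
    mean = config.base_density * (n - 1)
    if config.degree_sd == 0 or config.base_density in (0.0, 1.0):
        return np.full(n, mean)
    d = rng.normal(mean, config.degree_sd, size=n)
    lo, hi = max(0.5, 0.02 * (n - 1)), 0.98 * (n - 1)
    lo = min(lo, mean) if mean > 0 else lo
    for _ in range(30):
        d = np.clip(d, lo, hi)
        d = d + (mean - d.mean())
    return np.clip(d, 0.0, float(n - 1))


def fit_edge_probabilities(degrees: np.ndarray, tol: float = 1e-9,
                           max_iter: int = 2000) -> np.ndarray:
    """Edge probabilities of the maximum-entropy graph with the given
    expected degree sequence (beta-model), p_ij = x_i x_j / (1 + x_i x_j).

    Fitted by the standard fixed-point iteration on the node
    propensities x.  Degrees are capped just below N-1 so the fixed
    point stays finite.
    """
    d = np.asarray(degrees, dtype=float)
    n = len(d)
    if n < 2 or d.max() <= 0:
        return np.zeros((n, n))
    d = np.clip(d, 0.0, (n - 1) * (1 - 1e-9))
    x = d / (n - 1)
    x = x / np.maximum(1.0 - x, 1e-12)
    for _ in range(max_iter):
        denom = 1.0 + np.outer(x, x)
        m = x[None, :] / denom          # m[i, j] = x_j / (1 + x_i x_j)
        np.fill_diagonal(m, 0.0)
        s = m.sum(axis=1)
        x_new = np.where(s > 0, d / np.maximum(s, 1e-300), 0.0)
        if np.max(np.abs(x_new - x)) < tol * (1 + np.max(np.abs(x))):
            x = x_new
            break
        x = x_new
    p = np.outer(x, x)
    p = p / (1.0 + p)
    np.fill_diagonal(p, 0.0)
    return p


def _edge_probabilities(config: SimulationConfig,
                        rng: np.random.Generator) -> np.ndarray:
    n = config.n_nodes
    if config.base_density == 0.0:
        return np.zeros((n, n))
    if config.base_density == 1.0:
        p = np.ones((n, n))
        np.fill_diagonal(p, 0.0)
        return p
    return fit_edge_probabilities(_target_degrees(config, rng))


def _draw_adjacency(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = p.shape[0]
    iu = np.triu_indices(n, 1)
    a = np.zeros((n, n), dtype=bool)
    a[iu] = rng.random(len(iu[0])) < p[iu]
    return a | a.T


def _noisy_subject_adjacency(base: np.ndarray, config: SimulationConfig,
                             rng: np.random.Generator) -> np.ndarray:
    """Per-subject copy of a base adjacency: drop each edge with probability
    ``subject_edge_noise``, add each non-edge with the probability that
    preserves the expected mean degree."""
    delta = config.subject_edge_noise
    if delta == 0:
        return base.copy()
    dens = config.base_density
    eta = delta * dens / (1.0 - dens) if dens < 1.0 else 0.0
    eta = min(eta, 1.0)
    n = base.shape[0]
    iu = np.triu_indices(n, 1)
    u = rng.random(len(iu[0]))
    present = base[iu]
    keep = np.where(present, u >= delta, u < eta)
    a = np.zeros((n, n), dtype=bool)
    a[iu] = keep
    return a | a.T


def _assign_weights(adjacency: np.ndarray, config: SimulationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """FA weights for present edges: Normal(fa_mean, fa_sd) clipped into
    (0, 1); the clipped mass is negligible at the default location/scale."""
    n = adjacency.shape[0]
    iu = np.triu_indices(n, 1)
    w = np.zeros((n, n))
    vals = rng.normal(config.fa_mean, config.fa_sd, size=len(iu[0]))
    vals = np.clip(vals, 1e-3, 1.0 - 1e-3)
    w[iu] = np.where(adjacency[iu], vals, 0.0)
    return w + w.T


# ---------------------------------------------------------------------------
# public operations


def generate_control_connectome(config: SimulationConfig,
                                rng: np.random.Generator,
                                *, base: np.ndarray | None = None,
                                edge_probs: np.ndarray | None = None,
                                subject_id: str = "control") -> ConnectivityMatrix:
    """Draw one control connectome.

    Standalone calls draw a fresh graph from the configured edge-
    probability model; cohort generation passes the shared backbone via
    ``base`` so subjects differ only by the per-subject edge noise.
    """
    config.validate()
    if base is not None:
        adjacency = _noisy_subject_adjacency(np.asarray(base, bool), config, rng)
    else:
        if edge_probs is None:
            edge_probs = _edge_probabilities(config, rng)
        adjacency = _draw_adjacency(edge_probs, rng)
    weights = _assign_weights(adjacency, config, rng)
    return ConnectivityMatrix(weights, subject_id=subject_id)


def _remove_deficit_edges(weights: np.ndarray, config: SimulationConfig,
                          rng: np.random.Generator) -> np.ndarray:
    w = weights.copy()
    p = config.edge_removal_prob
    if p == 0:
        return w
    for v in config.deficit_nodes:
        incident = np.flatnonzero(w[v] > 0)
        drop = incident[rng.random(len(incident)) < p]
        w[v, drop] = 0.0
        w[drop, v] = 0.0
    return w


def _reduce_planted_fa(weights: np.ndarray, config: SimulationConfig) -> np.ndarray:
    w = weights.copy()
    for i, j in config.planted_edges:
        if w[i, j] > 0:
            val = max(w[i, j] - config.fa_effect, 1e-3)
            w[i, j] = w[j, i] = val
    return w


def _kappa_profile(reference_degrees: np.ndarray, kappa: float) -> np.ndarray:
    ref = np.asarray(reference_degrees, dtype=float)
    d = ref + kappa * (ref - ref.mean())
    return np.clip(d, 0.5, 0.98 * (len(ref) - 1))


def apply_patient_effects(matrix: ConnectivityMatrix, config: SimulationConfig,
                          rng: np.random.Generator,
                          *, reference_degrees: np.ndarray | None = None
                          ) -> ConnectivityMatrix:
    """Turn a control-style draw into a patient connectome.

    Applies, in order: the hub-disruption rescaling (when
    ``kappa_target`` is set, the adjacency is redrawn from a beta-model
    whose expected degree profile is the reference profile rescaled by
    the target slope, followed by the usual subject noise), the
    deficit-node edge deletions, and the planted-component FA
    reduction.  With all effect parameters at zero the input is
    returned unchanged.
    """
    config.validate()
    n = matrix.n_nodes
    if n != config.n_nodes:
        raise ConfigurationError("n_nodes",
                                 f"matrix has {n} nodes, config says {config.n_nodes}")
    if config.kappa_target is not None:
        if reference_degrees is None:
            raise ConfigurationError(
                "kappa_target",
                "planting a hub-disruption slope requires reference_degrees "
                "(the cohort backbone degree profile)")
        p2 = fit_edge_probabilities(_kappa_profile(reference_degrees,
                                                   config.kappa_target))
        adjacency = _noisy_subject_adjacency(_draw_adjacency(p2, rng), config, rng)
        weights = _assign_weights(adjacency, config, rng)
    else:
        weights = matrix.weights.copy()
    weights = _remove_deficit_edges(weights, config, rng)
    weights = _reduce_planted_fa(weights, config)
    return ConnectivityMatrix(weights, list(matrix.node_ids), matrix.subject_id)


def generate_clinical(cohort: Cohort, config: SimulationConfig,
                      rng: np.random.Generator) -> Cohort:
    """Attach ALSFRS-R and disease duration to every patient.

    The disease progression rate (48 - ALSFRS-R)/duration is sampled
    from a lognormal marginal matched to the emulated cohort
    (0.9 +/- 0.9 per month) and coupled to the configured nodal metric
    through a Gaussian copula so that the Spearman correlation between
    metric and rate is approximately ``clinical_rho``.  ALSFRS-R is an
    integer; duration is back-solved so the progression-rate formula
    holds exactly.
    """
    config.validate()
    patients = cohort.patients
    if not patients:
        raise CohortError("cohort has no patient subjects")
    from . import metrics as gm

    node = config.clinical_node_index
    vals = []
    for s in patients:
        if config.clinical_metric == "degree":
            vals.append(gm.node_degree(s.matrix)[node])
        elif config.clinical_metric == "eloc":
            vals.append(gm.local_efficiency(s.matrix)[node])
        elif config.clinical_metric == "bc":
            vals.append(gm.betweenness_centrality(s.matrix)[node])
        else:
            raise ConfigurationError("clinical_metric",
                                     f"unknown metric {config.clinical_metric!r}")
    vals = np.asarray(vals, dtype=float)
    npat = len(patients)

    from scipy.stats import rankdata

    scores = ndtri((rankdata(vals) - 0.5) / npat)
    sd = scores.std()
    scores = scores / sd if sd > 0 else np.zeros(npat)
    # Pearson copula parameter that yields the target Spearman correlation
    rho_p = 2.0 * np.sin(np.pi * config.clinical_rho / 6.0)
    z = rho_p * scores + np.sqrt(max(1.0 - rho_p ** 2, 0.0)) * rng.standard_normal(npat)
    rate = np.exp(_RATE_MU + _RATE_SIGMA * z)
    rate = np.clip(rate, 0.02, 6.0)
    dur0 = np.clip(np.exp(_DUR_MU + _DUR_SIGMA * rng.standard_normal(npat)), 5.0, 61.0)
    alsfrs = np.clip(np.round(48.0 - rate * dur0), 0.0, 47.0)
    duration = (48.0 - alsfrs) / rate
    subjects = []
    by_id = {s.subject_id: s for s in patients}
    for s in cohort.subjects:
        if s.subject_id in by_id:
            k = patients.index(s)
            clin = ClinicalRecord(float(alsfrs[k]), float(duration[k]))
            subjects.append(Subject(s.subject_id, s.group, s.matrix, clin))
        else:
            subjects.append(s)
    return Cohort(subjects, list(cohort.node_ids), cohort.demographics)


def generate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort under the configured conditions."""
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = config.with_seed(seed)
    config.validate()
    if config.n_patients < 1 or config.n_controls < 1:
        raise ConfigurationError("n_patients", "cohort needs both groups")
    rng_struct = _rng(config.seed, _STREAM_STRUCTURE)
    edge_probs = _edge_probabilities(config, rng_struct)
    backbone = _draw_adjacency(edge_probs, rng_struct)
    for i, j in config.planted_edges:       # planted edges always exist
        backbone[i, j] = backbone[j, i] = True
    backbone_degrees = backbone.sum(axis=0).astype(float)

    kappa_probs = None
    if config.kappa_target is not None:
        kappa_probs = fit_edge_probabilities(
            _kappa_profile(backbone_degrees, config.kappa_target))

    subjects = []
    for k in range(config.n_patients):
        sid = f"sub-P{k + 1:02d}"
        rng_s = _subject_rng(config.seed, sid)
        if kappa_probs is not None:
            adjacency = _noisy_subject_adjacency(
                _draw_adjacency(kappa_probs, rng_s), config, rng_s)
            weights = _assign_weights(adjacency, config, rng_s)
        else:
            adjacency = _noisy_subject_adjacency(backbone, config, rng_s)
            weights = _assign_weights(adjacency, config, rng_s)
        weights = _remove_deficit_edges(weights, config, rng_s)
        weights = _reduce_planted_fa(weights, config)
        subjects.append(Subject(sid, "patient",
                                ConnectivityMatrix(weights, subject_id=sid)))
    for k in range(config.n_controls):
        sid = f"sub-C{k + 1:02d}"
        rng_s = _subject_rng(config.seed, sid)
        subjects.append(Subject(
            sid, "control",
            generate_control_connectome(config, rng_s, base=backbone,
                                        subject_id=sid)))

    demographics = _demographics(subjects, config)
    cohort = Cohort(subjects, demographics=demographics)
    cohort = generate_clinical(cohort, config,
                               _rng(config.seed, _STREAM_CLINICAL))

    truth = {
        "seed": config.seed,
        "n_nodes": config.n_nodes,
        "n_patients": config.n_patients,
        "n_controls": config.n_controls,
        "planted_edges": [list(e) for e in config.planted_edges],
        "fa_effect": config.fa_effect,
        "deficit_nodes": config.deficit_nodes,
        "edge_removal_prob": config.edge_removal_prob,
        "kappa_target": config.kappa_target,
        "clinical_rho": config.clinical_rho,
        "clinical_node": config.clinical_node_index,
        "clinical_metric": config.clinical_metric,
        "backbone_mean_degree": float(backbone_degrees.mean()),
    }
    return SyntheticCohort(cohort, truth, config)


def _demographics(subjects, config: SimulationConfig):
    """Age and sex per subject, matched to the emulated cohort profile
    (patients ~55 +/- 10 y, 16/25 male; controls ~51 +/- 10 y, 15/26 male)."""
    import pandas as pd

    rng = _rng(config.seed, _STREAM_DEMOGRAPHICS)
    rows = []
    for s in subjects:
        if s.group == "patient":
            age = rng.normal(55.0, 10.0)
            male = rng.random() < 16 / 25
        else:
            age = rng.normal(51.0, 10.0)
            male = rng.random() < 15 / 26
        rows.append({"subject_id": s.subject_id, "group": s.group,
                     "age": float(np.clip(age, 25.0, 85.0)),
                     "sex": "M" if male else "F"})
    return pd.DataFrame(rows)
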