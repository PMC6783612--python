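"""Network-based statistics (NBS) with permutation FWER inference.

NBS tests for a connected subnetwork of altered connections instead of
correcting 13k edge-wise tests individually: an edge-wise two-sample
statistic is thresholded at a primary threshold, connected components
of the supra-threshold graph are extracted, and the family-wise-error
corrected p-value of each component's extent (edge count) is obtained
from the permutation distribution of the *maximal* component extent
under random relabeling of the group labels.

The default orientation is one-sided in the FA-decrease direction
(statistic = control mean minus patient mean over the pooled-variance
standard error), since the phenomenon of interest is reduced tract
integrity in patients; two-sided testing is available.  Edges enter
testing only when present (nonzero) in at least ``edge_mask_rule`` of
the subjects, so group means are not computed over wildly differing
support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import CohortError, ConfigurationError, ConnectokitError
from .io import Cohort, ConnectivityMatrix

__all__ = ["NBSConfig", "Component", "NBSResult", "edge_statistic",
           "supra_threshold_components", "nbs_fa_sum", "nbs_test",
           "NetworkBasedStatistic"]


@dataclass
class NBSConfig:
    """Parameters of one NBS run.

    ``edge_stat`` chooses the edge-wise two-sample statistic:
    ``"t"`` (pooled-variance t) or ``"rank"`` (rank-sum z).
    ``primary_threshold`` is in the units of that statistic.
    ``edge_mask_rule`` is the minimum fraction of subjects in which an
    edge must be nonzero to enter testing.
    """

    edge_stat: str = "t"
    primary_threshold: float = 3.0
    n_permutations: int = 5000
    alpha: float = 0.05
    edge_mask_rule: float = 0.9
    alternative: str = "greater"     # FA decrease in patients; or "two-sided"
    seed: int = 0

    def __post_init__(self):
        if self.edge_stat not in ("t", "rank"):
            raise ConfigurationError("edge_stat",
                                     f"must be 't' or 'rank', got {self.edge_stat!r}")
        if self.n_permutations < 100:
            raise ConfigurationError("n_permutations",
                                     f"need >= 100, got {self.n_permutations}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha", f"must lie in (0, 1), got {self.alpha}")
        if not self.primary_threshold > 0:
            raise ConfigurationError("primary_threshold",
                                     f"must be > 0, got {self.primary_threshold}")
        if not 0.0 <= self.edge_mask_rule <= 1.0:
            raise ConfigurationError("edge_mask_rule", "must lie in [0, 1]")
        if self.alternative not in ("greater", "two-sided"):
            raise ConfigurationError("alternative",
                                     "must be 'greater' or 'two-sided'")


@dataclass(frozen=True)
class Component:
    """A connected component of the supra-threshold graph."""

    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]

    @property
    def extent(self) -> int:
        return len(self.edges)


@dataclass
class NBSResult:
    """Observed components, permutation null, and FWER p-values."""

    components: list[Component]
    p_fwer: list[float]
    null_max_extent: np.ndarray
    significant: list[bool]
    stat_matrix: np.ndarray = field(repr=False, default=None)
    mask: np.ndarray = field(repr=False, default=None)
    fa_sums: pd.DataFrame | None = None
    zero_variance_edges: list[tuple[int, int]] = field(default_factory=list)
    config: NBSConfig | None = None

    @property
    def max_extent(self) -> int:
        return max((c.extent for c in self.components), default=0)

    def significant_components(self) -> list[Component]:
        return [c for c, s in zip(self.components, self.significant) if s]

    def summary(self) -> str:
        lines = [f"NBS: {len(self.components)} supra-threshold component(s), "
                 f"{len(self.null_max_extent)} permutations"]
        for c, p, s in zip(self.components, self.p_fwer, self.significant):
            flag = "*" if s else " "
            lines.append(f"  {flag} {len(c.nodes)} nodes / {c.extent} edges, "
                         f"p_fwer = {p:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# edge-wise statistics (vectorized over edges x permutations)


def _t_statistic(x: np.ndarray, is_patient: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t per edge, oriented control - patient.

    ``x`` is (n_subjects, n_edges); ``is_patient`` boolean per subject.
    Returns (t, standard error); zero-pooled-variance edges get
    statistic 0.
    """
    n1 = int(is_patient.sum())
    n2 = len(is_patient) - n1
    xp = x[is_patient]
    xc = x[~is_patient]
    mp, mc = xp.mean(axis=0), xc.mean(axis=0)
    ssq = ((xp - mp) ** 2).sum(axis=0) + ((xc - mc) ** 2).sum(axis=0)
    sp2 = ssq / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mc - mp) / np.where(se > 0, se, 1.0), 0.0)
    return t, se


def _rank_statistic(ranks: np.ndarray, is_patient: np.ndarray) -> np.ndarray:
    """Rank-sum z per edge (tie-corrected), oriented so larger control
    weights give a positive statistic.  ``ranks`` are per-edge ranks of
    the pooled sample (n_subjects, n_edges).  Returns (z, variance)."""
    n = len(is_patient)
    n1 = int(is_patient.sum())
    n2 = n - n1
    rc = ranks[~is_patient].sum(axis=0)
    mu = n2 * (n + 1) / 2.0
    base = n1 * n2 * (n + 1) / 12.0
    corr = np.zeros(ranks.shape[1])
    for e in range(ranks.shape[1]):
        _, counts = np.unique(ranks[:, e], return_counts=True)
        corr[e] = (counts ** 3 - counts).sum()
    var = base - n1 * n2 * corr / (12.0 * n * (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (rc - mu) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    return z, var


def edge_statistic(cohort: Cohort, config: NBSConfig | None = None
                   ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Edge-wise statistic matrix over masked edges.

    Returns ``(stat, mask, zero_variance_edges)``; ``stat`` is NxN
    symmetric with NaN where the edge is not tested, ``mask`` the
    boolean NxN matrix of tested edges.
    """
    if config is None:
        config = NBSConfig()
    order = np.argsort(cohort.subject_ids)   # canonical subject order, so
    stack = cohort.stack()[order]            # results ignore cohort ordering
    is_patient = cohort.is_patient_mask()[order]
    if is_patient.sum() < 2 or (~is_patient).sum() < 2:
        raise CohortError("NBS needs >= 2 subjects per group")
    n = stack.shape[1]
    iu = np.triu_indices(n, 1)
    x = stack[:, iu[0], iu[1]]                       # (S, E_all)
    present = (x > 0).mean(axis=0)
    keep = present >= config.edge_mask_rule - 1e-12
    xk = x[:, keep]
    if config.edge_stat == "t":
        s, scale = _t_statistic(xk, is_patient)
    else:
        ranks = rankdata(xk, axis=0)
        s, scale = _rank_statistic(ranks, is_patient)
    zero_var = scale <= 1e-12      # tolerates fp residue of identical values
    stat = np.full((n, n), np.nan)
    mask = np.zeros((n, n), dtype=bool)
    ik, jk = iu[0][keep], iu[1][keep]
    stat[ik, jk] = stat[jk, ik] = s
    mask[ik, jk] = mask[jk, ik] = True
    zv = [(int(a), int(b)) for a, b in zip(ik[zero_var], jk[zero_var])]
    return stat, mask, zv


# ---------------------------------------------------------------------------
# components


def _components_from_edges(edge_i: np.ndarray, edge_j: np.ndarray
                           ) -> list[tuple[list[int], list[tuple[int, int]]]]:
    """Union-find over an explicit edge list; returns (nodes, edges) groups."""
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in zip(edge_i, edge_j):
        a, b = int(a), int(b)
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, tuple[list[int], list[tuple[int, int]]]] = {}
    for v in parent:
        groups.setdefault(find(v), ([], []))[0].append(v)
    for a, b in zip(edge_i, edge_j):
        groups[find(int(a))][1].append((int(min(a, b)), int(max(a, b))))
    return list(groups.values())


def supra_threshold_components(stat_matrix: np.ndarray, threshold: float,
                               alternative: str = "greater") -> list[Component]:
    """Connected components of the graph of supra-threshold edges."""
    s = np.asarray(stat_matrix, dtype=float)
    tri = np.triu(np.ones_like(s, dtype=bool), 1)
    vals = np.where(np.isnan(s), -np.inf, s)
    if alternative == "two-sided":
        vals = np.abs(vals)
    hit = tri & (vals >= threshold)
    i, j = np.nonzero(hit)
    comps = []
    for nodes, edges in _components_from_edges(i, j):
        comps.append(Component(tuple(sorted(nodes)),
                               tuple(sorted(edges))))
    comps.sort(key=lambda c: (-c.extent, c.nodes))
    return comps


def nbs_fa_sum(matrix: ConnectivityMatrix, edges) -> float:
    """Sum of a subject's FA weights over a component's edges.

    Edges absent in the subject contribute 0.
    """
    edges = list(edges)
    if not edges:
        raise ConnectokitError("empty component edge set")
    w = matrix.weights
    return float(sum(w[i, j] for i, j in edges))


# ---------------------------------------------------------------------------
# the permutation test


def _max_extent(edge_i: np.ndarray, edge_j: np.ndarray) -> int:
    comps = _components_from_edges(edge_i, edge_j)
    return max((len(e) for _, e in comps), default=0)


class NetworkBasedStatistic:
    """NBS model object: built from a cohort, ``fit()`` runs the test."""

    def __init__(self, cohort: Cohort, config: NBSConfig | None = None):
        self.cohort = cohort
        self.config = config or NBSConfig()

    def fit(self, exact: bool = False) -> NBSResult:
        cohort, config = self.cohort, self.config
        stat, mask, zero_var = edge_statistic(cohort, config)
        obs_comps = supra_threshold_components(stat, config.primary_threshold,
                                               config.alternative)

        order = np.argsort(cohort.subject_ids)
        stack = cohort.stack()[order]
        is_patient = cohort.is_patient_mask()[order]
        n_sub = len(is_patient)
        n_pat = int(is_patient.sum())
        n = stack.shape[1]
        iu = np.triu_indices(n, 1)
        keep = mask[iu]
        x = stack[:, iu[0], iu[1]][:, keep]          # (S, E)
        ik, jk = iu[0][keep], iu[1][keep]
        use_rank = config.edge_stat == "rank"
        if use_rank:
            x = rankdata(x, axis=0)

        total = comb(n_sub, n_pat)
        if exact:
            labelings = np.zeros((total, n_sub), dtype=bool)
            for r, idx in enumerate(combinations(range(n_sub), n_pat)):
                labelings[r, list(idx)] = True
        else:
            if total < config.n_permutations:
                raise CohortError(
                    f"only {total} distinct group labelings exist but "
                    f"{config.n_permutations} permutations were requested; "
                    f"use fit(exact=True) for exhaustive enumeration")
            rng = np.random.default_rng(config.seed)
            labelings = np.zeros((config.n_permutations, n_sub), dtype=bool)
            for r in range(config.n_permutations):
                labelings[r, rng.permutation(n_sub)[:n_pat]] = True

        null = self._null_max_extents(x, labelings, ik, jk)
        k = len(null)
        p_fwer, significant = [], []
        for c in obs_comps:
            p = (1.0 + int((null >= c.extent).sum())) / (k + 1.0)
            p_fwer.append(float(p))
            significant.append(bool(p <= config.alpha))

        fa_sums = self._fa_sums(obs_comps, significant)
        return NBSResult(obs_comps, p_fwer, null, significant, stat, mask,
                         fa_sums, zero_var, config)

    def _null_max_extents(self, x: np.ndarray, labelings: np.ndarray,
                          ik: np.ndarray, jk: np.ndarray) -> np.ndarray:
        """Maximal supra-threshold component extent per relabeling.

        Group sums for all relabelings are computed with one matrix
        product per chunk; the component search only ever sees the few
        supra-threshold edges of each relabeling.
        """
        config = self.config
        n_sub, n_edges = x.shape
        n_pat = int(labelings[0].sum())
        n_ctrl = n_sub - n_pat
        thr = config.primary_threshold
        two_sided = config.alternative == "two-sided"
        use_rank = config.edge_stat == "rank"

        tot = x.sum(axis=0)
        if use_rank:
            mu = n_ctrl * (n_sub + 1) / 2.0
            base = n_pat * n_ctrl * (n_sub + 1) / 12.0
            corr = np.zeros(n_edges)
            for e in range(n_edges):
                _, counts = np.unique(x[:, e], return_counts=True)
                corr[e] = (counts ** 3 - counts).sum()
            var = base - n_pat * n_ctrl * corr / (12.0 * n_sub * (n_sub - 1))
            sd = np.sqrt(np.where(var > 0, var, np.inf))
        else:
            totsq = (x ** 2).sum(axis=0)

        out = np.empty(labelings.shape[0], dtype=int)
        chunk = max(1, int(2e7 // max(n_edges, 1)))
        xt = np.ascontiguousarray(x.T)               # (E, S)
        xt2 = xt ** 2 if not use_rank else None
        for start in range(0, labelings.shape[0], chunk):
            lab = labelings[start:start + chunk].T.astype(float)   # (S, K)
            s_pat = xt @ lab                                       # (E, K)
            if use_rank:
                rc = (tot[:, None] - s_pat)
                z = (rc - mu) / sd[:, None]
                stat = z
            else:
                ssq_pat = xt2 @ lab
                mp = s_pat / n_pat
                mc = (tot[:, None] - s_pat) / n_ctrl
                ssq = (ssq_pat - n_pat * mp ** 2 +
                       (totsq[:, None] - ssq_pat) - n_ctrl * mc ** 2)
                sp2 = np.maximum(ssq, 0.0) / (n_sub - 2)
                se = np.sqrt(sp2 * (1.0 / n_pat + 1.0 / n_ctrl))
                with np.errstate(divide="ignore", invalid="ignore"):
                    stat = np.where(se > 0, (mc - mp) / np.where(se > 0, se, 1.0),
                                    0.0)
            if two_sided:
                stat = np.abs(stat)
            hits = stat >= thr                                      # (E, K)
            for c in range(hits.shape[1]):
                e = np.flatnonzero(hits[:, c])
                out[start + c] = _max_extent(ik[e], jk[e])
        return out

    def _fa_sums(self, components, significant) -> pd.DataFrame | None:
        sig = [(idx, c) for idx, (c, s) in enumerate(zip(components, significant))
               if s]
        if not sig:
            return None
        rows = []
        for idx, c in sig:
            for s in self.cohort.subjects:
                rows.append({"component": idx, "subject_id": s.subject_id,
                             "group": s.group,
                             "nbs_fa_sum": nbs_fa_sum(s.matrix, c.edges)})
        return pd.DataFrame(rows)


def nbs_test(cohort: Cohort, config: NBSConfig | None = None,
             exact: bool = False) -> NBSResult:
    """Functional wrapper around :class:`NetworkBasedStatistic`."""
    return NetworkBasedStatistic(cohort, config).fit(exact=exact)
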