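"""Binarized correlation networks, graph metrics and permutation inference.

Measures are nodes; the strongest quarter of the C(p,2) pairwise Pearson
correlations (ranked by |r|) become unweighted edges.  Two topology
summaries quantify reorganization after surgery: the mean local clustering
coefficient and the Newman-Girvan modularity Q of Louvain partitions
averaged over repeated runs with independent random node orders.  Network
change is measured as mean Delta-r - the mean over all measure pairs of the
(absolute, by default) change in correlation between two visits.

Because the study deposits no analytic null, inference is by resampling:

* ``within_subject_visit`` - per subject, the pre- and post-surgery measure
  vectors are swapped with probability one half and the whole statistic
  pipeline recomputed; exchangeable under "surgery did not alter the joint
  distribution of the measures".
* ``between_group`` - group labels are reshuffled over subjects preserving
  group sizes; exchangeable under "arms do not differ".

Probabilities are one-sided on the magnitude statistic with the +1
correction (never exactly zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("painnet")


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    n: int
    group: str | None = None
    visit: str | None = None

    @property
    def measure_ids(self) -> list[str]:
        return list(self.r.columns)

    def to_dict(self) -> dict:
        return {"measure_ids": self.measure_ids, "n": self.n,
                "group": self.group, "visit": self.visit,
                "r": self.r.to_numpy().tolist()}


def correlation_matrix(harmonized: pd.DataFrame, group: str | None = None,
                       visit: str | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlations of a complete subjects x measures matrix."""
    X = harmonized.to_numpy(float)
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 subjects")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [c for c, s in zip(harmonized.columns, sds) if s == 0]
        raise ValueError(f"zero-variance measures: {bad}")
    R = np.corrcoef(X, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(
        r=pd.DataFrame(R, index=harmonized.columns, columns=harmonized.columns),
        n=n, group=group, visit=visit)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher z test for the difference of two independent correlations."""
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in each sample")
    z = (np.arctanh(r2) - np.arctanh(r1)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

@dataclass
class BinaryNetwork:
    graph: nx.Graph
    fraction: float
    communities: dict = field(default_factory=dict)
    group: str | None = None
    visit: str | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes())

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def ranked_pairs(R: np.ndarray, names: Sequence) -> list[tuple]:
    """All off-diagonal pairs ranked by |r| descending, ties lexicographic."""
    iu, ju = np.triu_indices(R.shape[0], 1)
    pairs = [(float(abs(R[i, j])), names[i], names[j]) for i, j in zip(iu, ju)]
    pairs.sort(key=lambda t: (-t[0], str(t[1]), str(t[2])))
    return pairs


def binarize_top(corr: CorrelationMatrix, fraction: float = 0.25,
                 communities: dict | None = None,
                 absolute: bool = True) -> BinaryNetwork:
    """Keep the top round(fraction * C(p,2)) strongest correlations as edges.

    Ranking uses |r| by default (both strongly negative and strongly positive
    correlations can form edges; the walking-distance measure correlates
    negatively with everything "worse"); set ``absolute=False`` for
    positive-only ranking.  Community labels (normally the factor-model
    membership) are attached to nodes.
    """
    names = corr.measure_ids
    p = len(names)
    if p < 3:
        raise ValueError("need at least 3 nodes")
    R = corr.r.to_numpy(float).copy()
    if not absolute:
        R = np.where(R > 0, R, 0.0)
    n_pairs = p * (p - 1) // 2
    k = _round_half_up(fraction * n_pairs)
    if k < 1:
        raise ValueError(f"fraction {fraction} keeps zero edges")
    pairs = ranked_pairs(np.abs(R), names)
    G = nx.Graph()
    G.add_nodes_from(names)
    for _, a, b in pairs[:k]:
        G.add_edge(a, b)
    communities = dict(communities or {})
    for node in G.nodes():
        G.nodes[node]["community"] = str(communities.get(node, "unassigned"))
    return BinaryNetwork(graph=G, fraction=fraction, communities=communities,
                         group=corr.group, visit=corr.visit)


# ---------------------------------------------------------------------------
# Graph metrics
# ---------------------------------------------------------------------------

@dataclass
class NetworkMetrics:
    mean_clustering: float
    modularity_mean: float
    modularity_sd: float
    reps: int
    best_partition: list = field(default_factory=list)
    modularity_draws: list = field(default_factory=list)


def mean_clustering(net: BinaryNetwork | nx.Graph) -> float:
    """Mean local clustering coefficient; degree < 2 nodes contribute 0."""
    G = net.graph if isinstance(net, BinaryNetwork) else net
    if G.number_of_nodes() < 1:
        raise ValueError("empty graph")
    return float(nx.average_clustering(G, count_zeros=True))


def louvain_modularity(net: BinaryNetwork | nx.Graph, reps: int = 100,
                       seed: int = 0, starts: int = 5) -> NetworkMetrics:
    """Louvain partitions over ``reps`` random node orders; Newman-Girvan Q.

    A single greedy Louvain pass is not a consistent estimator of the
    achievable Q on small rugged graphs (it can stick in a multi-node-trap
    local optimum), so each repetition reports the best of ``starts``
    independent random-order runs.  Returns the mean and SD of Q over
    repetitions plus the best partition seen.  Deterministic given ``seed``.
    """
    G = net.graph if isinstance(net, BinaryNetwork) else net
    if G.number_of_edges() < 1:
        raise ValueError("graph has no edges")
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(reps * starts)
    qs = []
    best_q, best_part = -np.inf, None
    for r in range(reps):
        rep_q, rep_part = -np.inf, None
        for j in range(starts):
            part = nx.community.louvain_communities(
                G, seed=int(sub[r * starts + j] % (2 ** 31)))
            q = nx.community.modularity(G, part)
            if q > rep_q:
                rep_q, rep_part = q, part
        qs.append(rep_q)
        if rep_q > best_q:
            best_q, best_part = rep_q, rep_part
    qs = np.asarray(qs)
    return NetworkMetrics(
        mean_clustering=mean_clustering(G),
        modularity_mean=float(qs.mean()),
        modularity_sd=float(qs.std(ddof=1)) if reps > 1 else 0.0,
        reps=reps,
        best_partition=[sorted(c) for c in best_part],
        modularity_draws=qs.tolist(),
    )


# ---------------------------------------------------------------------------
# Network change
# ---------------------------------------------------------------------------

@dataclass
class NetworkComparison:
    mean_delta_r: float                 # mean |r_b - r_a| over all pairs
    mean_delta_r_signed: float          # mean (r_b - r_a), reported alongside
    delta_r: pd.DataFrame               # per-pair signed change
    delta_clustering: float | None = None
    delta_modularity: float | None = None
    permutation_results: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_delta_r": self.mean_delta_r,
            "mean_delta_r_signed": self.mean_delta_r_signed,
            "delta_clustering": self.delta_clustering,
            "delta_modularity": self.delta_modularity,
            "permutation_results": {k: v.to_dict() if hasattr(v, "to_dict") else v
                                    for k, v in self.permutation_results.items()},
        }


def mean_delta_r(corr_a: CorrelationMatrix, corr_b: CorrelationMatrix
                 ) -> NetworkComparison:
    """Change in correlation for every measure pair, averaged over the network."""
    if corr_a.measure_ids != corr_b.measure_ids:
        raise ValueError("correlation matrices cover different measures")
    A = corr_a.r.to_numpy(float)
    B = corr_b.r.to_numpy(float)
    D = B - A
    iu = np.triu_indices(A.shape[0], 1)
    return NetworkComparison(
        mean_delta_r=float(np.abs(D[iu]).mean()),
        mean_delta_r_signed=float(D[iu].mean()),
        delta_r=pd.DataFrame(D, index=corr_a.r.index, columns=corr_a.r.columns),
    )


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    statistic: str
    observed: float
    draws: np.ndarray
    probability: float
    reps: int
    seed: int
    scheme: str
    redraws: int = 0

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "observed": self.observed,
                "draws": np.asarray(self.draws).tolist(),
                "probability": self.probability, "reps": self.reps,
                "seed": self.seed, "scheme": self.scheme, "redraws": self.redraws}

    @classmethod
    def from_dict(cls, d: dict) -> "PermutationResult":
        kw = dict(d)
        kw["draws"] = np.asarray(kw["draws"], float)
        return cls(**kw)


# statistic factories -------------------------------------------------------

def _pearson(X: np.ndarray) -> np.ndarray:
    Z = X - X.mean(axis=0)
    sd = Z.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = Z / sd
        return (Z.T @ Z) / X.shape[0]


def stat_mean_delta_r(a: np.ndarray, b: np.ndarray) -> float:
    """Mean |Delta r| between the correlation matrices of two visit blocks."""
    Ra, Rb = _pearson(a), _pearson(b)
    iu = np.triu_indices(Ra.shape[0], 1)
    return float(np.abs(Rb[iu] - Ra[iu]).mean())


def _binary_graph(X: np.ndarray, fraction: float) -> nx.Graph:
    R = np.abs(_pearson(X))
    p = R.shape[0]
    iu = np.triu_indices(p, 1)
    vals = R[iu]
    k = _round_half_up(fraction * vals.size)
    order = np.lexsort((iu[1], iu[0], -vals))
    G = nx.Graph()
    G.add_nodes_from(range(p))
    G.add_edges_from((int(iu[0][t]), int(iu[1][t])) for t in order[:k])
    return G


def make_clustering_delta_stat(fraction: float = 0.25) -> Callable:
    def stat(a: np.ndarray, b: np.ndarray) -> float:
        return abs(nx.average_clustering(_binary_graph(b, fraction))
                   - nx.average_clustering(_binary_graph(a, fraction)))

    stat.__name__ = "mean_clustering_delta"
    return stat


def make_modularity_delta_stat(fraction: float = 0.25, louvain_reps: int = 3,
                               seed: int = 0) -> Callable:
    sub = np.random.SeedSequence(seed).generate_state(max(louvain_reps, 1))

    def q(G: nx.Graph) -> float:
        return float(np.mean([
            nx.community.modularity(
                G, nx.community.louvain_communities(G, seed=int(s % (2 ** 31))))
            for s in sub[:louvain_reps]]))

    def stat(a: np.ndarray, b: np.ndarray) -> float:
        return abs(q(_binary_graph(b, fraction)) - q(_binary_graph(a, fraction)))

    stat.__name__ = "modularity_delta"
    return stat


# schemes -------------------------------------------------------------------

def _resampling_probability(observed: float, draws: np.ndarray) -> float:
    return float((1 + np.sum(draws >= observed)) / (1 + draws.size))


def permute_within_subject(mat_pre: pd.DataFrame, mat_post: pd.DataFrame,
                           statistic: Callable[[np.ndarray, np.ndarray], float],
                           reps: int = 10_000, seed: int = 0,
                           max_redraws: int = 1000) -> PermutationResult:
    """Visit-swap null: per subject, exchange pre and post vectors with p=1/2.

    The statistic pipeline is recomputed for every draw; draws on which the
    statistic is undefined (e.g. a zero-variance measure) are redrawn and
    counted.  Subjects are aligned on the index intersection.
    """
    if reps < 100:
        import warnings

        warnings.warn(f"reps={reps} is very low for resampling inference")
    common = mat_pre.index.intersection(mat_post.index)
    A = mat_pre.loc[common].to_numpy(float)
    B = mat_post.loc[common].to_numpy(float)
    observed = statistic(A, B)
    rng = np.random.default_rng(seed)
    draws = np.empty(reps)
    redraws = 0
    i = 0
    while i < reps:
        sw = rng.random(A.shape[0]) < 0.5
        a = np.where(sw[:, None], B, A)
        b = np.where(sw[:, None], A, B)
        try:
            val = statistic(a, b)
        except (ValueError, FloatingPointError):
            val = np.nan
        if np.isnan(val):
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("statistic undefined on too many permutation draws")
            continue
        draws[i] = val
        i += 1
    if redraws:
        logger.info("permute_within_subject: %d draws redrawn", redraws)
    return PermutationResult(
        statistic=getattr(statistic, "__name__", "statistic"),
        observed=float(observed), draws=draws,
        probability=_resampling_probability(observed, draws),
        reps=reps, seed=seed, scheme="within_subject_visit", redraws=redraws)


def permute_between_group(pre: pd.DataFrame, post: pd.DataFrame,
                          labels: pd.Series,
                          statistic: Callable[[np.ndarray, np.ndarray], float],
                          reps: int = 10_000, seed: int = 0) -> PermutationResult:
    """Group-shuffle null for the between-arm difference of a change statistic.

    ``statistic`` is evaluated per arm on the (pre, post) blocks; the test
    statistic is |stat(arm1) - stat(arm2)|.  Labels are reshuffled over
    subjects preserving group sizes.
    """
    common = pre.index.intersection(post.index).intersection(labels.index)
    A = pre.loc[common].to_numpy(float)
    B = post.loc[common].to_numpy(float)
    lab = labels.loc[common].to_numpy()
    groups = np.unique(lab)
    if groups.size != 2:
        raise ValueError("between-group scheme needs exactly two groups")

    def contrast(assignment: np.ndarray) -> float:
        m1 = assignment == groups[0]
        return abs(statistic(A[m1], B[m1]) - statistic(A[~m1], B[~m1]))

    observed = contrast(lab)
    rng = np.random.default_rng(seed)
    draws = np.empty(reps)
    for i in range(reps):
        draws[i] = contrast(rng.permutation(lab))
    name = getattr(statistic, "__name__", "statistic")
    return PermutationResult(
        statistic=f"between_group[{name}]",
        observed=float(observed), draws=draws,
        probability=_resampling_probability(observed, draws),
        reps=reps, seed=seed, scheme="between_group")
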