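"""Signed co-occurrence network construction and topology statistics.

The network is an undirected, signed, weighted graph over community ASVs.
Topology statistics follow the conventions of desktop network tools for
microbial co-occurrence analysis:

* all path-based measures use unweighted hop counts, within connected
  components; negative edges are traversed like positive ones,
* betweenness is normalized by ``(N-1)(N-2)`` over ordered pairs with N the
  component size; closeness is (reachable nodes) / (sum of hop distances),
* radiality of v is ``sum_w (diam + 1 - d(v, w)) / (N - 1)`` over the other
  nodes w of v's component, with ``diam`` the component diameter,
* hubs are nodes simultaneously exceeding degree > 7, betweenness > 0.1 and
  closeness > 0.3 (all strict).

A deliberately simple permutation-based co-occurrence inference (CLR +
Spearman + per-pair permutation null + Benjamini-Hochberg) is provided for
self-contained runs; externally inferred networks can be supplied as edge
lists to reproduce the downstream statistics.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .fractions import mann_whitney_u

logger = logging.getLogger(__name__)

POSITIVE = "+"
NEGATIVE = "-"

CENTRALITY_MEASURES = (
    "closeness",
    "neighborhood_connectivity",
    "radiality",
    "avg_shortest_path_length",
    "nearest_hub_distance",
)


@dataclass(frozen=True)
class HubCriteria:
    """Joint strict thresholds a node must exceed to be called a hub."""

    degree_min: int = 7
    betweenness_min: float = 0.1
    closeness_min: float = 0.3

    def __post_init__(self) -> None:
        if self.degree_min <= 0 or self.betweenness_min <= 0 or self.closeness_min <= 0:
            raise ValueError("hub thresholds must be positive")


class InteractionNetwork:
    """Signed weighted undirected graph over ASV nodes.

    Node attributes: ``class_name`` (taxonomic class), ``mean_rel_abundance``,
    ``cultured`` (bool).  Edge attributes: ``sign`` in ``{+, -}`` and
    ``weight`` in ``(0, 1]``.  Self-loops and duplicate edges are rejected.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_node(
        self,
        node: str,
        class_name: Optional[str] = None,
        mean_rel_abundance: Optional[float] = None,
        cultured: Optional[bool] = None,
    ) -> None:
        self.graph.add_node(
            node,
            class_name=class_name,
            mean_rel_abundance=mean_rel_abundance,
            cultured=cultured,
        )

    def add_edge(self, a: str, b: str, sign: str, weight: float) -> None:
        if a == b:
            raise ValueError(f"self-loop on node {a!r}")
        if self.graph.has_edge(a, b):
            raise ValueError(f"duplicate edge {a!r} -- {b!r}")
        if sign not in (POSITIVE, NEGATIVE):
            raise ValueError(f"edge sign must be '+' or '-', got {sign!r}")
        if not 0.0 < weight <= 1.0:
            raise ValueError(f"edge weight must be in (0, 1], got {weight}")
        for n in (a, b):
            if n not in self.graph:
                self.add_node(n)
        self.graph.add_edge(a, b, sign=sign, weight=float(weight))

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, str, float]],
        node_attrs: Optional[pd.DataFrame] = None,
    ) -> "InteractionNetwork":
        """Build from ``(node_a, node_b, sign, weight)`` tuples.

        ``node_attrs``, if given, is indexed by ASV id with columns
        ``class_name``, ``mean_rel_abundance``, ``cultured``.
        """
        net = cls()
        if node_attrs is not None:
            for asv, row in node_attrs.iterrows():
                net.add_node(
                    str(asv),
                    class_name=row.get("class_name"),
                    mean_rel_abundance=row.get("mean_rel_abundance"),
                    cultured=(
                        None if pd.isna(row.get("cultured")) else bool(row.get("cultured"))
                    ),
                )
        for a, b, sign, weight in edges:
            net.add_edge(str(a), str(b), sign, float(weight))
        return net

    def set_cultured_flags(self, flags: Mapping[str, bool]) -> None:
        for node in self.graph.nodes:
            if node in flags:
                self.graph.nodes[node]["cultured"] = bool(flags[node])

    def edge_tuples(self) -> list[tuple[str, str, str, float]]:
        return [
            (a, b, d["sign"], d["weight"]) for a, b, d in self.graph.edges(data=True)
        ]


# ---------------------------------------------------------------------------
# centrality measures (unweighted, within components)
# ---------------------------------------------------------------------------


def _require_nonempty(network: InteractionNetwork) -> nx.Graph:
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    return network.graph


def degree(network: InteractionNetwork) -> dict[str, int]:
    g = _require_nonempty(network)
    return {n: int(d) for n, d in g.degree()}


def betweenness(network: InteractionNetwork) -> dict[str, float]:
    """Betweenness normalized within each connected component."""
    g = _require_nonempty(network)
    out: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        out.update(nx.betweenness_centrality(sub, normalized=True, weight=None))
    return {n: float(v) for n, v in out.items()}


def closeness(network: InteractionNetwork) -> dict[str, float]:
    """(reachable nodes) / (sum of hop distances); isolated nodes get 0."""
    g = _require_nonempty(network)
    return {
        n: float(v)
        for n, v in nx.closeness_centrality(g, wf_improved=False).items()
    }


def _component_distances(g: nx.Graph, comp: set) -> dict:
    sub = g.subgraph(comp)
    return dict(nx.all_pairs_shortest_path_length(sub))


def radiality(network: InteractionNetwork) -> dict[str, float]:
    """Component-diameter-referenced closeness variant; singletons get 0."""
    g = _require_nonempty(network)
    out: dict[str, float] = {}
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        dist = _component_distances(g, comp)
        diam = max(max(d.values()) for d in dist.values())
        n = len(comp)
        for v in comp:
            total = sum(diam + 1 - d for w, d in dist[v].items() if w != v)
            out[v] = total / (n - 1)
    return out


def neighborhood_connectivity(network: InteractionNetwork) -> dict[str, float]:
    """Mean degree of each node's neighbors; NaN for isolated nodes."""
    g = _require_nonempty(network)
    out = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        out[v] = float(np.mean([g.degree(w) for w in nbrs])) if nbrs else float("nan")
    return out


def avg_shortest_path_length(network: InteractionNetwork) -> dict[str, float]:
    """Mean hop distance from each node to its reachable nodes; NaN for singletons."""
    g = _require_nonempty(network)
    out: dict[str, float] = {}
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            out[next(iter(comp))] = float("nan")
            continue
        dist = _component_distances(g, comp)
        for v in comp:
            ds = [d for w, d in dist[v].items() if w != v]
            out[v] = float(np.mean(ds))
    return out


def classify_hubs(
    profiles: pd.DataFrame, criteria: HubCriteria | None = None
) -> set[str]:
    """Nodes simultaneously exceeding all three strict hub thresholds."""
    crit = criteria or HubCriteria()
    mask = (
        (profiles["degree"] > crit.degree_min)
        & (profiles["betweenness"] > crit.betweenness_min)
        & (profiles["closeness"] > crit.closeness_min)
    )
    return set(profiles.index[mask])


def nearest_hub_distance(
    network: InteractionNetwork, hubs: Iterable[str]
) -> dict[str, float]:
    """Multi-source BFS hop distance to the closest hub.

    Hubs get 0; nodes with no reachable hub (including every node when the
    hub set is empty) get NaN.
    """
    g = _require_nonempty(network)
    hubs = [h for h in hubs if h in g]
    dist = {n: float("nan") for n in g.nodes}
    queue = deque()
    for h in hubs:
        dist[h] = 0.0
        queue.append(h)
    while queue:
        v = queue.popleft()
        for w in g.neighbors(v):
            if np.isnan(dist[w]):
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def compute_profiles(
    network: InteractionNetwork, criteria: HubCriteria | None = None
) -> pd.DataFrame:
    """Full per-node topology profile.

    Columns: degree, betweenness, closeness, radiality,
    neighborhood_connectivity, avg_shortest_path_length, hub,
    nearest_hub_distance (NaN where undefined).
    """
    g = _require_nonempty(network)
    df = pd.DataFrame(
        {
            "degree": pd.Series(degree(network)),
            "betweenness": pd.Series(betweenness(network)),
            "closeness": pd.Series(closeness(network)),
            "radiality": pd.Series(radiality(network)),
            "neighborhood_connectivity": pd.Series(neighborhood_connectivity(network)),
            "avg_shortest_path_length": pd.Series(avg_shortest_path_length(network)),
        }
    ).loc[list(g.nodes)]
    hubs = classify_hubs(df, criteria)
    df["hub"] = df.index.isin(hubs)
    df["nearest_hub_distance"] = pd.Series(nearest_hub_distance(network, hubs))
    return df


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


def pearson_chi2(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a contingency table (no continuity correction
    by default)."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=correction)
    return float(chi2), float(p)


def edge_sharing_classification(
    network: InteractionNetwork, correction: bool = False
) -> tuple[pd.DataFrame, np.ndarray, float, float]:
    """Majority-partner labels and the cultured-vs-uncultured association test.

    For every connected node the fraction of incident edges whose opposite
    endpoint is cultured is computed; nodes with fraction > 0.5 are labeled
    ``majority_cultured``, < 0.5 ``majority_uncultured``, and exact ties are
    excluded.  Returns ``(per_node, table, chi2, p)`` where ``table`` is the
    2x2 contingency of node fraction (cultured/uncultured) x majority label.
    """
    g = _require_nonempty(network)
    rows = []
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        if not nbrs:
            continue
        flag = g.nodes[v].get("cultured")
        if flag is None:
            raise ValueError(f"node {v!r} is missing the cultured flag")
        for w in nbrs:
            if g.nodes[w].get("cultured") is None:
                raise ValueError(f"node {w!r} is missing the cultured flag")
        frac = np.mean([bool(g.nodes[w]["cultured"]) for w in nbrs])
        if frac > 0.5:
            label = "majority_cultured"
        elif frac < 0.5:
            label = "majority_uncultured"
        else:
            label = "tie"
        rows.append(
            {
                "node": v,
                "cultured": bool(flag),
                "cultured_partner_fraction": float(frac),
                "majority": label,
            }
        )
    per_node = pd.DataFrame(rows).set_index("node")
    kept = per_node[per_node["majority"] != "tie"]
    table = np.array(
        [
            [
                ((kept["cultured"] == c) & (kept["majority"] == m)).sum()
                for m in ("majority_cultured", "majority_uncultured")
            ]
            for c in (True, False)
        ],
        dtype=float,
    )
    # a zero margin makes the test undefined (no variation to compare)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return per_node, table, float("nan"), float("nan")
    chi2, p = pearson_chi2(table, correction=correction)
    return per_node, table, chi2, p


def centrality_group_test(
    profiles: pd.DataFrame,
    cultured: Mapping[str, bool],
    include_hubs_in_distance: bool = False,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney per topology measure, cultured vs uncultured.

    Hubs are excluded from the nearest-hub-distance comparison by default
    (they sit at distance 0 by definition); NaN values (unreachable,
    undefined) are always excluded.  No multiplicity adjustment is applied.
    """
    flags = pd.Series({n: bool(cultured[n]) for n in profiles.index})
    if flags.all() or (~flags).all():
        raise ValueError("both cultured and uncultured groups must be non-empty")
    rows = []
    for measure in CENTRALITY_MEASURES:
        vals = profiles[measure]
        if measure == "nearest_hub_distance" and not include_hubs_in_distance:
            vals = vals[~profiles["hub"]]
        vals = vals.dropna()
        x = vals[flags.reindex(vals.index)].to_numpy()
        y = vals[~flags.reindex(vals.index)].to_numpy()
        if x.size == 0 or y.size == 0:
            rows.append({"measure": measure, "U": np.nan, "p": np.nan,
                         "n_cultured": x.size, "n_uncultured": y.size})
            continue
        u, p = mann_whitney_u(x, y)
        rows.append({"measure": measure, "U": u, "p": p,
                     "n_cultured": x.size, "n_uncultured": y.size})
    return pd.DataFrame(rows).set_index("measure")


def centrality_pca(
    profiles: pd.DataFrame, features: Optional[Sequence[str]] = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of z-scored topology measures (plus abundance if present).

    Eigendecomposition of the correlation matrix of the selected feature
    columns; rows with any NaN feature are dropped, zero-variance features
    are dropped with a warning.  Components are ordered by decreasing
    variance and signed so that the largest-magnitude loading is positive.

    Returns ``(loadings, scores, explained_variance_ratio)``.
    """
    if features is None:
        features = [
            c
            for c in (
                "degree",
                "betweenness",
                "closeness",
                "radiality",
                "neighborhood_connectivity",
                "avg_shortest_path_length",
                "mean_rel_abundance",
            )
            if c in profiles.columns
        ]
    X = profiles[list(features)].dropna()
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 3 complete nodes and 2 features")
    sd = X.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance features: {dead}", stacklevel=2)
        logger.warning("PCA dropped zero-variance features: %s", dead)
        X = X.drop(columns=dead)
        if X.shape[1] < 2:
            raise ValueError("fewer than 2 informative features left for PCA")
    Z = (X - X.mean()) / X.std(ddof=1)
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    comp_names = [f"PC{i + 1}" for i in range(evecs.shape[1])]
    loadings = pd.DataFrame(evecs, index=X.columns, columns=comp_names)
    scores = pd.DataFrame(Z.to_numpy() @ evecs, index=X.index, columns=comp_names)
    ratio = evals / evals.sum()
    return loadings, scores, ratio


# ---------------------------------------------------------------------------
# simple co-occurrence inference (stand-in, not a causal-inference method)
# ---------------------------------------------------------------------------


def clr_transform(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio per sample; counts is ASVs x samples."""
    logc = np.log(counts + pseudocount)
    return logc - logc.mean(axis=0, keepdims=True)


def infer_network(
    table: pd.DataFrame,
    min_obs: int = 20,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> InteractionNetwork:
    """Permutation-tested CLR/Spearman co-occurrence network.

    A deliberately simple inference: ASVs present in at least ``min_obs``
    samples are CLR-transformed (pseudocount 1), all pairwise Spearman rank
    correlations are tested against a per-pair permutation null (independent
    sample-label shuffles, ``n_perm`` draws each) and retained after
    Benjamini-Hochberg control at ``alpha``.  Edge sign is the correlation
    sign, weight its absolute value.  This is a transparent baseline, not a
    reimplementation of conditional-independence methods such as FlashWeave.
    """
    n_samples = table.shape[1]
    if min_obs > n_samples:
        raise ValueError(f"min_obs={min_obs} exceeds n_samples={n_samples}")
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    present = (table.to_numpy() > 0).sum(axis=1)
    kept = table.index[present >= min_obs]
    logger.info("network inference: %d/%d ASVs pass min_obs=%d",
                len(kept), table.shape[0], min_obs)
    net = InteractionNetwork()
    for asv in kept:
        net.add_node(str(asv))
    if len(kept) < 2:
        return net

    clr = clr_transform(table.loc[kept].to_numpy(dtype=float))
    ranks = stats.rankdata(clr, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    rng = np.random.default_rng(seed)

    pairs = []
    pvals = []
    rhos = []
    ids = list(map(str, kept))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            xi, yj = ranks[i], ranks[j]
            denom = norms[i] * norms[j]
            if denom == 0:
                continue
            rho = float(xi @ yj / denom)
            # permute one margin; dot with the fixed other margin
            perms = np.argsort(rng.random((n_perm, n_samples)), axis=1)
            null = (yj[perms] @ xi) / denom
            p = (1 + np.sum(np.abs(null) >= abs(rho) - 1e-12)) / (n_perm + 1)
            pairs.append((ids[i], ids[j]))
            rhos.append(rho)
            pvals.append(p)

    if not pairs:
        return net
    reject = _benjamini_hochberg(np.array(pvals), alpha)
    for (a, b), rho, keep in zip(pairs, rhos, reject):
        if keep and abs(rho) > 0:
            net.add_edge(a, b, POSITIVE if rho > 0 else NEGATIVE, min(abs(rho), 1.0))
    logger.info("network inference: %d significant edges of %d pairs tested",
                net.n_edges, len(pairs))
    return net


def _benjamini_hochberg(pvals: np.ndarray, alpha: float) -> np.ndarray:
    m = pvals.size
    order = np.argsort(pvals)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = pvals[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.nonzero(passed)[0].max()
        reject[order[: kmax + 1]] = True
    return reject
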