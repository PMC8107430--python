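"""Protein-interaction network construction and permutation interconnectivity tests.

The network is an undirected, confidence-filtered graph over gene symbols
read from a STRING-style edge list (node, node, combined score 0–1000,
score/1000 being the confidence fraction; edges above 0.4 are kept by
default).

Interconnectivity of a prioritized gene set is measured by two statistics —
the number of set members with at least one interaction inside the set, and
the number of within-set interactions — and, between two disjoint sets, by
their cross-set analogues. Significance comes from a permutation null:
random sets of the same size are drawn uniformly without replacement from
the node universe, the statistic is recomputed per replicate, and the
empirical p-value is (r + 1) / (N + 1) where r counts replicates with a
null statistic at or above the observed one (ties count toward r). When no
replicate reaches the observed value the p-value is reported as a floor,
"p < 1/N" — at the default N = 1,000,000, "p < 1.0e-06".
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


class Statistic(str, enum.Enum):
    """The four interconnectivity statistics."""

    WITHIN_EDGES = "within_edges"
    WITHIN_CONNECTED = "within_connected"
    CROSS_EDGES = "cross_edges"
    CROSS_CONNECTED = "cross_connected"


_WITHIN = {Statistic.WITHIN_EDGES, Statistic.WITHIN_CONNECTED}
_CROSS = {Statistic.CROSS_EDGES, Statistic.CROSS_CONNECTED}


class InteractionNetwork:
    """Undirected confidence-weighted interaction graph over gene symbols.

    Thin wrapper over :class:`networkx.Graph` guaranteeing no self-loops,
    one entry per unordered pair, and a confidence fraction in (0, 1] per
    edge, with a cached adjacency matrix for the permutation engine.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self._adjacency: Optional[np.ndarray] = None
        self._node_index: Optional[Dict[str, int]] = None

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_edge(self, a: str, b: str, confidence: float) -> bool:
        """Add an undirected edge; self-loops are rejected, duplicates keep
        the higher confidence. Returns True if the edge was new."""
        if a == b:
            raise ValueError(f"self-loop {a!r}–{b!r} not allowed")
        if not 0.0 < confidence <= 1.0:
            raise ValueError(f"confidence must be in (0,1], got {confidence}")
        new = not self.graph.has_edge(a, b)
        if new:
            self.graph.add_edge(a, b, confidence=confidence)
        else:
            prior = self.graph[a][b]["confidence"]
            self.graph[a][b]["confidence"] = max(prior, confidence)
        self._adjacency = None
        return new

    def add_node(self, a: str) -> None:
        self.graph.add_node(a)
        self._adjacency = None

    def confidence(self, a: str, b: str) -> float:
        return self.graph[a][b]["confidence"]

    def adjacency(self) -> Tuple[np.ndarray, Dict[str, int]]:
        """Boolean adjacency matrix over a deterministic node ordering."""
        if self._adjacency is None:
            order = sorted(self.graph.nodes)
            index = {name: i for i, name in enumerate(order)}
            adj = np.zeros((len(order), len(order)), dtype=bool)
            for a, b in self.graph.edges:
                i, j = index[a], index[b]
                adj[i, j] = adj[j, i] = True
            self._adjacency = adj
            self._node_index = index
        return self._adjacency, self._node_index


class EdgeListParseError(ValueError):
    """A row of the STRING-style edge list could not be parsed."""

    def __init__(self, message: str, row: int):
        super().__init__(f"{message} (row {row})")
        self.row = row


def load_edge_list(
    path: Union[str, Path], min_confidence: float = 0.4
) -> InteractionNetwork:
    """Load a STRING-dialect edge list, keeping edges strictly above ``min_confidence``.

    Rows are ``nodeA<TAB>nodeB<TAB>combined_score`` with the score an
    integer 0–1000 (score/1000 = confidence). A header row whose score cell
    is non-numeric is tolerated; ``#`` lines are ignored. Self-loops and
    duplicate pairs are dropped with a logged count.
    """
    net = InteractionNetwork()
    n_dropped_conf = n_self = n_dup = 0
    with open(path, "r", encoding="utf-8") as fh:
        for row, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise EdgeListParseError(
                    f"expected 3 tab-separated fields, got {len(cells)}", row
                )
            a, b, raw = cells[0].strip(), cells[1].strip(), cells[2].strip()
            try:
                score = int(raw)
            except ValueError:
                if row == 1:  # tolerate a header line
                    continue
                raise EdgeListParseError(
                    f"combined score must be an integer, got {raw!r}", row
                ) from None
            if not 0 <= score <= 1000:
                raise EdgeListParseError(
                    f"combined score must be in 0–1000, got {score}", row
                )
            confidence = score / 1000.0
            if confidence <= min_confidence:
                n_dropped_conf += 1
                continue
            if a == b:
                n_self += 1
                continue
            if not net.add_edge(a, b, confidence):
                n_dup += 1
    logger.info(
        "edge list %s: kept %d edges over %d nodes; dropped %d below "
        "confidence %.3g, %d self-loops, %d duplicates",
        path, net.n_edges, net.n_nodes, n_dropped_conf, min_confidence,
        n_self, n_dup,
    )
    if n_self:
        logger.warning("dropped %d self-loop row(s) in %s", n_self, path)
    return net


def within_set_stats(
    net: InteractionNetwork, genes: Iterable[str]
) -> Tuple[int, int]:
    """Within-set interconnectivity of a gene set.

    Returns ``(n_connected, n_edges)``: the number of set members with at
    least one interaction to another member, and the number of unordered
    member–member pairs with an edge. Genes absent from the network
    contribute nothing.
    """
    members = set(genes) & net.nodes
    n_edges = 0
    connected: Set[str] = set()
    for gene in members:
        for neighbor in net.graph[gene]:
            if neighbor in members:
                connected.add(gene)
                if gene < neighbor:
                    n_edges += 1
    return len(connected), n_edges


def cross_set_stats(
    net: InteractionNetwork, set_a: Iterable[str], set_b: Iterable[str]
) -> Tuple[int, int]:
    """Cross-set connectivity from set B into set A.

    Returns ``(n_b_connected, n_edges)``: members of B with at least one
    interaction into A, and the number of A–B pairs with an edge. The sets
    must be disjoint.
    """
    a, b = set(set_a), set(set_b)
    overlap = a & b
    if overlap:
        raise ValueError(f"sets must be disjoint; both contain {sorted(overlap)}")
    a &= net.nodes
    b &= net.nodes
    n_edges = 0
    connected: Set[str] = set()
    for gene in b:
        for neighbor in net.graph[gene]:
            if neighbor in a:
                connected.add(gene)
                n_edges += 1
    return len(connected), n_edges


class CrossMode(str, enum.Enum):
    """Null model for cross-set statistics: resample both sets, or hold A fixed."""

    RESAMPLE_BOTH = "resample_both"
    FIX_A_RESAMPLE_B = "fix_a_resample_b"


@dataclass(frozen=True)
class PermutationConfig:
    """Replicate count, seed and sampling frame of the permutation null."""

    n_permutations: int = 1_000_000
    seed: int = 0
    universe: Optional[Sequence[str]] = None  # defaults to all network nodes
    cross_mode: CrossMode = CrossMode.RESAMPLE_BOTH

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, null summary, and add-one empirical p-value."""

    statistic_name: str
    observed: int
    n_permutations: int
    n_null_geq: int
    p_empirical: float
    p_is_floor: bool
    seed: int
    null_mean: float
    null_max: int

    def report(self) -> str:
        """Textual p-value: ``p < 1/N`` when no replicate reached the observed."""
        if self.p_is_floor:
            return f"p < {1.0 / self.n_permutations:.1e}"
        return f"p = {self.p_empirical:.3g}"

    def to_dict(self) -> Dict[str, object]:
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "n_permutations": self.n_permutations,
            "n_null_geq": self.n_null_geq,
            "p_empirical": self.p_empirical,
            "p_is_floor": self.p_is_floor,
            "p_report": self.report(),
            "seed": self.seed,
            "null_mean": self.null_mean,
            "null_max": self.null_max,
        }


def _within_counts(adj: np.ndarray, idx: np.ndarray) -> Tuple[int, int]:
    sub = adj[np.ix_(idx, idx)]
    deg = sub.sum(axis=0)
    return int(deg.sum()) // 2, int((deg > 0).sum())


def _cross_counts(adj: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> Tuple[int, int]:
    block = adj[np.ix_(ia, ib)]
    to_a = block.sum(axis=0)
    return int(to_a.sum()), int((to_a > 0).sum())


def sample_null_statistics(
    net: InteractionNetwork,
    statistic: Statistic,
    set_sizes: Tuple[int, ...],
    cfg: PermutationConfig,
    fixed_a: Optional[Iterable[str]] = None,
) -> np.ndarray:
    """Draw the permutation null distribution of one statistic.

    Each replicate draws node set(s) of the given size(s) uniformly without
    replacement from the universe. For cross statistics under
    ``RESAMPLE_BOTH`` both sets are drawn jointly (hence disjoint); under
    ``FIX_A_RESAMPLE_B`` the observed A (``fixed_a``) is held and B is drawn
    from the remaining universe.
    """
    statistic = Statistic(statistic)
    adj, index = net.adjacency()
    if cfg.universe is None:
        universe = np.arange(len(index))
    else:
        universe = np.array([index[g] for g in cfg.universe if g in index])
    n_universe = len(universe)
    if sum(set_sizes) > n_universe and statistic in _CROSS and cfg.cross_mode is CrossMode.RESAMPLE_BOTH:
        raise ValueError(
            f"combined set sizes {set_sizes} exceed universe size {n_universe}"
        )
    if max(set_sizes) > n_universe:
        raise ValueError(f"set sizes {set_sizes} exceed universe size {n_universe}")

    rng = np.random.default_rng(cfg.seed)
    null = np.empty(cfg.n_permutations, dtype=np.int64)

    if statistic in _WITHIN:
        (k,) = set_sizes
        pick = 0 if statistic is Statistic.WITHIN_EDGES else 1
        for i in range(cfg.n_permutations):
            idx = universe[rng.choice(n_universe, size=k, replace=False)]
            null[i] = _within_counts(adj, idx)[pick]
        return null

    k_a, k_b = set_sizes
    pick = 0 if statistic is Statistic.CROSS_EDGES else 1
    if cfg.cross_mode is CrossMode.FIX_A_RESAMPLE_B:
        if fixed_a is None:
            raise ValueError("FIX_A_RESAMPLE_B requires the observed set A")
        ia = np.array(sorted(index[g] for g in fixed_a if g in index))
        pool = np.setdiff1d(universe, ia)
        for i in range(cfg.n_permutations):
            ib = pool[rng.choice(len(pool), size=k_b, replace=False)]
            null[i] = _cross_counts(adj, ia, ib)[pick]
    else:
        for i in range(cfg.n_permutations):
            both = universe[rng.choice(n_universe, size=k_a + k_b, replace=False)]
            null[i] = _cross_counts(adj, both[:k_a], both[k_a:])[pick]
    return null


def permutation_test(
    net: InteractionNetwork,
    observed_sets: Union[Iterable[str], Tuple[Iterable[str], Iterable[str]]],
    statistic: Union[Statistic, str],
    cfg: PermutationConfig = PermutationConfig(),
) -> PermutationResult:
    """Permutation test of one interconnectivity statistic.

    ``observed_sets`` is one gene set for the within-set statistics or a
    pair ``(set_a, set_b)`` of disjoint sets for the cross statistics.
    Reproducible: same seed, same inputs, same result.
    """
    statistic = Statistic(statistic)
    if statistic in _WITHIN:
        if isinstance(observed_sets, tuple) and len(observed_sets) == 2 \
                and not isinstance(observed_sets[0], str):
            raise ValueError(f"{statistic.value} takes a single gene set")
        genes = set(observed_sets)
        members = genes & net.nodes
        n_connected, n_edges = within_set_stats(net, genes)
        observed = n_edges if statistic is Statistic.WITHIN_EDGES else n_connected
        set_sizes: Tuple[int, ...] = (len(members),)
        fixed_a = None
    else:
        if not (isinstance(observed_sets, tuple) and len(observed_sets) == 2):
            raise ValueError(f"{statistic.value} takes a pair (set_a, set_b)")
        set_a, set_b = (set(s) for s in observed_sets)
        n_b_connected, n_edges = cross_set_stats(net, set_a, set_b)
        observed = n_edges if statistic is Statistic.CROSS_EDGES else n_b_connected
        set_sizes = (len(set_a & net.nodes), len(set_b & net.nodes))
        fixed_a = set_a

    null = sample_null_statistics(net, statistic, set_sizes, cfg, fixed_a=fixed_a)
    return summarize_null(statistic, observed, null, cfg.seed)


def within_permutation_pair(
    net: InteractionNetwork,
    genes: Iterable[str],
    cfg: PermutationConfig = PermutationConfig(),
) -> Tuple[PermutationResult, PermutationResult]:
    """Test both within-set statistics on one shared set of replicates.

    Each replicate's random set is scored for the edge count and the
    connected-member count simultaneously, so the two results are perfectly
    coupled (and the loop runs once). Returns
    ``(edge_count_result, connected_count_result)``.
    """
    members = set(genes) & net.nodes
    n_connected, n_edges = within_set_stats(net, members)
    adj, index = net.adjacency()
    if cfg.universe is None:
        universe = np.arange(len(index))
    else:
        universe = np.array([index[g] for g in cfg.universe if g in index])
    k = len(members)
    if k > len(universe):
        raise ValueError(f"set size {k} exceeds universe size {len(universe)}")
    rng = np.random.default_rng(cfg.seed)
    null_edges = np.empty(cfg.n_permutations, dtype=np.int64)
    null_conn = np.empty(cfg.n_permutations, dtype=np.int64)
    n_universe = len(universe)
    for i in range(cfg.n_permutations):
        idx = universe[rng.choice(n_universe, size=k, replace=False)]
        null_edges[i], null_conn[i] = _within_counts(adj, idx)
    return (
        summarize_null(Statistic.WITHIN_EDGES, n_edges, null_edges, cfg.seed),
        summarize_null(Statistic.WITHIN_CONNECTED, n_connected, null_conn, cfg.seed),
    )


def summarize_null(
    statistic: Union[Statistic, str],
    observed: int,
    null: np.ndarray,
    seed: int,
) -> PermutationResult:
    """Fold a sampled null into a :class:`PermutationResult` (add-one estimator)."""
    n = int(null.size)
    r = int((null >= observed).sum())
    return PermutationResult(
        statistic_name=Statistic(statistic).value,
        observed=int(observed),
        n_permutations=n,
        n_null_geq=r,
        p_empirical=(r + 1) / (n + 1),
        p_is_floor=(r == 0),
        seed=seed,
        null_mean=float(null.mean()),
        null_max=int(null.max()),
    )


def exact_within_pvalue(
    net: InteractionNetwork,
    set_size: int,
    observed: int,
    statistic: Statistic,
    universe: Optional[Sequence[str]] = None,
) -> float:
    """Exact tail probability P(statistic >= observed) by exhaustive enumeration.

    Enumerates every size-``set_size`` subset of the universe; tractable
    only for small universes (used as the oracle in tests).
    """
    statistic = Statistic(statistic)
    if statistic not in _WITHIN:
        raise ValueError("exact enumeration implemented for within-set statistics")
    adj, index = net.adjacency()
    pool = (
        list(range(len(index)))
        if universe is None
        else [index[g] for g in universe if g in index]
    )
    pick = 0 if statistic is Statistic.WITHIN_EDGES else 1
    total = math.comb(len(pool), set_size)
    hits = 0
    for combo in itertools.combinations(pool, set_size):
        if _within_counts(adj, np.array(combo))[pick] >= observed:
            hits += 1
    return hits / total
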