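"""Network-based survival marker discovery (the netSurvival method).

The method turns a normalized expression cohort into patient-sharing graphs
and reads prognostic markers off survival-associated random-walk paths:

1. per gene, take the samples with the top 10% highest absolute normalized
   expression (the *extreme set*) and group them by one-dimensional
   single-linkage clustering; each retained cluster is a candidate node;
2. per sampling iteration, pick one cluster per gene uniformly at random and
   connect two nodes when their members share at least ``min_overlap``
   patients (edge weight = number of shared patients);
3. run weight-proportional self-avoiding random walks on each sampled graph;
   each walk is a path whose pooled patients (union over its nodes) form a
   candidate risk group;
4. test every distinct path with a two-group log-rank test (path patients vs
   all other patients) and call a path significant at ``alpha``;
5. per gene, build the 2x2 table of significant/non-significant paths
   containing/not containing the gene and test enrichment with a one-sided
   Fisher exact test, BH-corrected across genes;
6. repeat per cross-validation fold and keep genes selected in at least
   ``min_folds`` folds (the consensus marker set).
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import benjamini_hochberg, logrank_two_group_batch
from .cohort import Cohort
from .errors import ConfigurationError, ValidationError
from .evaluate import logrank_test
from .preprocess import FoldSplit, log_z_normalize, logrank_screen, make_patient_folds

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class NetSurvivalConfig:
    """Tunable parameters of the network stage (defaults documented in docs/)."""

    screen_top_n: int = 1000          # genes kept by the univariate log-rank screen
    extreme_fraction: float = 0.10    # fraction of samples in a gene's extreme set
    min_cluster_size: int = 3         # discard clusters smaller than this
    max_clusters: int = 4             # cap on clusters per gene
    n_graphs: int = 1000              # graph sampling iterations per fold
    walks_per_graph: int = 100
    max_len: int = 10                 # maximum walk length in nodes
    min_overlap: int = 1              # shared patients required for an edge
    alpha: float = 0.05               # path log-rank significance level
    min_group: int = 10               # path patient-group size bounds
    q_max: float = 0.05               # BH threshold for marker selection
    k_folds: int = 5
    min_folds: int = 3                # folds required for consensus


# ---------------------------------------------------------------------------
# nodes


@dataclass
class ClusterNode:
    """One expression cluster of a gene's extreme samples."""

    gene_id: str
    member_samples: tuple[str, ...]
    centroid: float


@dataclass
class SampledGraph:
    """One graph-sampling iteration: a chosen node per gene plus overlap edges."""

    nodes: list[ClusterNode]
    weights: np.ndarray  # symmetric patient-overlap counts, zero diagonal
    min_overlap: int = 1
    iteration: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> np.ndarray:
        return self.weights >= self.min_overlap


@dataclass
class WalkPath:
    """A self-avoiding walk with its pooled patient group and log-rank call."""

    node_indices: tuple[int, ...]
    genes: tuple[str, ...]
    patients: frozenset
    statistic: float = np.nan
    p: float = np.nan
    significant: bool = False
    testable: bool = True


def extreme_set(values: pd.Series, fraction: float = 0.10) -> list[str]:
    """Sample IDs of the ceil(fraction * n) largest |normalized expression|.

    Ties are broken by sample ID so the set is deterministic; an all-zero
    gene degenerates to the first samples by ID (logged).
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    n = len(values)
    m = int(np.ceil(fraction * n))
    if np.ptp(values.to_numpy(float)) == 0:
        logger.debug("extreme_set: constant gene; tie-broken by sample ID")
    ranked = sorted(values.index, key=lambda s: (-abs(float(values[s])), s))
    return ranked[:m]


def _split_sorted_1d(sorted_values: np.ndarray, n_clusters: int) -> list[np.ndarray]:
    """Partition sorted 1-D points into n_clusters at the largest gaps.

    Equivalent to cutting the single-linkage dendrogram of 1-D points into
    ``n_clusters`` groups: splits fall at the n_clusters - 1 largest adjacent
    gaps (ties broken by position).
    """
    gaps = np.diff(sorted_values)
    if n_clusters <= 1 or gaps.size == 0:
        return [np.arange(sorted_values.size)]
    split_at = np.sort(np.argsort(-gaps, kind="stable")[: n_clusters - 1])
    return np.split(np.arange(sorted_values.size), split_at + 1)


def cluster_extreme_samples(
    values: pd.Series,
    min_cluster_size: int = 3,
    max_clusters: int = 4,
) -> list[ClusterNode]:
    """Cluster a gene's extreme-set values on the line; return retained nodes.

    Single-linkage agglomeration on 1-D values; the tree is cut where the
    sorted merge distances jump the most (capped at ``max_clusters``
    clusters), and clusters smaller than ``min_cluster_size`` are discarded.
    May return an empty list, in which case the gene is absent from sampled
    graphs.
    """
    if len(values) < min_cluster_size:
        return []
    gene = values.name if values.name is not None else ""
    order = np.lexsort((values.index.to_numpy(), values.to_numpy(float)))
    sorted_vals = values.to_numpy(float)[order]
    sorted_ids = values.index.to_numpy()[order]
    # single-linkage merge heights on the line are the adjacent gaps, sorted
    heights = np.sort(np.diff(sorted_vals))
    if heights.size == 0 or heights[-1] == 0:
        n_clusters = 1  # all values identical (or a single point)
    else:
        jumps = np.diff(heights)
        if jumps.size == 0 or jumps.max() == 0:
            # a single merge, or equally spaced merges: no gap structure
            n_clusters = 1
        else:
            # cut below the merges that sit above the largest height jump
            i_star = int(np.argmax(jumps))
            n_clusters = heights.size - i_star
        n_clusters = min(n_clusters, max_clusters)
    nodes = []
    for chunk in _split_sorted_1d(sorted_vals, n_clusters):
        if chunk.size < min_cluster_size:
            continue
        nodes.append(
            ClusterNode(
                gene_id=str(gene),
                member_samples=tuple(sorted_ids[chunk]),
                centroid=float(sorted_vals[chunk].mean()),
            )
        )
    return nodes


# ---------------------------------------------------------------------------
# graph sampling and random walks


def sample_interaction_graph(
    nodes_by_gene: dict[str, list[ClusterNode]],
    clinical: pd.DataFrame,
    rng: np.random.Generator,
    min_overlap: int = 1,
    iteration: int = 0,
) -> SampledGraph:
    """Draw one cluster per gene and connect nodes sharing enough patients."""
    genes = [g for g in nodes_by_gene if nodes_by_gene[g]]
    if len(genes) < 2:
        raise ValidationError("graph sampling needs >= 2 genes with clusters")
    sample_to_patient = dict(zip(clinical["sample_id"], clinical["patient_id"]))
    patients = sorted(clinical["patient_id"].unique())
    pat_index = {p: i for i, p in enumerate(patients)}
    chosen, masks = [], []
    for g in genes:
        node = nodes_by_gene[g][int(rng.integers(len(nodes_by_gene[g])))]
        mask = np.zeros(len(patients), dtype=bool)
        for s in node.member_samples:
            mask[pat_index[sample_to_patient[s]]] = True
        chosen.append(node)
        masks.append(mask)
    member_matrix = np.array(masks, dtype=np.float64)
    weights = member_matrix @ member_matrix.T
    np.fill_diagonal(weights, 0.0)
    return SampledGraph(
        nodes=chosen, weights=weights, min_overlap=min_overlap, iteration=iteration
    )


def _walk_once(
    neighbors: list[np.ndarray],
    nbr_weights: list[np.ndarray],
    start: int,
    max_len: int,
    n_nodes: int,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    visited = np.zeros(n_nodes, dtype=bool)
    visited[start] = True
    path = [start]
    current = start
    while len(path) < max_len:
        nbr = neighbors[current]
        if nbr.size == 0:
            break
        unvisited = ~visited[nbr]
        if not unvisited.any():
            break
        cand = nbr[unvisited]
        w = nbr_weights[current][unvisited]
        cw = np.cumsum(w)
        # rng.random() < 1 but the product can round up to cw[-1]; clamp
        j = min(np.searchsorted(cw, rng.random() * cw[-1], side="right"), cand.size - 1)
        nxt = int(cand[j])
        visited[nxt] = True
        path.append(nxt)
        current = nxt
    return tuple(path)


def random_walk_paths(
    graph: SampledGraph,
    walks_per_graph: int,
    max_len: int,
    rng: np.random.Generator,
) -> list[tuple[int, ...]]:
    """Weight-proportional self-avoiding walks; keeps walks of length >= 2.

    Start nodes are uniform over non-isolated nodes; each step moves to an
    unvisited neighbor with probability proportional to the edge weight and
    the walk stops when stuck or at ``max_len`` nodes.  Returns node-index
    tuples (annotate with :func:`path_logrank_test` downstream).
    """
    adj = graph.adjacency()
    neighbors = [np.flatnonzero(adj[i]) for i in range(graph.n_nodes)]
    nbr_weights = [graph.weights[i, neighbors[i]] for i in range(graph.n_nodes)]
    non_isolated = np.flatnonzero([n.size > 0 for n in neighbors])
    if non_isolated.size == 0:
        logger.debug("random_walk_paths: edgeless graph, no walks")
        return []
    starts = non_isolated[rng.integers(non_isolated.size, size=walks_per_graph)]
    paths = []
    for s in starts:
        path = _walk_once(neighbors, nbr_weights, int(s), max_len, graph.n_nodes, rng)
        if len(path) >= 2:
            paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# path testing and enrichment


def path_logrank_test(
    path: WalkPath,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    min_group: int = 10,
) -> WalkPath:
    """Two-group log-rank of the path's pooled patients vs all other patients.

    Paths whose pooled group is smaller than ``min_group`` or larger than
    N - ``min_group`` are marked untestable and excluded from the Fisher
    contingency margins.
    """
    patient_tbl = (
        clinical.groupby("patient_id", sort=True).first().reset_index()
    )
    membership = patient_tbl["patient_id"].isin(path.patients).to_numpy()
    size = int(membership.sum())
    n = membership.size
    if size < min_group or size > n - min_group:
        return WalkPath(
            node_indices=path.node_indices,
            genes=path.genes,
            patients=path.patients,
            testable=False,
        )
    stat, p = logrank_test(
        membership.astype(int),
        patient_tbl["time"].to_numpy(float),
        patient_tbl["event"].to_numpy(int),
    )
    return WalkPath(
        node_indices=path.node_indices,
        genes=path.genes,
        patients=path.patients,
        statistic=stat,
        p=p,
        significant=bool(p < alpha),
        testable=True,
    )


def fisher_enrichment_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the 2x2 table [[a,b],[c,d]].

    Computed as the hypergeometric upper tail P(X >= a) with population
    a+b+c+d, a+c draws marked (paths containing the gene) and a+b successes
    (significant paths); identical to
    ``scipy.stats.fisher_exact(..., alternative="greater")``.
    """
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def fisher_marker_enrichment(
    paths: list[WalkPath],
    genes,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Per-gene enrichment of significant paths; BH-corrected selection.

    For gene g: a = significant paths containing g, b = significant without,
    c = non-significant with, d = non-significant without (untestable paths
    excluded entirely).  Genes absent from every path get p = 1.
    """
    genes = list(genes)
    testable = [p for p in paths if p.testable]
    if not testable:
        raise ValidationError("no testable paths for marker enrichment")
    n_sig = sum(p.significant for p in testable)
    n_nonsig = len(testable) - n_sig
    gene_pos = {g: i for i, g in enumerate(genes)}
    a = np.zeros(len(genes), dtype=int)
    with_gene = np.zeros(len(genes), dtype=int)
    for p in testable:
        for g in set(p.genes):
            i = gene_pos.get(g)
            if i is None:
                continue
            with_gene[i] += 1
            if p.significant:
                a[i] += 1
    c = with_gene - a
    b = n_sig - a
    d = n_nonsig - c
    pvals = stats.hypergeom.sf(a - 1, n_sig + n_nonsig, with_gene, n_sig)
    pvals = np.where(with_gene == 0, 1.0, pvals)
    q = benjamini_hochberg(pvals)
    return pd.DataFrame(
        {
            "gene": genes,
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "p": pvals,
            "q": q,
            "selected": q < q_max,
        }
    )


def consensus_markers(per_fold: list[pd.DataFrame], min_folds: int = 3) -> pd.DataFrame:
    """Genes selected in at least ``min_folds`` folds.

    Sorted by number of folds selected (descending), then mean q across the
    folds where the gene was tested, then gene ID.
    """
    if len(per_fold) < min_folds:
        raise ConfigurationError("fewer fold results than min_folds")
    stacked = pd.concat(
        [t.assign(fold=i + 1) for i, t in enumerate(per_fold)], ignore_index=True
    )
    summary = (
        stacked.groupby("gene")
        .agg(folds_selected=("selected", "sum"), mean_q=("q", "mean"))
        .reset_index()
    )
    summary["consensus"] = summary["folds_selected"] >= min_folds
    return summary.sort_values(
        ["folds_selected", "mean_q", "gene"], ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# the per-fold engine (vectorized variant of the operations above)


def _fold_markers(
    train: Cohort,
    config: NetSurvivalConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Run screen -> clusters -> sampled graphs -> walks -> Fisher on one fold."""
    normalized = log_z_normalize(train.expression)
    screen = logrank_screen(
        Cohort(expression=normalized, clinical=train.clinical), config.screen_top_n
    )
    kept_genes = screen.loc[screen["selected"], "gene"].tolist()
    frame = pd.DataFrame(
        normalized.subset_genes(kept_genes).values,
        index=kept_genes,
        columns=normalized.sample_ids,
    )

    patients = sorted(train.clinical["patient_id"].unique())
    pat_index = {p: i for i, p in enumerate(patients)}
    sample_pat = train.clinical.set_index("sample_id")["patient_id"].to_dict()

    # nodes per gene, each as a patient mask
    node_gene: list[int] = []
    node_masks: list[np.ndarray] = []
    gene_node_offsets: list[tuple[int, int]] = []  # (offset, count) per gene
    gene_list: list[str] = []
    for gi, gene in enumerate(kept_genes):
        values = frame.loc[gene]
        ext = extreme_set(values, config.extreme_fraction)
        nodes = cluster_extreme_samples(
            values[ext], config.min_cluster_size, config.max_clusters
        )
        offset = len(node_masks)
        for node in nodes:
            mask = np.zeros(len(patients), dtype=bool)
            for s in node.member_samples:
                mask[pat_index[sample_pat[s]]] = True
            node_masks.append(mask)
            node_gene.append(len(gene_list))
        if nodes:
            gene_node_offsets.append((offset, len(nodes)))
            gene_list.append(gene)
    if len(gene_list) < 2:
        raise ValidationError("fewer than 2 genes produced cluster nodes")
    masks = np.array(node_masks, dtype=np.float32)
    offsets = np.array([o for o, _ in gene_node_offsets])
    counts = np.array([c for _, c in gene_node_offsets])
    n_genes = len(gene_list)

    # draw the cluster choice of every gene for every iteration up front
    choice = offsets[None, :] + rng.integers(
        0, counts[None, :], size=(config.n_graphs, n_genes)
    )

    unique_walks: set[tuple[int, ...]] = set()
    for it in range(config.n_graphs):
        node_idx = choice[it]
        member = masks[node_idx]
        weights = member @ member.T
        np.fill_diagonal(weights, 0.0)
        adj = weights >= config.min_overlap
        neighbors = [np.flatnonzero(adj[i]) for i in range(n_genes)]
        nbr_weights = [weights[i, neighbors[i]] for i in range(n_genes)]
        non_isolated = np.flatnonzero([nb.size > 0 for nb in neighbors])
        if non_isolated.size == 0:
            continue
        starts = non_isolated[
            rng.integers(non_isolated.size, size=config.walks_per_graph)
        ]
        for s in starts:
            walk = _walk_once(
                neighbors, nbr_weights, int(s), config.max_len, n_genes, rng
            )
            if len(walk) >= 2:
                # store global node ids so identical gene/cluster paths dedup
                unique_walks.add(tuple(int(node_idx[i]) for i in walk))

    if not unique_walks:
        raise ValidationError("no walks of length >= 2; graphs may be edgeless")

    walk_list = sorted(unique_walks)
    bool_masks = masks.astype(bool)
    pooled = np.array([bool_masks[list(w)].any(axis=0) for w in walk_list])
    sizes = pooled.sum(axis=1)
    n_pat = len(patients)
    testable = (sizes >= config.min_group) & (sizes <= n_pat - config.min_group)

    patient_tbl = train.patient_table()
    chi2 = np.full(len(walk_list), np.nan)
    pvals = np.full(len(walk_list), np.nan)
    if testable.any():
        chi2_t, p_t = logrank_two_group_batch(
            pooled[testable].T,
            patient_tbl["time"].to_numpy(float),
            patient_tbl["event"].to_numpy(int),
        )
        chi2[testable] = chi2_t
        pvals[testable] = p_t
    significant = testable & (pvals < config.alpha)

    node_gene_arr = np.array(node_gene)
    paths = [
        WalkPath(
            node_indices=w,
            genes=tuple(gene_list[node_gene_arr[i]] for i in w),
            patients=frozenset(
                np.array(patients)[bool_masks[list(w)].any(axis=0)]
            ),
            statistic=chi2[j],
            p=pvals[j],
            significant=bool(significant[j]),
            testable=bool(testable[j]),
        )
        for j, w in enumerate(walk_list)
    ]
    markers = fisher_marker_enrichment(paths, gene_list, config.q_max)
    info = {
        "n_screened_genes": len(kept_genes),
        "n_genes_with_nodes": n_genes,
        "n_nodes": len(node_masks),
        "n_unique_paths": len(walk_list),
        "n_testable_paths": int(testable.sum()),
        "n_significant_paths": int(significant.sum()),
    }
    return markers, info


@dataclass
class NetSurvivalResult:
    """Full per-fold marker tables, fold diagnostics and the consensus set."""

    per_fold: list[pd.DataFrame]
    fold_info: list[dict]
    consensus: pd.DataFrame
    config: NetSurvivalConfig
    seed: int

    @property
    def consensus_genes(self) -> list[str]:
        return self.consensus.loc[self.consensus["consensus"], "gene"].tolist()


def run_netsurvival(
    cohort: Cohort,
    config: NetSurvivalConfig | None = None,
    seed: int = 0,
    folds: FoldSplit | None = None,
) -> NetSurvivalResult:
    """Run the whole network pipeline over patient-grouped folds.

    The cohort should be TPM-stage and already low-expression filtered;
    each training fold is normalized and screened independently.  All
    randomness (fold split, cluster choices, walks) derives from ``seed``
    through per-fold substreams.
    """
    config = config or NetSurvivalConfig()
    if folds is None:
        folds = make_patient_folds(cohort, k=config.k_folds, seed=seed)
    streams = np.random.SeedSequence(seed).spawn(folds.k)
    per_fold, fold_info = [], []
    for fold in range(1, folds.k + 1):
        t0 = _time.perf_counter()
        train_ids, _ = folds.train_test_samples(cohort.clinical, fold)
        train = cohort.subset_samples(train_ids)
        markers, info = _fold_markers(
            train, config, np.random.default_rng(streams[fold - 1])
        )
        info["fold"] = fold
        info["seconds"] = round(_time.perf_counter() - t0, 2)
        logger.info("netsurvival fold %d: %s", fold, info)
        per_fold.append(markers)
        fold_info.append(info)
    consensus = consensus_markers(per_fold, config.min_folds)
    return NetSurvivalResult(
        per_fold=per_fold,
        fold_info=fold_info,
        consensus=consensus,
        config=config,
        seed=seed,
    )
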