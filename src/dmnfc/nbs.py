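"""Network-based statistic (NBS) with permutation familywise-error control.

The NBS tests for a group difference in edge weights of subject-level
connectivity graphs while controlling the familywise error rate weakly at
the component level.  Per edge, a pooled-variance two-sample t statistic
compares the Fisher-z weights between groups; edges whose t exceeds an
uncorrected threshold (default 3.2) form a suprathreshold graph whose
connected components are the candidate effects.  The null distribution of
the maximal component extent (edge count) is built by randomly exchanging
group labels (default 10,000 permutations, or exact enumeration of all
label assignments on small cohorts), and a component of extent k receives
the corrected p-value  p = #{null max >= k} / n_permutations.

Increased and decreased connectivity are tested in two separate one-sided
runs, each with its own max-extent null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

Tail = Literal["greater", "less", "both"]

#: Exact enumeration refuses above this many label assignments.
EXACT_ENUMERATION_CAP = 200_000


@dataclass
class NbsConfig:
    """Tuning parameters of the network-based statistic."""

    t_threshold: float = 3.2
    n_permutations: int = 10_000
    tail: Tail = "both"
    seed: int = 0
    exact_enumeration: bool = False
    welch: bool = False
    #: add-one smoothing of the permutation p (off: plain proportion)
    p_smoothing: bool = False

    def __post_init__(self) -> None:
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.tail not in ("greater", "less", "both"):
            raise ValueError(f"unknown tail {self.tail!r}")


@dataclass
class EdgeStats:
    """Edge-wise two-sample t statistics (group A minus group B)."""

    t: np.ndarray  # (p, p) symmetric, zero diagonal
    df: float
    group_means: dict  # label -> (p, p) mean-z matrix

    @property
    def n_rois(self) -> int:
        return self.t.shape[0]


@dataclass
class NbsComponent:
    """A connected suprathreshold component and its corrected p-value."""

    edges: list[tuple[int, int]]  # 1-based ROI index pairs, i < j
    p_fwe: float = float("nan")

    @property
    def nodes(self) -> set[int]:
        return {n for e in self.edges for n in e}

    @property
    def size_k(self) -> int:
        return len(self.edges)

    @property
    def significant(self) -> bool:
        return self.p_fwe < 0.05


@dataclass
class NbsResult:
    """Observed edge statistics, per-tail components and permutation nulls."""

    config: NbsConfig
    stats: EdgeStats
    components: dict  # tail -> list[NbsComponent]
    null_max_sizes: dict  # tail -> np.ndarray of length n_permutations
    n_edges_tested: int
    group_a: str = ""
    group_b: str = ""

    def significant_components(self, tail: str | None = None):
        tails = [tail] if tail else list(self.components)
        return [
            (t, c)
            for t in tails
            for c in self.components[t]
            if c.significant
        ]


def _stack_upper(z_matrices: Sequence[np.ndarray]) -> tuple[np.ndarray, int]:
    """Stack the strict upper triangles into an (n_subjects, E) array."""
    first = np.asarray(z_matrices[0])
    p = first.shape[0]
    iu = np.triu_indices(p, k=1)
    X = np.stack([np.asarray(z)[iu] for z in z_matrices])
    return X, p


def _edge_t_vec(
    xa: np.ndarray, xb: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, float]:
    """Vectorised two-sample t over columns; returns (t, df).

    Pooled-variance Student's t by default (df = n_a + n_b - 2).  Edges
    with zero pooled variance get t = 0.
    """
    na, nb = xa.shape[0], xb.shape[0]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    if welch:
        se2 = va / na + vb / nb
        df = float(na + nb - 2)  # reported df stays pooled-style
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = float(na + nb - 2)
    degenerate = _degenerate(se2, ma, mb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
    t = np.where(degenerate, 0.0, t)
    return t, df, degenerate


def _degenerate(se2: np.ndarray, ma: np.ndarray, mb: np.ndarray) -> np.ndarray:
    """Edges whose pooled variance is zero up to floating-point noise."""
    scale = np.maximum(1.0, ma**2 + mb**2)
    return se2 <= 1e-14 * scale


def edge_t_tests(
    z_group_a: Sequence[np.ndarray],
    z_group_b: Sequence[np.ndarray],
    welch: bool = False,
    labels: tuple[str, str] = ("A", "B"),
) -> EdgeStats:
    """Pooled two-sample t per edge; positive t means group A > group B."""
    if len(z_group_a) < 2 or len(z_group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    Xa, p = _stack_upper(z_group_a)
    Xb, pb = _stack_upper(z_group_b)
    if pb != p:
        raise ValueError("group matrices are not conformable")
    tvec, df, degenerate = _edge_t_vec(Xa, Xb, welch=welch)
    if degenerate.any():
        warnings.warn("zero pooled variance at some edges; t set to 0")
    iu = np.triu_indices(p, k=1)
    t = np.zeros((p, p))
    t[iu] = tvec
    t = t + t.T
    means = {}
    for lab, X in ((labels[0], Xa), (labels[1], Xb)):
        m = np.zeros((p, p))
        m[iu] = X.mean(axis=0)
        means[lab] = m + m.T
    return EdgeStats(t=t, df=df, group_means=means)


def suprathreshold_graph(
    stats: EdgeStats, threshold: float, tail: Tail
) -> np.ndarray:
    """Boolean adjacency of edges strictly exceeding the threshold.

    ``tail="greater"`` keeps t > threshold, ``tail="less"`` keeps
    -t > threshold.  Ties at exactly the threshold are excluded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if tail == "greater":
        adj = stats.t > threshold
    elif tail == "less":
        adj = -stats.t > threshold
    else:
        raise ValueError("suprathreshold_graph takes a single tail")
    np.fill_diagonal(adj, False)
    return adj


class _UnionFind:
    """Union-find over node indices, used for component search."""

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def connected_components(adjacency: np.ndarray) -> list[NbsComponent]:
    """Connected components of a suprathreshold graph, largest first.

    Only nodes with at least one incident edge participate.  Component
    size is the number of edges ("extent").  Edges are reported as
    1-based ROI index pairs.
    """
    adj = np.asarray(adjacency, dtype=bool)
    adj = adj | adj.T
    iu, ju = np.triu_indices(adj.shape[0], k=1)
    sel = adj[iu, ju]
    ei, ej = iu[sel], ju[sel]
    if ei.size == 0:
        return []
    uf = _UnionFind(adj.shape[0])
    for i, j in zip(ei, ej):
        uf.union(int(i), int(j))
    groups: dict[int, list[tuple[int, int]]] = {}
    for i, j in zip(ei, ej):
        groups.setdefault(uf.find(int(i)), []).append((int(i) + 1, int(j) + 1))
    comps = [NbsComponent(edges=sorted(e)) for e in groups.values()]
    comps.sort(key=lambda c: (-c.size_k, c.edges))
    return comps


def _max_component_size(adj_vec: np.ndarray, pair_index: np.ndarray,
                        n_nodes: int) -> int:
    """Edge count of the largest component given a boolean edge vector."""
    sel = np.flatnonzero(adj_vec)
    if sel.size == 0:
        return 0
    uf = _UnionFind(n_nodes)
    pairs = pair_index[sel]
    for i, j in pairs:
        uf.union(int(i), int(j))
    counts: dict[int, int] = {}
    for i, _ in pairs:
        r = uf.find(int(i))
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


def _permutation_masks(
    member_a: np.ndarray, config: NbsConfig
) -> np.ndarray:
    """(n_perm, n) boolean masks marking permuted group-A membership.

    Sampled masks permute the observed membership vector, with the
    permutation of index k derived deterministically from the seed, so
    results are reproducible under any execution order and swapping the
    group labels exchanges the two tails exactly.  Exact mode enumerates
    all C(n, n_a) assignments.
    """
    n = member_a.size
    n_a = int(member_a.sum())
    if config.exact_enumeration:
        n_comb = math.comb(n, n_a)
        if n_comb > EXACT_ENUMERATION_CAP:
            raise ValueError(
                f"exact enumeration of {n_comb} assignments exceeds the cap "
                f"of {EXACT_ENUMERATION_CAP}"
            )
        masks = np.zeros((n_comb, n), dtype=bool)
        for m, idx in zip(masks, combinations(range(n), n_a)):
            m[list(idx)] = True
        return masks
    root = np.random.SeedSequence(config.seed)
    masks = np.empty((config.n_permutations, n), dtype=bool)
    for k, child in enumerate(root.spawn(config.n_permutations)):
        rng = np.random.default_rng(child)
        masks[k] = member_a[rng.permutation(n)]
    return masks


def permutation_null(
    z_all: Sequence[np.ndarray],
    labels: Sequence,
    config: NbsConfig,
    tail: Tail = "greater",
    group_a=None,
) -> np.ndarray:
    """Null distribution of the maximal suprathreshold component extent.

    For each permutation the group labels are exchanged (preserving group
    sizes), the edge t statistics recomputed, thresholded at the same tail,
    and the largest component's edge count recorded (0 when no edge
    survives).
    """
    X, p = _stack_upper(z_all)
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("labels must take exactly two values")
    if group_a is None:
        group_a = uniq[0]
    n = X.shape[0]
    member_a = labels == group_a
    n_a = int(member_a.sum())
    masks = _permutation_masks(member_a, config)
    iu = np.triu_indices(p, k=1)
    pair_index = np.column_stack(iu)
    null = np.empty(masks.shape[0], dtype=int)
    # Batch the t statistics over permutations via group-sum algebra.
    X2 = X**2
    n_b = n - n_a
    tot = X.sum(axis=0)
    tot2 = X2.sum(axis=0)
    batch = 512
    sign = 1.0 if tail == "greater" else -1.0
    for start in range(0, masks.shape[0], batch):
        M = masks[start:start + batch].astype(float)
        sa = M @ X
        sa2 = M @ X2
        sb = tot - sa
        sb2 = tot2 - sa2
        ma, mb = sa / n_a, sb / n_b
        va = (sa2 - sa**2 / n_a) / (n_a - 1)
        vb = (sb2 - sb**2 / n_b) / (n_b - 1)
        if config.welch:
            se2 = va / n_a + vb / n_b
        else:
            sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
            se2 = sp2 * (1.0 / n_a + 1.0 / n_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ma - mb) / np.sqrt(se2)
        t = np.where(_degenerate(se2, ma, mb), 0.0, t)
        supra = sign * t > config.t_threshold
        for k in range(supra.shape[0]):
            null[start + k] = _max_component_size(supra[k], pair_index, p)
    return null


def fwe_pvalue(
    observed_k: int, null_max_sizes: np.ndarray, smoothing: bool = False
) -> float:
    """Proportion of permutations whose maximal component extent >= k.

    With ``smoothing`` the add-one estimator (#{null >= k} + 1)/(n + 1)
    is used instead of the plain proportion.
    """
    null = np.asarray(null_max_sizes)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if observed_k < 0:
        raise ValueError("component size must be non-negative")
    count = int(np.sum(null >= observed_k))
    if smoothing:
        return (count + 1) / (null.size + 1)
    return count / null.size


def run_nbs(
    z_matrices: Sequence[np.ndarray],
    labels: Sequence,
    config: NbsConfig | None = None,
    group_a=None,
) -> NbsResult:
    """Full NBS: observed statistics, components, permutation null, FWE p.

    ``labels`` assigns each matrix to one of two groups; ``group_a`` fixes
    the t-statistic orientation (positive t means group A > group B) and
    defaults to the first label encountered.  With ``config.tail="both"``
    the increased (greater) and decreased (less) directions are evaluated
    as two separate one-sided runs, each scored against its own
    max-extent null.
    """
    config = config or NbsConfig()
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("labels must take exactly two values")
    if group_a is None:
        group_a = uniq[0]
    group_b = [u for u in uniq if u != group_a][0]
    za = [z for z, lab in zip(z_matrices, labels) if lab == group_a]
    zb = [z for z, lab in zip(z_matrices, labels) if lab == group_b]
    stats = edge_t_tests(za, zb, welch=config.welch,
                         labels=(str(group_a), str(group_b)))
    p = stats.n_rois
    n_edges = p * (p - 1) // 2
    tails = ["greater", "less"] if config.tail == "both" else [config.tail]
    components: dict[str, list[NbsComponent]] = {}
    nulls: dict[str, np.ndarray] = {}
    for tail in tails:
        adj = suprathreshold_graph(stats, config.t_threshold, tail)
        comps = connected_components(adj)
        null = permutation_null(z_matrices, labels, config, tail=tail,
                                group_a=group_a)
        for c in comps:
            c.p_fwe = fwe_pvalue(c.size_k, null, smoothing=config.p_smoothing)
        components[tail] = comps
        nulls[tail] = null
    return NbsResult(
        config=config,
        stats=stats,
        components=components,
        null_max_sizes=nulls,
        n_edges_tested=n_edges,
        group_a=str(group_a),
        group_b=str(group_b),
    )
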