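"""Network-Based Statistic (NBS) for paired connectome comparisons.

Edgewise paired t-tests are thresholded at a primary edge alpha; connected
components of the suprathreshold graph are then tested against a permutation
null of maximal component sizes (component size = number of suprathreshold
edges).  For a paired design the exchangeability scheme is within-subject
sign flipping of the per-subject difference matrices.  When the full
sign-flip group is no larger than the requested permutation count the exact
enumeration is used instead of random sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import ConnectivityMatrix

__all__ = ["NBSConfig", "NBSComponent", "NBSResult", "edgewise_paired_t", "nbs_test"]


@dataclass(frozen=True)
class NBSConfig:
    edge_alpha: float = 0.001
    component_alpha: float = 0.05
    n_perm: int = 2000
    seed: int = 0
    tail: str = "two_sided"  # {"greater", "less", "two_sided"}

    def __post_init__(self) -> None:
        if not (0 < self.edge_alpha < self.component_alpha < 1):
            raise ValueError("require 0 < edge_alpha < component_alpha < 1")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.tail not in ("greater", "less", "two_sided"):
            raise ValueError(f"unknown tail {self.tail!r}")


@dataclass
class NBSComponent:
    edges: list[tuple[int, int]]  # region index pairs (i < j)
    size: int  # number of suprathreshold edges
    sign: int  # +1 for a > b direction, -1 for a < b
    p_corrected: float = float("nan")


@dataclass
class NBSResult:
    labels: list[str]
    edge_t: np.ndarray
    edge_p: np.ndarray
    suprathreshold: np.ndarray  # 0/1 matrix (union over signs)
    components: list[NBSComponent]
    null_max_sizes: np.ndarray
    excluded: np.ndarray  # edges with undefined t (zero difference variance)
    t_critical: float
    exact: bool = False

    def significant_components(self, alpha: float) -> list[NBSComponent]:
        return [c for c in self.components if c.p_corrected < alpha]

    def to_dict(self) -> dict:
        return {
            "t_critical": self.t_critical,
            "exact": self.exact,
            "null_max_sizes": self.null_max_sizes.tolist(),
            "components": [
                {
                    "size": c.size,
                    "sign": c.sign,
                    "p_corrected": c.p_corrected,
                    "edges": [
                        [self.labels[i], self.labels[j]] for i, j in c.edges
                    ],
                }
                for c in self.components
            ],
        }


def _difference_stack(
    a: list[ConnectivityMatrix], b: list[ConnectivityMatrix]
) -> tuple[np.ndarray, list[str], tuple[np.ndarray, np.ndarray]]:
    if len(a) != len(b):
        raise ValueError("paired samples must have equal subject counts")
    if len(a) < 3:
        raise ValueError("need at least 3 subjects")
    labels = a[0].labels
    for cm in (*a, *b):
        if cm.labels != labels:
            raise ValueError("all matrices must share identical region labels")
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    diffs = np.stack([x.values[iu] - y.values[iu] for x, y in zip(a, b)])
    return diffs, labels, iu


def _paired_t_vector(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """t statistics per edge.

    An edge whose differences are identically zero has t = 0; a nonzero
    constant difference leaves t undefined (nan) and the edge is flagged as
    excluded.
    """
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    excluded = (sd == 0) & (mean != 0)
    return t, excluded


def edgewise_paired_t(
    a: list[ConnectivityMatrix], b: list[ConnectivityMatrix]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge paired t over subjects' (a - b) differences.

    Returns (t matrix, two-sided p matrix), both symmetric with zero/unit
    diagonals respectively untouched (diagonal entries are set to 0 and 1).
    Edges with zero difference variance are returned as NaN.
    """
    diffs, labels, iu = _difference_stack(a, b)
    n_sub = diffs.shape[0]
    t_vec, excluded = _paired_t_vector(diffs)
    p_vec = np.where(
        np.isnan(t_vec), np.nan, 2.0 * stats.t.sf(np.abs(t_vec), df=n_sub - 1)
    )
    n = len(labels)
    t_mat = np.zeros((n, n))
    p_mat = np.ones((n, n))
    t_mat[iu] = t_vec
    p_mat[iu] = p_vec
    t_mat += t_mat.T
    p_mat = np.minimum(p_mat, p_mat.T)
    np.fill_diagonal(p_mat, 1.0)
    return t_mat, p_mat


def _component_sizes(
    mask: np.ndarray, iu: tuple[np.ndarray, np.ndarray], n_nodes: int
) -> tuple[list[list[int]], np.ndarray]:
    """Connected components of the graph formed by masked edges.

    Returns (list of edge-index lists per component, component edge counts).
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return [], np.array([], dtype=int)
    rows = iu[0][idx]
    cols = iu[1][idx]
    data = np.ones(idx.size)
    adj = csr_matrix((data, (rows, cols)), shape=(n_nodes, n_nodes))
    adj = adj + adj.T
    _, node_labels = connected_components(adj, directed=False)
    comp_of_edge = node_labels[rows]  # endpoints share a component
    comps: dict[int, list[int]] = {}
    for e, c in zip(idx, comp_of_edge):
        comps.setdefault(int(c), []).append(int(e))
    edge_lists = list(comps.values())
    sizes = np.array([len(e) for e in edge_lists], dtype=int)
    return edge_lists, sizes


def _max_component_size(
    t_vec: np.ndarray, t_crit: float, tail: str, iu, n_nodes: int
) -> int:
    best = 0
    if tail in ("greater", "two_sided"):
        _, sizes = _component_sizes(t_vec > t_crit, iu, n_nodes)
        if sizes.size:
            best = max(best, int(sizes.max()))
    if tail in ("less", "two_sided"):
        _, sizes = _component_sizes(t_vec < -t_crit, iu, n_nodes)
        if sizes.size:
            best = max(best, int(sizes.max()))
    return best


def nbs_test(
    a: list[ConnectivityMatrix],
    b: list[ConnectivityMatrix],
    cfg: NBSConfig = NBSConfig(),
) -> NBSResult:
    """Paired NBS between two matched lists of connectivity matrices.

    For ``tail='two_sided'`` suprathreshold graphs and components are formed
    separately per sign, and the null maximal component size is taken over
    both signs.  Corrected p per component is ``(1 + #{null >= size}) /
    (1 + n_perm)`` under random sign flips, or the exact proportion over the
    full sign-flip group when ``2**n_subjects <= n_perm``.
    """
    diffs, labels, iu = _difference_stack(a, b)
    n_sub, n_edges = diffs.shape
    n_nodes = len(labels)
    df = n_sub - 1
    if cfg.tail == "two_sided":
        t_crit = float(stats.t.isf(cfg.edge_alpha / 2.0, df))
    else:
        t_crit = float(stats.t.isf(cfg.edge_alpha, df))

    t_vec, excluded = _paired_t_vector(diffs)
    t_safe = np.where(np.isnan(t_vec), 0.0, t_vec)

    # observed components, per sign
    components: list[NBSComponent] = []
    supra = np.zeros(n_edges, dtype=bool)
    sign_masks = []
    if cfg.tail in ("greater", "two_sided"):
        sign_masks.append((1, t_safe > t_crit))
    if cfg.tail in ("less", "two_sided"):
        sign_masks.append((-1, t_safe < -t_crit))
    for sign, mask in sign_masks:
        supra |= mask
        edge_lists, sizes = _component_sizes(mask, iu, n_nodes)
        for edges_idx, size in zip(edge_lists, sizes):
            pairs = [(int(iu[0][e]), int(iu[1][e])) for e in edges_idx]
            components.append(NBSComponent(pairs, int(size), sign))

    # permutation null of the maximal component size
    exact = 2**n_sub <= cfg.n_perm
    if exact:
        signs = np.array(
            [[1 if (k >> s) & 1 else -1 for s in range(n_sub)] for k in range(2**n_sub)],
            dtype=float,
        )
    else:
        rng = np.random.default_rng(cfg.seed)
        signs = rng.choice([-1.0, 1.0], size=(cfg.n_perm, n_sub))
    n_perm = signs.shape[0]
    # vectorized per-permutation t: sum of squares is sign-invariant
    sumsq = (diffs**2).sum(axis=0)
    means = (signs @ diffs) / n_sub
    var = np.maximum(sumsq - n_sub * means**2, 0.0) / (n_sub - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(var > 0, means / np.sqrt(var / n_sub), 0.0)
    null_max = np.empty(n_perm, dtype=int)
    for k in range(n_perm):
        null_max[k] = _max_component_size(t_perm[k], t_crit, cfg.tail, iu, n_nodes)

    for comp in components:
        if exact:
            comp.p_corrected = float((null_max >= comp.size).mean())
        else:
            comp.p_corrected = float(
                (1 + int((null_max >= comp.size).sum())) / (1 + n_perm)
            )

    n = n_nodes
    t_mat = np.zeros((n, n))
    t_mat[iu] = t_safe
    t_mat += t_mat.T
    p_mat = np.ones((n, n))
    p_vec = np.where(np.isnan(t_vec), np.nan, 2.0 * stats.t.sf(np.abs(t_safe), df))
    p_mat[iu] = p_vec
    p_mat = np.minimum(p_mat, p_mat.T)
    supra_mat = np.zeros((n, n), dtype=np.int8)
    supra_mat[iu] = supra.astype(np.int8)
    supra_mat |= supra_mat.T
    excl_mat = np.zeros((n, n), dtype=bool)
    excl_mat[iu] = excluded
    excl_mat |= excl_mat.T

    components.sort(key=lambda c: -c.size)
    return NBSResult(
        labels=labels,
        edge_t=t_mat,
        edge_p=p_mat,
        suprathreshold=supra_mat,
        components=components,
        null_max_sizes=null_max,
        excluded=excl_mat,
        t_critical=t_crit,
        exact=exact,
    )
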