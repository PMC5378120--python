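"""Consensus-map construction by order-constrained linear programming.

Component linkage groups for one chromosome are first orientation-normalised
(groups whose common-marker order has mean negative rank correlation against
the rest are reversed; groups sharing no markers are discarded).  The merge
then solves an L1 linear program over consensus positions: for each
component map and each marker pair at most K intervals apart an order
constraint x_j - x_i >= 0 is added, and the objective minimises the sum of
absolute deviations between consensus and component adjacent-marker
distances, each component weighted equally.  Contradictory order constraints
(cycles in the union order graph) are removed greedily by lowest support
before solving.  Candidate maps for K = 1..3 are scored by per-component
RMSE after an affine rescaling, and the candidate with lowest mean RMSE
(ties: lower SD, then lower K) is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linprog
from scipy.stats import spearmanr

from .linkage import LinkageGroup

__all__ = ["ConsensusMap", "orient_lgs", "merge_lgs", "select_K", "build_consensus"]


@dataclass
class ConsensusMap:
    chromosome: str
    markers: list
    positions: np.ndarray
    K: int
    component_ids: list
    rmse: np.ndarray  # per component
    removed_constraints: list = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.positions) and (
            np.any(np.diff(self.positions) < -1e-9) or abs(self.positions[0]) > 1e-9
        ):
            raise ValueError("consensus positions must be non-decreasing from 0")

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse)) if len(self.rmse) else 0.0

    @property
    def sd_rmse(self) -> float:
        return float(np.std(self.rmse, ddof=1)) if len(self.rmse) > 1 else 0.0

    @property
    def length_cM(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    def position_of(self, marker):
        try:
            return float(self.positions[self.markers.index(marker)])
        except ValueError:
            return None


def orient_lgs(lgs):
    """Normalise component orientations for one chromosome.

    Pairwise Spearman correlations of common-marker ranks are computed; any
    group whose mean correlation against all comparable groups is negative
    is reversed.  Groups with no markers in common with any other group are
    discarded with a warning.  Returns the oriented list.
    """
    lgs = list(lgs)
    n = len(lgs)
    if n <= 1:
        return lgs
    sets = [set(lg.markers) for lg in lgs]
    rho = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            common = sets[i] & sets[j]
            if len(common) < 2:
                continue
            ri = [lgs[i].markers.index(m) for m in common]
            rj = [lgs[j].markers.index(m) for m in common]
            if len(common) == 2:
                r = 1.0 if (np.sign(np.diff(ri)) == np.sign(np.diff(rj)))[0] else -1.0
            else:
                r = spearmanr(ri, rj).statistic
            rho[i, j] = rho[j, i] = r
    keep, oriented = [], []
    for i, lg in enumerate(lgs):
        row = rho[i]
        if np.all(np.isnan(row)):
            warnings.warn(
                f"linkage group {lg.lg_id} shares no markers with any other "
                f"component; discarded from consensus"
            )
            continue
        mean = np.nanmean(row)
        oriented.append(lg.reversed() if mean < 0 else lg)
        keep.append(i)
    return oriented


def merge_lgs(lgs, K=1):
    """Merge oriented component groups into one consensus map by LP.

    Returns a :class:`ConsensusMap`.  Raises if no markers remain.
    """
    lgs = list(lgs)
    if not lgs:
        raise ValueError("no component linkage groups to merge")
    if K < 1:
        raise ValueError("K must be >= 1")
    markers = sorted({m for lg in lgs for m in lg.markers})
    idx = {m: i for i, m in enumerate(markers)}
    nm = len(markers)

    # order constraints as a weighted digraph; weight = number of supporting maps
    g = nx.DiGraph()
    g.add_nodes_from(range(nm))
    for lg in lgs:
        ids = [idx[m] for m in lg.markers]
        for a in range(len(ids)):
            for q in range(1, K + 1):
                if a + q >= len(ids):
                    break
                u, v = ids[a], ids[a + q]
                if u == v:
                    continue
                if g.has_edge(u, v):
                    g[u][v]["weight"] += 1
                else:
                    g.add_edge(u, v, weight=1)

    removed = []
    while True:
        try:
            cycle = nx.find_cycle(g, orientation="original")
        except nx.NetworkXNoCycle:
            break
        # drop the least-supported constraint in the cycle
        u, v, _ = min(cycle, key=lambda e: (g[e[0]][e[1]]["weight"], e[0], e[1]))
        removed.append((markers[u], markers[v], g[u][v]["weight"]))
        g.remove_edge(u, v)

    # objective terms: adjacent (q=1) pairs of every component, equal total
    # weight per component
    terms = []  # (i, j, distance, weight)
    for lg in lgs:
        ids = [idx[m] for m in lg.markers]
        pairs = [
            (ids[a], ids[a + 1], float(lg.positions[a + 1] - lg.positions[a]))
            for a in range(len(ids) - 1)
            if ids[a] != ids[a + 1]
        ]
        if not pairs:
            continue
        w = 1.0 / len(pairs)
        terms.extend((i, j, d, w) for i, j, d in pairs)

    nt = len(terms)
    # variables: x (nm) then slack e (nt); minimise sum w*e
    c = np.concatenate([np.zeros(nm), np.array([t[3] for t in terms])])
    rows, cols, vals, rhs = [], [], [], []
    row = 0
    for t, (i, j, d, _w) in enumerate(terms):
        # (x_j - x_i) - d <= e  ->  -x_i + x_j - e <= d
        rows += [row, row, row]; cols += [i, j, nm + t]; vals += [-1.0, 1.0, -1.0]
        rhs.append(d); row += 1
        # d - (x_j - x_i) <= e  ->  x_i - x_j - e <= -d
        rows += [row, row, row]; cols += [i, j, nm + t]; vals += [1.0, -1.0, -1.0]
        rhs.append(-d); row += 1
    for u, v in g.edges:
        # x_v - x_u >= 0  ->  x_u - x_v <= 0
        rows += [row, row]; cols += [u, v]; vals += [1.0, -1.0]
        rhs.append(0.0); row += 1
    from scipy.sparse import coo_matrix

    a_ub = coo_matrix((vals, (rows, cols)), shape=(row, nm + nt))
    res = linprog(c, A_ub=a_ub, b_ub=np.array(rhs),
                  bounds=[(0, None)] * nm + [(0, None)] * nt, method="highs")
    if not res.success:
        raise RuntimeError(f"consensus LP failed: {res.message}; removed={removed}")
    x = res.x[:nm]
    x = x - x.min()

    # consensus order: by position; ties resolved by topological order of the
    # surviving constraint DAG, then by name
    topo = {m: t for t, m in enumerate(nx.lexicographical_topological_sort(
        nx.relabel_nodes(g, {i: m for i, m in enumerate(markers)})))}
    order = sorted(range(nm), key=lambda i: (round(x[i], 9), topo.get(markers[i], 0),
                                             markers[i]))
    out_markers = [markers[i] for i in order]
    out_pos = np.maximum.accumulate(x[order])

    cmap = ConsensusMap(
        chromosome=lgs[0].chromosome or "",
        markers=out_markers,
        positions=out_pos - out_pos[0] if nm else out_pos,
        K=K,
        component_ids=[lg.lg_id for lg in lgs],
        rmse=np.zeros(len(lgs)),
        removed_constraints=removed,
    )
    cmap.rmse = np.array([_component_rmse(cmap, lg) for lg in lgs])
    return cmap


def _component_rmse(cmap: ConsensusMap, lg: LinkageGroup) -> float:
    """RMSE between consensus positions and an affinely rescaled component."""
    pos_c, pos_m = [], []
    for m, p in zip(lg.markers, lg.positions):
        pc = cmap.position_of(m)
        if pc is not None:
            pos_c.append(pc)
            pos_m.append(p)
    if len(pos_c) < 2:
        return 0.0
    pos_c = np.asarray(pos_c)
    pos_m = np.asarray(pos_m)
    A = np.column_stack([np.ones_like(pos_m), pos_m])
    coef, *_ = np.linalg.lstsq(A, pos_c, rcond=None)
    resid = pos_c - A @ coef
    return float(np.sqrt(np.mean(resid**2)))


def select_K(candidates):
    """Choose among per-K consensus candidates: lowest mean RMSE, ties by
    lower SD of RMSE, then lower K."""
    if not candidates:
        raise ValueError("no candidates")
    return min(candidates, key=lambda c: (round(c.mean_rmse, 9),
                                          round(c.sd_rmse, 9), c.K))


def build_consensus(maps, Ks=(1, 2, 3)):
    """Build one consensus map per chromosome from many per-population maps.

    ``maps`` is an iterable of GeneticMap.  Linkage groups are pooled by
    their majority chromosome label, oriented, merged for each K, and the
    best candidate per chromosome selected.  Returns {chromosome:
    ConsensusMap}.
    """
    by_chrom = {}
    for gmap in maps:
        for lg in gmap.lgs:
            if lg.chromosome and lg.n_markers >= 2:
                by_chrom.setdefault(lg.chromosome, []).append(lg)
    out = {}
    for chrom in sorted(by_chrom):
        oriented = orient_lgs(by_chrom[chrom])
        if not oriented:
            continue
        cands = [merge_lgs(oriented, K=k) for k in Ks]
        out[chrom] = select_K(cands)
    return out
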