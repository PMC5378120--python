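"""Linkage-group formation, seriation ordering and genetic-map construction.

The workflow mirrors classical two-point RIL mapping: estimate pairwise
recombination fractions and linkage LODs under the generation-aware selfing
model, group markers by single-linkage transitive closure (LOD >= 3 and
r <= 0.3 by default), order each group by greedy seriation minimising the
sum of adjacent recombination fractions (SARF) with progressive rippling,
convert adjacent fractions to Kosambi cM, and split groups at gaps of
35 cM or more.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import genetics
from .io import GenotypeMatrix, CODE_NA, CODE_AB, validate_matrix

__all__ = [
    "EstRFMatrix",
    "LinkageGroup",
    "GeneticMap",
    "est_rf_matrix",
    "form_linkage_groups",
    "order_lg",
    "split_lg",
    "build_map",
]

# r at which adjacent-interval Kosambi distances are capped; keeps positions
# finite when an adjacent pair in an ordered group is effectively unlinked
# (such intervals exceed the 35 cM split threshold and are cut anyway)
_R_CAP = 0.4999


@dataclass
class EstRFMatrix:
    """Pairwise recombination-fraction and LOD estimates.

    ``rf`` and ``lod`` are symmetric (n, n) arrays; pairs with no joint
    observations carry rf = nan, lod = 0.  ``informative`` marks markers
    with at least one scored heterozygote (collapsed-likelihood markers are
    excluded from downstream distortion/translocation scans).
    """

    markers: list
    rf: np.ndarray
    lod: np.ndarray
    informative: np.ndarray

    def index(self, name):
        return self.markers.index(name)

    def submatrix(self, names):
        idx = np.array([self.markers.index(n) for n in names])
        return EstRFMatrix(
            markers=list(names),
            rf=self.rf[np.ix_(idx, idx)],
            lod=self.lod[np.ix_(idx, idx)],
            informative=self.informative[idx],
        )


@dataclass
class LinkageGroup:
    lg_id: str
    markers: list
    positions: np.ndarray
    chromosome: str | None = None
    sarf: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.positions) != len(self.markers):
            raise ValueError("positions/markers length mismatch")
        if len(self.positions) and (
            np.any(np.diff(self.positions) < 0) or self.positions[0] != 0
        ):
            raise ValueError("positions must be non-decreasing and start at 0")

    @property
    def length_cM(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def reversed(self) -> "LinkageGroup":
        pos = self.positions[-1] - self.positions[::-1]
        return LinkageGroup(self.lg_id, list(self.markers[::-1]), pos,
                            self.chromosome, self.sarf)


@dataclass
class GeneticMap:
    population_id: str
    lgs: list
    singletons: list = field(default_factory=list)

    @property
    def total_length_cM(self) -> float:
        return float(sum(lg.length_cM for lg in self.lgs))

    @property
    def n_linked_markers(self) -> int:
        return sum(lg.n_markers for lg in self.lgs)

    @property
    def n_cosegregating_markers(self) -> int:
        # markers sitting at the same cM as their predecessor (adjacent r=0)
        n = 0
        for lg in self.lgs:
            if lg.n_markers > 1:
                n += int(np.sum(np.diff(lg.positions) == 0))
        return n

    @property
    def chromosomes(self) -> set:
        return {lg.chromosome for lg in self.lgs if lg.chromosome}


def pair_counts(calls_i, calls_j):
    """3x3 two-locus genotype contingency table, missing excluded."""
    ok = (calls_i != CODE_NA) & (calls_j != CODE_NA)
    counts = np.zeros((3, 3))
    np.add.at(counts, (calls_i[ok], calls_j[ok]), 1.0)
    return counts


def _collapse_transform(collapse_a, collapse_b):
    """(9, n_classes) 0/1 matrix merging AB with BB along collapsed axes."""
    ra = [0, 1, 1] if collapse_a else [0, 1, 2]
    rb = [0, 1, 1] if collapse_b else [0, 1, 2]
    na, nb = max(ra) + 1, max(rb) + 1
    t = np.zeros((9, na * nb))
    for a in range(3):
        for b in range(3):
            t[3 * a + b, nb * ra[a] + rb[b]] = 1.0
    return t


def est_rf_matrix(matrix: GenotypeMatrix, chunk=8192) -> EstRFMatrix:
    """Estimate all pairwise recombination fractions and LODs.

    Markers with no heterozygote calls (in non-inbred populations) use the
    collapsed AA-vs-non-AA likelihood on their axis.  The MLE is taken on
    the shared r grid of :func:`namkit.genetics.estimate_rf` (step 0.001),
    which is ample for grouping, ordering, and translocation screening; use
    :func:`namkit.genetics.estimate_rf` directly for a refined scalar
    estimate.
    """
    calls = matrix.calls
    m = matrix.n_markers
    k = matrix.generation
    kk = None if (isinstance(k, float) and math.isinf(k)) else int(k)
    inbred = kk is None
    has_het = (calls == CODE_AB).sum(axis=1) > 0
    collapse = ~has_het & ~inbred

    # 9-class contingency counts for every pair in nine M x M products
    ind = [(calls == g).astype(np.float64) for g in (0, 1, 2)]
    iu, ju = np.triu_indices(m, k=1)
    counts = np.empty((len(iu), 9))
    for a in range(3):
        for b in range(3):
            counts[:, 3 * a + b] = (ind[a] @ ind[b].T)[iu, ju]
    total = counts.sum(axis=1)

    rf = np.full((m, m), np.nan)
    lod = np.zeros((m, m))
    np.fill_diagonal(rf, 0.0)
    ln10 = math.log(10)
    grid = genetics._R_GRID
    for ca in (False, True):
        for cb in (False, True):
            mask = (collapse[iu] == ca) & (collapse[ju] == cb) & (total >= 1)
            if not mask.any():
                continue
            t = _collapse_transform(ca, cb)
            logp = genetics._model_grid(kk, ca, cb)  # (G, ncls)
            logp = np.where(np.isfinite(logp), logp, -1e30)
            cc = counts[mask] @ t
            idx = np.where(mask)[0]
            for s in range(0, len(idx), chunk):
                block = cc[s:s + chunk]
                ll = block @ logp.T  # (B, G)
                best = np.argmax(ll, axis=1)
                sel = idx[s:s + chunk]
                r_hat = grid[best]
                l_hat = np.maximum(
                    (ll[np.arange(len(block)), best] - ll[:, -1]) / ln10, 0.0)
                rf[iu[sel], ju[sel]] = r_hat
                lod[iu[sel], ju[sel]] = l_hat
    rf[ju, iu] = rf[iu, ju]
    lod[ju, iu] = lod[iu, ju]
    return EstRFMatrix(
        markers=list(matrix.marker_names), rf=rf, lod=lod,
        informative=has_het | inbred,
    )


def form_linkage_groups(est: EstRFMatrix, lod_min=3.0, rf_max=0.3):
    """Single-linkage partition: markers joined by any chain of pairs with
    LOD >= lod_min and r <= rf_max.  Returns (groups, singletons); groups
    are lists of marker names sorted for determinism, largest first."""
    g = nx.Graph()
    g.add_nodes_from(est.markers)
    n = len(est.markers)
    with np.errstate(invalid="ignore"):
        linked = (est.lod >= lod_min) & (est.rf <= rf_max)
    ii, jj = np.where(np.triu(linked, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(est.markers[i], est.markers[j])
    comps = [sorted(c) for c in nx.connected_components(g)]
    groups = sorted((c for c in comps if len(c) > 1), key=lambda c: (-len(c), c[0]))
    singletons = sorted(c[0] for c in comps if len(c) == 1)
    return groups, singletons


def _sarf(order, rf):
    return float(sum(rf[a, b] for a, b in zip(order, order[1:])))


def order_lg(markers, est: EstRFMatrix, ripple_window=3, lg_id="LG1",
             chromosome=None, assignments=None):
    """Order one linkage group by greedy seriation + progressive rippling.

    Seeding: the marker pair with smallest r (ties by name); growth: each
    unplaced marker is tried at every insertion position and the
    (marker, position) pair minimising SARF is committed (ties broken by
    marker name, then position, for determinism).  Rippling then slides a
    window of ``ripple_window`` markers along the order and accepts any
    in-window permutation that strictly lowers SARF, repeating until no
    improvement.  Positions are cumulative Kosambi distances of adjacent
    estimated fractions.
    """
    names = list(markers)
    if len(names) < 2:
        raise ValueError("ordering needs at least 2 markers")
    sub = est.submatrix(names)
    rf = sub.rf.copy()
    if np.isnan(rf).any():
        # unobserved pairs are treated as unlinked for ordering purposes
        rf = np.where(np.isnan(rf), 0.5, rf)
    n = len(names)

    # seed pair: smallest rf, ties by name order
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            key = (rf[i, j], names[i], names[j])
            if best is None or key < best[0]:
                best = (key, (i, j))
    order = list(best[1])
    unplaced = [i for i in range(n) if i not in order]
    # deterministic greedy insertion
    while unplaced:
        cand = None
        for mi in sorted(unplaced, key=lambda i: names[i]):
            for pos in range(len(order) + 1):
                trial = order[:pos] + [mi] + order[pos:]
                s = _sarf(trial, rf)
                key = (s, names[mi], pos)
                if cand is None or key < cand[0]:
                    cand = (key, mi, trial)
        order = cand[2]
        unplaced.remove(cand[1])

    # progressive rippling
    w = max(2, int(ripple_window))
    improved = True
    while improved:
        improved = False
        current = _sarf(order, rf)
        for start in range(0, len(order) - w + 1):
            window = order[start:start + w]
            for perm in itertools.permutations(window):
                if list(perm) == window:
                    continue
                trial = order[:start] + list(perm) + order[start + w:]
                s = _sarf(trial, rf)
                if s < current - 1e-12:
                    order = trial
                    current = s
                    improved = True

    adj = np.array([rf[a, b] for a, b in zip(order, order[1:])])
    dists = genetics.kosambi(np.minimum(adj, _R_CAP))
    positions = np.concatenate([[0.0], np.cumsum(dists)])
    ordered_names = [names[i] for i in order]
    chrom = chromosome
    if chrom is None and assignments:
        votes = [assignments.get(nm) for nm in ordered_names if assignments.get(nm)]
        if votes:
            vals, counts = np.unique(votes, return_counts=True)
            chrom = str(vals[np.argmax(counts)])
    lg = LinkageGroup(lg_id, ordered_names, positions, chrom, _sarf(order, rf))
    # canonical orientation: majority-assigned chromosome handled upstream;
    # here normalise so the lexicographically smaller end marker comes first
    if lg.markers[0] > lg.markers[-1]:
        lg = lg.reversed()
        lg.positions = lg.positions - lg.positions[0]
    return lg


def split_lg(lg: LinkageGroup, gap_cM=35.0):
    """Split a linkage group at every adjacent gap >= ``gap_cM`` (inclusive);
    fragments are re-anchored at 0 and suffixed .1, .2, ..."""
    if lg.n_markers < 2:
        return [lg]
    gaps = np.diff(lg.positions)
    cuts = np.where(gaps >= gap_cM)[0]
    if len(cuts) == 0:
        return [lg]
    pieces = []
    start = 0
    bounds = list(cuts + 1) + [lg.n_markers]
    for part, stop in enumerate(bounds, start=1):
        pos = lg.positions[start:stop] - lg.positions[start]
        pieces.append(
            LinkageGroup(
                f"{lg.lg_id}.{part}", lg.markers[start:stop], pos, lg.chromosome
            )
        )
        start = stop
    return pieces


def build_map(matrix: GenotypeMatrix, lod_min=3.0, rf_max=0.3, max_missing=0.10,
              split_gap_cM=35.0, ripple_window=3, est=None):
    """Full per-population map construction: validate, estimate pairwise
    recombination fractions, group, order, split.  Returns (GeneticMap,
    EstRFMatrix, validation report)."""
    kept, report = validate_matrix(matrix, max_missing=max_missing)
    if est is None:
        est = est_rf_matrix(kept)
    assignments = {m.name: m.assigned_chromosome for m in kept.markers}
    groups, singletons = form_linkage_groups(est, lod_min=lod_min, rf_max=rf_max)
    lgs = []
    counter = 0
    for group in groups:
        counter += 1
        lg = order_lg(group, est, ripple_window=ripple_window,
                      lg_id=f"LG{counter}", assignments=assignments)
        for piece in split_lg(lg, gap_cM=split_gap_cM):
            # re-derive the majority label per fragment
            votes = [assignments.get(nm) for nm in piece.markers if assignments.get(nm)]
            if votes:
                vals, cnts = np.unique(votes, return_counts=True)
                piece.chromosome = str(vals[np.argmax(cnts)])
            lgs.append(piece)
    gmap = GeneticMap(population_id=matrix.population_id, lgs=lgs,
                      singletons=singletons)
    return gmap, est, report
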