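"""Synthetic NAM-panel generator for selfed-RIL populations.

Simulates single-seed-descent populations from a biparental F1 with known
truth: per-chromosome crossovers are Poisson with mean length/100 (Haldane,
no interference), crossover positions uniform, and selfing proceeds with
exactly one offspring per line per generation.  Structural variants
(translocations, inversions) are realised by rearranging the carrier
population's *physical* marker layout: markers in a translocated or inverted
segment segregate with their rearranged location while keeping their
original (a-priori) chromosome assignment — which is precisely the signature
the mapped- and estRF-translocation callers look for.

Selection at segregation-distortion loci acts as relative zygote survival
per generation; a crossover-modifier locus scales the genome-wide expected
crossover number additively per allele copy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io import GenotypeMatrix, MarkerInfo, CODE_NA

__all__ = [
    "ChromosomeSpec",
    "GenomeSpec",
    "Translocation",
    "Inversion",
    "StructuralVariantSpec",
    "SDL",
    "XOModifier",
    "SelectionSpec",
    "SimulationConfig",
    "TruthRecord",
    "simulate_meiosis",
    "simulate_ssd_population",
    "apply_observation_noise",
    "wheat_like_genome",
    "uniform_genome",
]

_INBRED_ROUNDS = 25  # residual heterozygosity 2^-24 ~ 6e-8; then coin-flipped


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length_cM: float
    positions: tuple  # strictly increasing true cM positions
    marker_names: tuple

    def __post_init__(self):
        if self.length_cM < 0:
            raise ValueError(f"{self.name}: negative length")
        pos = np.asarray(self.positions, float)
        if len(pos) != len(self.marker_names):
            raise ValueError(f"{self.name}: positions/names length mismatch")
        if len(pos) and (np.any(np.diff(pos) <= 0) or pos[0] < 0 or pos[-1] > self.length_cM):
            raise ValueError(f"{self.name}: positions must be strictly increasing within [0, length]")


@dataclass(frozen=True)
class GenomeSpec:
    """True marker layout: chromosome names, genetic lengths and marker
    positions.  Marker names must be unique genome-wide."""

    chromosomes: tuple

    def __post_init__(self):
        names = [n for c in self.chromosomes for n in c.marker_names]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names across genome")

    def chromosome(self, name) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def n_markers(self):
        return sum(len(c.marker_names) for c in self.chromosomes)

    def assigned_chromosome(self) -> dict:
        return {n: c.name for c in self.chromosomes for n in c.marker_names}


@dataclass(frozen=True)
class Translocation:
    donor: str
    segment: tuple  # (start cM, end cM) on donor
    recipient: str
    insertion_point: float
    reciprocal: bool = False
    carrier_parent: int = 1  # 0 = reference parent, 1 = other


@dataclass(frozen=True)
class Inversion:
    chromosome: str
    interval: tuple
    carrier_parent: int = 1


@dataclass(frozen=True)
class StructuralVariantSpec:
    translocations: tuple = ()
    inversions: tuple = ()

    def __post_init__(self):
        used = {}
        for t in self.translocations:
            a, b = t.segment
            if not 0 <= a < b:
                raise ValueError(f"bad segment {t.segment} on {t.donor}")
            used.setdefault(t.donor, []).append((a, b))
        for inv in self.inversions:
            a, b = inv.interval
            if not 0 <= a < b:
                raise ValueError(f"bad interval {inv.interval} on {inv.chromosome}")
            used.setdefault(inv.chromosome, []).append((a, b))
        for chrom, ivals in used.items():
            ivals.sort()
            for (a1, b1), (a2, b2) in zip(ivals, ivals[1:]):
                if a2 < b1:
                    raise ValueError(f"overlapping variants on {chrom}")


@dataclass(frozen=True)
class SDL:
    """Segregation-distortion locus: relative zygote survival weights for
    (AA, AB, BB) applied each generation at the marker nearest the locus."""

    chromosome: str
    position_cM: float
    weights: tuple  # (wAA, wAB, wBB), >= 0, not all zero

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if w.shape != (3,) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("SDL weights must be three non-negative values, not all zero")


@dataclass(frozen=True)
class XOModifier:
    """Crossover-count modifier: each copy of the non-reference allele at the
    locus adds ``effect`` to the expected crossover number of every
    chromosome in that individual's meioses."""

    chromosome: str
    position_cM: float
    effect: float

    def __post_init__(self):
        if not math.isfinite(self.effect):
            raise ValueError("modifier effect must be finite")


@dataclass(frozen=True)
class SelectionSpec:
    sdl: tuple = ()
    xo_modifier: XOModifier | None = None


@dataclass(frozen=True)
class SimulationConfig:
    genome: GenomeSpec
    n_individuals: int = 94
    generation: float = 4  # k; math.inf = fully inbred (riself)
    variants: StructuralVariantSpec = StructuralVariantSpec()
    selection: SelectionSpec = SelectionSpec()
    missing_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0
    population_id: str = "sim"
    parents: tuple = ("Par", "other")
    ancestral_group: str | None = None

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        k = self.generation
        if not ((isinstance(k, (int, float)) and (k == math.inf or int(k) == k and k >= 2))):
            raise ValueError(f"invalid generation {k!r}")
        for r in (self.missing_rate, self.error_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth serialized next to the simulated genotypes so tests and
    acceptance checks never re-derive it."""

    population_id: str
    true_map: dict  # chrom -> {"markers": [...], "positions": [...]} post-rearrangement
    assigned_chromosome: dict  # marker -> a-priori (pre-rearrangement) chromosome
    true_genotypes: np.ndarray  # pre-noise calls, markers x individuals
    xo_counts: np.ndarray  # realised ancestry junctions per line (both haplotypes)
    translocations: list
    inversions: list
    sdl: list
    xo_modifier: dict | None
    marker_names: list

    def to_json(self, path):
        obj = {
            "population_id": self.population_id,
            "true_map": self.true_map,
            "assigned_chromosome": self.assigned_chromosome,
            "true_genotypes": self.true_genotypes.tolist(),
            "xo_counts": self.xo_counts.tolist(),
            "translocations": self.translocations,
            "inversions": self.inversions,
            "sdl": self.sdl,
            "xo_modifier": self.xo_modifier,
            "marker_names": self.marker_names,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path):
        obj = json.loads(Path(path).read_text())
        obj["true_genotypes"] = np.array(obj["true_genotypes"], dtype=np.int8)
        obj["xo_counts"] = np.array(obj["xo_counts"])
        return cls(**obj)


# --- genome construction -----------------------------------------------------

def wheat_like_genome(seed=0, markers_ab=(8, 31), markers_d=(2, 8),
                      length_range=(90.0, 160.0), d_length_range=(80.0, 130.0)):
    """A 21-chromosome hexaploid-wheat-like marker layout: chromosomes
    1A..7D with moderately dense A/B genomes and sparse D-genome coverage,
    mirroring array-genotyped landrace populations."""
    rng = np.random.default_rng(seed)
    chroms = []
    for num in range(1, 8):
        for genome in "ABD":
            name = f"{num}{genome}"
            if genome == "D":
                n = int(rng.integers(markers_d[0], markers_d[1] + 1))
                length = float(rng.uniform(*d_length_range))
            else:
                n = int(rng.integers(markers_ab[0], markers_ab[1] + 1))
                length = float(rng.uniform(*length_range))
            pos = np.sort(rng.uniform(0, length, size=n))
            # enforce strict increase (collisions vanishingly rare)
            pos = np.maximum.accumulate(pos + np.arange(n) * 1e-9)
            names = tuple(f"M{name}_{i:03d}" for i in range(n))
            chroms.append(ChromosomeSpec(name, length, tuple(pos), names))
    return GenomeSpec(tuple(chroms))


def uniform_genome(n_chromosomes=5, n_markers=12, length_cM=120.0, prefix="C"):
    """Small regular genome for tests: evenly spaced markers."""
    chroms = []
    for c in range(n_chromosomes):
        name = f"{prefix}{c + 1}"
        pos = np.linspace(0, length_cM, n_markers)
        if n_markers == 1:
            pos = np.array([length_cM / 2])
        names = tuple(f"M{name}_{i:03d}" for i in range(n_markers))
        chroms.append(ChromosomeSpec(name, length_cM, tuple(pos), names))
    return GenomeSpec(tuple(chroms))


def _apply_variants(genome: GenomeSpec, variants: StructuralVariantSpec) -> GenomeSpec:
    """Physical (rearranged) genome of a variant-carrier population."""
    layout = {
        c.name: list(zip(c.marker_names, c.positions)) for c in genome.chromosomes
    }
    lengths = {c.name: c.length_cM for c in genome.chromosomes}

    for t in variants.translocations:
        a, b = t.segment
        seg_len = b - a
        donor = layout[t.donor]
        moved = [(n, p) for n, p in donor if a <= p <= b]
        layout[t.donor] = [(n, p) for n, p in donor if not (a <= p <= b)]
        p0 = t.insertion_point
        if t.reciprocal:
            # swap with the equal-length recipient segment starting at p0
            rec = layout[t.recipient]
            back = [(n, p) for n, p in rec if p0 <= p <= p0 + seg_len]
            layout[t.recipient] = [(n, p) for n, p in rec if not (p0 <= p <= p0 + seg_len)]
            layout[t.donor].extend((n, a + (p - p0)) for n, p in back)
            layout[t.recipient].extend((n, p0 + (p - a)) for n, p in moved)
        else:
            # insert, shifting downstream recipient markers by the segment length
            rec = [(n, p if p < p0 else p + seg_len) for n, p in layout[t.recipient]]
            rec.extend((n, p0 + (p - a)) for n, p in moved)
            layout[t.recipient] = rec
            lengths[t.recipient] += seg_len

    for inv in variants.inversions:
        a, b = inv.interval
        layout[inv.chromosome] = [
            (n, a + b - p if a <= p <= b else p) for n, p in layout[inv.chromosome]
        ]

    chroms = []
    for c in genome.chromosomes:
        entries = sorted(layout[c.name], key=lambda np_: (np_[1], np_[0]))
        pos = np.array([p for _, p in entries])
        pos = np.maximum.accumulate(pos + np.arange(len(pos)) * 1e-9)
        chroms.append(
            ChromosomeSpec(
                c.name,
                max(lengths[c.name], float(pos[-1]) if len(pos) else 0.0),
                tuple(pos),
                tuple(n for n, _ in entries),
            )
        )
    return GenomeSpec(tuple(chroms))


# --- meiosis and population simulation ---------------------------------------

def simulate_meiosis(diplotype, genome: GenomeSpec, rng, extra_xo: float = 0.0):
    """One gamete from a diplotype.

    ``diplotype`` maps chromosome name -> (hap1, hap2), uint8 allele arrays
    over that chromosome's markers.  Crossover counts are Poisson with mean
    length/100 plus ``extra_xo`` (the crossover-modifier boost, applied to
    every chromosome of positive length); positions are uniform (no
    interference).  Returns (gamete dict, total crossover count drawn).
    """
    gamete = {}
    n_xo_total = 0
    for c in genome.chromosomes:
        h1, h2 = diplotype[c.name]
        mean = c.length_cM / 100.0
        if extra_xo and c.length_cM > 0:
            mean += extra_xo
        n_xo = rng.poisson(mean) if mean > 0 else 0
        n_xo_total += n_xo
        start = rng.integers(2)
        if len(c.positions) == 0:
            gamete[c.name] = np.empty(0, dtype=np.uint8)
            continue
        pos = np.asarray(c.positions)
        if n_xo == 0:
            phase = np.full(len(pos), start)
        else:
            xo = np.sort(rng.uniform(0, c.length_cM, size=n_xo))
            phase = (start + np.searchsorted(xo, pos)) % 2
        gamete[c.name] = np.where(phase == 0, h1, h2).astype(np.uint8)
    return gamete, n_xo_total


def _nearest_marker(genome: GenomeSpec, chromosome: str, position: float):
    c = genome.chromosome(chromosome)
    if not len(c.positions):
        raise ValueError(f"no markers on {chromosome}")
    i = int(np.argmin(np.abs(np.asarray(c.positions) - position)))
    return c.marker_names[i], i


def simulate_ssd_population(config: SimulationConfig):
    """Simulate one SSD population and return (GenotypeMatrix, TruthRecord).

    F1 is heterozygous everywhere; each line is advanced independently
    (one offspring per generation) to F_k, with SDL viability selection by
    rejection sampling.  Observation noise is applied afterwards; the truth
    record keeps the pre-noise calls.
    """
    rng = np.random.default_rng(config.seed)
    genome = _apply_variants(config.genome, config.variants)
    k = config.generation
    inbred = math.isinf(k)
    n_rounds = _INBRED_ROUNDS if inbred else int(k) - 1  # meioses from F1 to F_k

    sdl_idx = [
        (s.chromosome, _nearest_marker(genome, s.chromosome, s.position_cM)[1],
         np.asarray(s.weights, float))
        for s in config.selection.sdl
    ]
    mod = config.selection.xo_modifier
    mod_idx = None
    if mod is not None:
        mod_idx = (mod.chromosome, _nearest_marker(genome, mod.chromosome, mod.position_cM)[1])

    f1 = {
        c.name: (
            np.zeros(len(c.marker_names), dtype=np.uint8),
            np.ones(len(c.marker_names), dtype=np.uint8),
        )
        for c in genome.chromosomes
    }

    lines, xo_counts = [], []
    for _ in range(config.n_individuals):
        indiv = f1
        for _gen in range(n_rounds):
            extra = 0.0
            if mod is not None:
                chrom, mi = mod_idx
                h1, h2 = indiv[chrom]
                extra = mod.effect * (int(h1[mi]) + int(h2[mi]))
            for attempt in range(1000):
                g1, _ = simulate_meiosis(indiv, genome, rng, extra_xo=extra)
                g2, _ = simulate_meiosis(indiv, genome, rng, extra_xo=extra)
                child = {c: (g1[c], g2[c]) for c in g1}
                ok = True
                for chrom, mi, w in sdl_idx:
                    geno = int(child[chrom][0][mi]) + int(child[chrom][1][mi])
                    wmax = w.max()
                    if rng.random() >= w[geno] / wmax:
                        ok = False
                        break
                if ok:
                    break
            else:
                raise RuntimeError(
                    "selection weights rejected 1000 consecutive offspring; "
                    "no viable genotype class reachable"
                )
            indiv = child
        if inbred:
            # resolve residual heterozygous sites by a fair coin per site
            for chrom in indiv:
                h1, h2 = indiv[chrom]
                het = h1 != h2
                if het.any():
                    pick = rng.integers(2, size=int(het.sum())).astype(np.uint8)
                    allele = np.where(pick == 0, h1[het], h2[het])
                    h1 = h1.copy(); h2 = h2.copy()
                    h1[het] = allele
                    h2[het] = allele
                    indiv[chrom] = (h1, h2)
        lines.append(indiv)
        n_junc = 0
        for c in genome.chromosomes:
            h1, h2 = indiv[c.name]
            if len(h1) > 1:
                n_junc += int(np.sum(h1[1:] != h1[:-1])) + int(np.sum(h2[1:] != h2[:-1]))
        xo_counts.append(n_junc)

    marker_names = [n for c in genome.chromosomes for n in c.marker_names]
    assigned = config.genome.assigned_chromosome()
    calls = np.empty((len(marker_names), config.n_individuals), dtype=np.int8)
    row = 0
    for c in genome.chromosomes:
        for mi in range(len(c.marker_names)):
            for j, line in enumerate(lines):
                h1, h2 = line[c.name]
                calls[row, j] = int(h1[mi]) + int(h2[mi])
            row += 1

    markers = [MarkerInfo(name=n, assigned_chromosome=assigned[n]) for n in marker_names]
    individuals = [f"{config.population_id}_{i + 1:03d}" for i in range(config.n_individuals)]
    matrix = GenotypeMatrix(
        population_id=config.population_id,
        markers=markers,
        individuals=individuals,
        calls=calls.copy(),
        generation=config.generation,
        parents=config.parents,
        ancestral_group=config.ancestral_group,
    )

    truth = TruthRecord(
        population_id=config.population_id,
        true_map={
            c.name: {"markers": list(c.marker_names),
                     "positions": [float(p) for p in c.positions]}
            for c in genome.chromosomes
        },
        assigned_chromosome=assigned,
        true_genotypes=calls,
        xo_counts=np.array(xo_counts),
        translocations=[asdict(t) for t in config.variants.translocations],
        inversions=[asdict(v) for v in config.variants.inversions],
        sdl=[asdict(s) for s in config.selection.sdl],
        xo_modifier=asdict(mod) if mod is not None else None,
        marker_names=marker_names,
    )

    if config.missing_rate or config.error_rate:
        matrix = apply_observation_noise(
            matrix, config.missing_rate, config.error_rate, rng
        )
    return matrix, truth


def apply_observation_noise(matrix: GenotypeMatrix, missing_rate, error_rate, rng):
    """Independent per-call dropout and miscalls: each call is set missing
    with ``missing_rate``; each surviving call is replaced by one of the two
    other codes (uniformly) with ``error_rate``.  Returns a new matrix."""
    for r in (missing_rate, error_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must lie in [0, 1]")
    calls = matrix.calls.copy()
    obs = calls != CODE_NA
    if missing_rate:
        drop = obs & (rng.random(calls.shape) < missing_rate)
        calls[drop] = CODE_NA
        obs = obs & ~drop
    if error_rate:
        flip = obs & (rng.random(calls.shape) < error_rate)
        shift = rng.integers(1, 3, size=calls.shape)
        calls[flip] = (calls[flip] + shift[flip]) % 3
    out = GenotypeMatrix(
        population_id=matrix.population_id,
        markers=list(matrix.markers),
        individuals=list(matrix.individuals),
        calls=calls,
        generation=matrix.generation,
        parents=matrix.parents,
        ancestral_group=matrix.ancestral_group,
    )
    return out
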