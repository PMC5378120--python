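"""Reading, writing and validating genotype matrices and genetic maps.

On-disk formats are plain text:

* genotype CSV (rotated / "csvr-like"): ``#``-prefixed metadata header lines,
  then a header row ``marker,chrom,<ind1>,<ind2>,...`` and one row per marker
  with its name, a-priori chromosome assignment and genotype calls
  (default symbols A/H/B/-);
* genetic map TSV with columns marker, lg, chromosome, position_cM;
* optional panel metadata YAML (population -> generation, parents,
  ancestral group) for panels stored as one file per population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarkerInfo",
    "GenotypeMatrix",
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "validate_matrix",
]

CODE_AA, CODE_AB, CODE_BB, CODE_NA = 0, 1, 2, -1

DEFAULT_SYMBOLS = {"A": CODE_AA, "H": CODE_AB, "B": CODE_BB, "-": CODE_NA, "NA": CODE_NA}


@dataclass(frozen=True)
class MarkerInfo:
    """Per-marker metadata; the a-priori chromosome assignment comes from
    array annotation and may disagree with the mapped position (the basis of
    the mapped-translocation caller)."""

    name: str
    assigned_chromosome: str | None = None
    assay_type: str = "SNP"


@dataclass
class GenotypeMatrix:
    """Genotype calls for one biparental population.

    ``calls`` is an int8 array of shape (markers, individuals) with codes
    0=AA (reference-parent homozygote), 1=AB, 2=BB, -1=missing.
    ``generation`` is the selfing generation k (4, 5, 6) or ``math.inf`` for
    fully inbred lines.
    """

    population_id: str
    markers: list[MarkerInfo]
    individuals: list[str]
    calls: np.ndarray
    generation: float = 4
    parents: tuple[str, str] = ("Par", "other")
    ancestral_group: str | None = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.individuals)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.individuals)} individuals"
            )
        if len(self.individuals) < 2:
            raise ValueError("a population needs at least 2 individuals")
        k = self.generation
        if not (k in (4, 5, 6) or (isinstance(k, float) and math.isinf(k)) or
                (isinstance(k, int) and k >= 2)):
            raise ValueError(f"invalid generation {k!r}")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate marker names: {', '.join(dups)}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == CODE_NA).mean(axis=1)

    def subset_markers(self, names) -> "GenotypeMatrix":
        index = {m.name: i for i, m in enumerate(self.markers)}
        idx = [index[n] for n in names]
        return replace(
            self,
            markers=[self.markers[i] for i in idx],
            calls=self.calls[idx],
        )


def _parse_generation(value):
    s = str(value).strip().lower()
    if s in ("inf", "infinity", "riself"):
        return math.inf
    return int(s)


def write_genotypes(matrix: GenotypeMatrix, path, symbols=None):
    """Write a rotated genotype CSV with a ``#`` metadata header."""
    inv = {v: k for k, v in (symbols or DEFAULT_SYMBOLS).items()}
    inv[CODE_NA] = "-"
    path = Path(path)
    gen = "inf" if math.isinf(matrix.generation) else int(matrix.generation)
    with path.open("w") as fh:
        fh.write(f"# namkit genotype matrix\n")
        fh.write(f"# population: {matrix.population_id}\n")
        fh.write(f"# generation: {gen}\n")
        fh.write(f"# parents: {matrix.parents[0]},{matrix.parents[1]}\n")
        if matrix.ancestral_group is not None:
            fh.write(f"# ancestral_group: {matrix.ancestral_group}\n")
        fh.write("marker,chrom," + ",".join(matrix.individuals) + "\n")
        for m, row in zip(matrix.markers, matrix.calls):
            chrom = m.assigned_chromosome or ""
            fh.write(m.name + "," + chrom + "," + ",".join(inv[int(c)] for c in row) + "\n")


def read_genotypes(path, symbols=None) -> GenotypeMatrix:
    """Read a rotated genotype CSV written by :func:`write_genotypes`.

    Unknown genotype symbols, ragged rows and duplicate marker names raise
    ``ValueError`` naming the offending cell or marker.
    """
    symbols = dict(symbols or DEFAULT_SYMBOLS)
    path = Path(path)
    meta = {"population": path.stem, "generation": "4", "parents": "Par,other"}
    rows, header = [], None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                continue
            fields = line.split(",")
            if header is None:
                if fields[:2] != ["marker", "chrom"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header 'marker,chrom,...'"
                    )
                header = fields
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: ragged row for marker {fields[0]!r} "
                    f"({len(fields)} fields, expected {len(header)})"
                )
            rows.append((lineno, fields))
    if header is None:
        raise ValueError(f"{path}: no header row found")
    individuals = header[2:]
    markers, calls, seen = [], [], set()
    for lineno, fields in rows:
        name, chrom = fields[0], fields[1] or None
        if name in seen:
            raise ValueError(f"{path}:{lineno}: duplicate marker name {name!r}")
        seen.add(name)
        markers.append(MarkerInfo(name=name, assigned_chromosome=chrom))
        row = []
        for ind, sym in zip(individuals, fields[2:]):
            sym = sym.strip()
            if sym not in symbols:
                raise ValueError(
                    f"{path}:{lineno}: unknown genotype code {sym!r} for "
                    f"marker {name!r}, individual {ind!r}"
                )
            row.append(symbols[sym])
        calls.append(row)
    parents = tuple(p.strip() for p in meta["parents"].split(","))[:2]
    return GenotypeMatrix(
        population_id=meta["population"],
        markers=markers,
        individuals=individuals,
        calls=np.array(calls, dtype=np.int8),
        generation=_parse_generation(meta["generation"]),
        parents=parents,  # type: ignore[arg-type]
        ancestral_group=meta.get("ancestral_group"),
    )


def write_map(gmap, path):
    """Write a genetic map (anything exposing ``lgs`` with ordered markers
    and positions, or a DataFrame) as a TSV with header
    marker/lg/chromosome/position_cM."""
    if isinstance(gmap, pd.DataFrame):
        df = gmap[["marker", "lg", "chromosome", "position_cM"]]
    else:
        recs = []
        for lg in gmap.lgs:
            for name, pos in zip(lg.markers, lg.positions):
                recs.append((name, lg.lg_id, lg.chromosome or "", float(pos)))
        df = pd.DataFrame(recs, columns=["marker", "lg", "chromosome", "position_cM"])
    df.to_csv(path, sep="\t", index=False)


def read_map(path) -> pd.DataFrame:
    """Read a map TSV; positions must be numeric and non-decreasing within
    each linkage group (in file order)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"marker": str, "lg": str, "chromosome": str})
    except ValueError as exc:
        raise ValueError(f"{path}: failed to parse map TSV: {exc}") from exc
    required = {"marker", "lg", "chromosome", "position_cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: map TSV must have columns {sorted(required)}")
    pos = pd.to_numeric(df["position_cM"], errors="coerce")
    if pos.isna().any():
        bad = df.loc[pos.isna()].index[0] + 2  # +2: header + 1-based
        raise ValueError(f"{path}:{bad}: non-numeric cM position")
    df["position_cM"] = pos
    for lg_id, grp in df.groupby("lg", sort=False):
        d = np.diff(grp["position_cM"].to_numpy())
        if (d < 0).any():
            raise ValueError(f"{path}: decreasing positions within LG {lg_id!r}")
    df["chromosome"] = df["chromosome"].fillna("")
    return df


def validate_matrix(matrix: GenotypeMatrix, max_missing: float = 0.10):
    """Drop markers with missing fraction strictly above ``max_missing`` and
    flag markers with zero heterozygote calls in non-inbred populations.

    Returns ``(kept_matrix, report)`` where ``report`` is a DataFrame with
    one row per input marker (columns: marker, missing_fraction, dropped,
    no_het).  No-het markers are kept for mapping (with a collapsed
    likelihood) but are excluded later from segregation-distortion and
    estRF translocation scans.
    """
    miss = matrix.missing_fraction()
    dropped = miss > max_missing
    non_inbred = not math.isinf(matrix.generation)
    no_het = np.zeros(matrix.n_markers, dtype=bool)
    if non_inbred:
        no_het = (matrix.calls == CODE_AB).sum(axis=1) == 0
    report = pd.DataFrame(
        {
            "marker": matrix.marker_names,
            "missing_fraction": miss,
            "dropped": dropped,
            "no_het": no_het & ~dropped,
        }
    )
    kept = matrix.subset_markers(
        [m for m, d in zip(matrix.marker_names, dropped) if not d]
    )
    return kept, report
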