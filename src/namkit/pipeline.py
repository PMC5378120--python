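"""Panel-level orchestration: maps -> consensus -> comparisons ->
segregation distortion -> translocations -> crossover QTL, with a summary
report of per-population characteristics (population size, linked and
cosegregating markers, map length, linkage-group count, missing
chromosomes, incongruent and expanded groups, distortion percentages and
directions, translocation counts, mean crossovers, QTL counts) plus an
aggregate row.

Populations failing the allele-ratio QC are retained in the per-population
rows but flagged and excluded from the aggregate statistics.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import io as nio
from .compare import compare_maps
from .consensus import build_consensus
from .linkage import build_map, GeneticMap
from .segdist import impute_genotypes, segdist_scan, qc_allele_ratio, sdl_hotspots
from .simulate import SimulationConfig, simulate_ssd_population
from .transloc import (mapped_translocations, estrf_translocations,
                       classify_and_merge)
from .xo_qtl import xo_trait, qtl_scan, multiple_qtl_model, project_common_qtl

__all__ = ["run_panel", "missing_chromosomes", "PanelResult"]


def missing_chromosomes(gmap: GeneticMap, expected) -> list:
    """Expected chromosomes with no linkage group labelled to them."""
    present = gmap.chromosomes
    return [c for c in expected if c not in present]


@dataclasses.dataclass
class PanelResult:
    report: pd.DataFrame
    maps: dict
    consensus: dict
    mdr: pd.DataFrame
    order: pd.DataFrame
    sdl: dict
    hotspots_markers: pd.DataFrame
    translocations: pd.DataFrame
    translocation_types: pd.DataFrame
    qtl: dict
    common_qtl: pd.DataFrame
    qc: dict
    truth: dict | None = None


def _table1_row(pop, gmap, expected_chroms, mdr_df, order_df, sdl_df,
                transloc_counts, trait, qtls, qc):
    missing = missing_chromosomes(gmap, expected_chroms) if expected_chroms else []
    pop_mdr = mdr_df[mdr_df["population"] == pop] if len(mdr_df) else mdr_df
    pop_ord = order_df[order_df["population"] == pop] if len(order_df) else order_df
    n_sig = int(sdl_df["significant"].sum()) if len(sdl_df) else 0
    n_tested = len(sdl_df)
    sig = sdl_df[sdl_df["significant"]] if len(sdl_df) else sdl_df
    return dict(
        population=pop,
        n_individuals=len(trait.individuals),
        linked_markers=gmap.n_linked_markers,
        cosegregating_markers=gmap.n_cosegregating_markers,
        map_length_cM=round(gmap.total_length_cM, 1),
        n_LGs=len(gmap.lgs),
        missing_chromosomes=",".join(missing),
        n_incongruent_LGs=int((pop_ord["category"] == "incongruent").sum())
        if len(pop_ord) else 0,
        n_expanded_LGs=int(pop_mdr["expanded"].sum()) if len(pop_mdr) else 0,
        pct_SDL=round(100.0 * n_sig / n_tested, 2) if n_tested else 0.0,
        n_par_excess_SDL=int((sig["direction"] == "Par_excess").sum()) if n_sig else 0,
        n_other_excess_SDL=int((sig["direction"] == "other_excess").sum()) if n_sig else 0,
        n_translocations=int(transloc_counts.get(pop, 0)),
        mean_crossovers=round(trait.mean, 1),
        n_crossover_QTL=len(qtls),
        qc_flagged=qc["flagged"],
    )


def run_panel(populations, expected_chromosomes=None, seed=0,
              lod_min=3.0, rf_max=0.3, split_gap_cM=35.0,
              transloc_lod=7.0, sdl_alpha=0.05, qtl_lod=2.0,
              min_common=7, out_dir=None) -> PanelResult:
    """Run the full workflow over a panel.

    ``populations``: iterable of GenotypeMatrix, SimulationConfig, or paths
    to genotype CSVs.  Simulation configs are simulated (their truth is kept
    in ``result.truth``); a panel-level ``seed`` offsets each config's own
    seed deterministically.  Returns a :class:`PanelResult`; when
    ``out_dir`` is given all stage tables are also written as TSVs.
    """
    matrices, truth = [], {}
    for i, pop in enumerate(populations):
        if isinstance(pop, SimulationConfig):
            pop = dataclasses.replace(pop, seed=(pop.seed + seed * 100_003 + i) % (2**31))
            m, tr = simulate_ssd_population(pop)
            truth[m.population_id] = tr
        elif isinstance(pop, (str, Path)):
            try:
                m = nio.read_genotypes(pop)
            except ValueError as exc:
                raise ValueError(f"stage=read population_file={pop}: {exc}") from exc
        else:
            m = pop
        matrices.append(m)

    maps, ests, sdl_tables, qc, traits, qtl_by_pop = {}, {}, {}, {}, {}, {}
    calls = []
    for m in matrices:
        pid = m.population_id
        try:
            gmap, est, _report = build_map(
                m, lod_min=lod_min, rf_max=rf_max, split_gap_cM=split_gap_cM)
            maps[pid] = gmap
            ests[pid] = est
            qc[pid] = qc_allele_ratio(m)
            imp = impute_genotypes(m, gmap)
            sdl_tables[pid] = segdist_scan(imp, alpha=sdl_alpha)
            assignments = {mk.name: mk.assigned_chromosome for mk in m.markers}
            calls += mapped_translocations(gmap, assignments)
            chrom_of = {}
            for lg in gmap.lgs:
                for mk in lg.markers:
                    chrom_of[mk] = lg.chromosome
            calls += estrf_translocations(
                est, chrom_of, lod_threshold=transloc_lod, population=pid)
            trait = xo_trait(m, gmap, imp)
            traits[pid] = trait
            _curve, putative = qtl_scan(trait, imp, gmap, lod_min=qtl_lod,
                                        parents=m.parents)
            qtl_by_pop[pid] = multiple_qtl_model(
                putative, trait, imp, threshold=qtl_lod, gmap=gmap)
        except Exception as exc:
            raise RuntimeError(f"stage=per-population population={pid}: {exc}") from exc

    consensus = build_consensus(maps.values())
    mdr_df, order_df = compare_maps(maps.values(), consensus,
                                    min_common=min_common)
    merged_df, types_df, pop_counts = classify_and_merge(calls)
    hot_markers, _hot_bins = sdl_hotspots(sdl_tables, consensus)
    common = project_common_qtl(qtl_by_pop, consensus)

    rows = [
        _table1_row(pid, maps[pid], expected_chromosomes, mdr_df, order_df,
                    sdl_tables[pid], pop_counts, traits[pid], qtl_by_pop[pid],
                    qc[pid])
        for pid in maps
    ]
    report = pd.DataFrame(rows)
    # aggregate over QC-passing populations
    numeric = [c for c in report.columns
               if report[c].dtype.kind in "if" and c != "qc_flagged"]
    agg_base = report[~report["qc_flagged"]] if len(report) else report
    if len(agg_base):
        summary = {c: round(float(agg_base[c].mean()), 2) for c in numeric}
        summary["population"] = "MEAN"
        report = pd.concat([report, pd.DataFrame([summary])], ignore_index=True)

    result = PanelResult(
        report=report, maps=maps, consensus=consensus, mdr=mdr_df,
        order=order_df, sdl=sdl_tables, hotspots_markers=hot_markers,
        translocations=merged_df, translocation_types=types_df,
        qtl=qtl_by_pop, common_qtl=common, qc=qc,
        truth=truth or None,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PanelResult, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out_dir / "panel_report.tsv", sep="\t", index=False)
    result.mdr.to_csv(out_dir / "mdr.tsv", sep="\t", index=False)
    result.order.to_csv(out_dir / "order_comparison.tsv", sep="\t", index=False)
    result.translocations.to_csv(out_dir / "translocations.tsv", sep="\t", index=False)
    result.translocation_types.to_csv(out_dir / "translocation_types.tsv",
                                      sep="\t", index=False)
    result.hotspots_markers.to_csv(out_dir / "sdl_hotspots.tsv", sep="\t", index=False)
    result.common_qtl.to_csv(out_dir / "common_qtl.tsv", sep="\t", index=False)
    for pid, gmap in result.maps.items():
        nio.write_map(gmap, out_dir / f"map_{pid}.tsv")
    for pid, df in result.sdl.items():
        df.to_csv(out_dir / f"sdl_{pid}.tsv", sep="\t", index=False)
    cons_rows = []
    for chrom, cmap in result.consensus.items():
        for m, p in zip(cmap.markers, cmap.positions):
            cons_rows.append(dict(marker=m, lg=chrom, chromosome=chrom,
                                  position_cM=float(p), K=cmap.K))
    pd.DataFrame(cons_rows).to_csv(out_dir / "consensus.tsv", sep="\t", index=False)
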