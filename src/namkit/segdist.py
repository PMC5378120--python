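"""Genotype imputation and segregation-distortion scanning.

Imputation runs a three-state (AA/AB/BB) forward-backward pass per
individual along each mapped linkage group: initial probabilities are the
generation-k selfing marginals, transition matrices the conditionals of the
two-locus selfing distribution at the adjacent-interval recombination
fraction, and emissions allow a small genotyping-error probability.  Hard
calls take the state of maximal posterior ("max-marginal"); calls whose
maximum posterior falls below a confidence floor are left missing.

The distortion scan tests each marker's hard-call counts against the
generation-k Mendelian expectation (0.4375/0.125/0.4375 at F4) with a
chi-square goodness-of-fit test and Benjamini-Hochberg adjustment across
the population's markers.  Markers scored without a single heterozygote in
non-inbred populations are excluded (their heterozygote class was likely
absorbed into a homozygote cluster during scoring).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import genetics
from .io import GenotypeMatrix, CODE_NA
from .linkage import GeneticMap

__all__ = [
    "ImputedMatrix",
    "impute_genotypes",
    "segdist_scan",
    "qc_allele_ratio",
    "sdl_hotspots",
]


@dataclass
class ImputedMatrix:
    """Posterior genotype probabilities and max-marginal hard calls, in the
    map's marker order (markers x individuals x 3)."""

    population_id: str
    markers: list
    individuals: list
    posteriors: np.ndarray
    calls: np.ndarray
    error_prob: float
    generation: float

    @property
    def n_markers(self):
        return len(self.markers)


def _transition(r, k):
    joint = genetics.joint_selfing(r, k)
    marg = joint.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(marg > 0, joint / marg, 0.0)
    # unreachable rows (e.g. AB at k=inf) get an uninformative fallback
    bad = ~np.isfinite(t).all(axis=1) | (t.sum(axis=1) == 0)
    t[bad] = genetics.marginal_selfing(k)
    return t


def impute_genotypes(matrix: GenotypeMatrix, gmap: GeneticMap,
                     error_prob=1e-4, min_posterior=0.95) -> ImputedMatrix:
    """Forward-backward imputation of every mapped marker.

    ``min_posterior``: hard calls with max posterior below this are set
    missing; pass None to always call.  Markers absent from the map raise
    KeyError when accessed via the returned object (they are simply not
    imputed); markers on the map but absent from the matrix raise
    ValueError.
    """
    k = matrix.generation
    prior = genetics.marginal_selfing(k)
    index = {m: i for i, m in enumerate(matrix.marker_names)}
    n = matrix.n_individuals

    out_markers, out_post, out_calls = [], [], []
    for lg in gmap.lgs:
        try:
            rows = [index[m] for m in lg.markers]
        except KeyError as exc:
            raise ValueError(f"map marker {exc} missing from genotype matrix")
        obs = matrix.calls[rows]  # (M, N)
        m = len(rows)
        # emission: (M, N, 3)
        emit = np.full((m, n, 3), 1.0 / 3.0)
        scored = obs != CODE_NA
        emit[scored] = error_prob / 2
        emit[scored, obs[scored]] = 1 - error_prob
        r_adj = genetics.kosambi_inverse(np.diff(lg.positions)) if m > 1 else []
        trans = [_transition(r, k) for r in r_adj]

        alpha = np.empty((m, n, 3))
        scale = np.empty((m, n))
        a = prior[None, :] * emit[0]
        scale[0] = a.sum(axis=1)
        alpha[0] = a / scale[0][:, None]
        for t in range(1, m):
            a = (alpha[t - 1] @ trans[t - 1]) * emit[t]
            scale[t] = a.sum(axis=1)
            scale[t][scale[t] == 0] = 1.0
            alpha[t] = a / scale[t][:, None]
        beta = np.empty((m, n, 3))
        beta[-1] = 1.0
        for t in range(m - 2, -1, -1):
            b = (beta[t + 1] * emit[t + 1]) @ trans[t].T
            s = b.sum(axis=1, keepdims=True)
            s[s == 0] = 1.0
            beta[t] = b / s
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        calls = post.argmax(axis=2).astype(np.int8)
        if min_posterior is not None:
            calls[post.max(axis=2) < min_posterior] = CODE_NA
        out_markers.extend(lg.markers)
        out_post.append(post)
        out_calls.append(calls)

    return ImputedMatrix(
        population_id=matrix.population_id,
        markers=out_markers,
        individuals=list(matrix.individuals),
        posteriors=np.concatenate(out_post) if out_post else np.empty((0, n, 3)),
        calls=np.concatenate(out_calls) if out_calls else np.empty((0, n), np.int8),
        error_prob=error_prob,
        generation=k,
    )


def segdist_scan(imputed: ImputedMatrix, alpha=0.05, exclude_no_het=True,
                 min_informative=20) -> pd.DataFrame:
    """Per-marker chi-square segregation-distortion test with BH adjustment.

    Returns a DataFrame with one row per tested marker: observed counts,
    chi2, raw and adjusted p, significance at ``alpha``, distortion
    direction from the homozygote counts, and an ``underpowered`` flag for
    markers with fewer than ``min_informative`` scored calls.
    """
    k = imputed.generation
    inbred = isinstance(k, float) and math.isinf(k)
    expected = genetics.marginal_selfing(k)
    rows = []
    for i, marker in enumerate(imputed.markers):
        calls = imputed.calls[i]
        n_aa = int(np.sum(calls == 0))
        n_ab = int(np.sum(calls == 1))
        n_bb = int(np.sum(calls == 2))
        total = n_aa + n_ab + n_bb
        if total == 0:
            continue
        if exclude_no_het and not inbred and n_ab == 0:
            continue
        if inbred:
            obs = np.array([n_aa, n_bb], float)
            exp = np.array([0.5, 0.5]) * (n_aa + n_bb)
        else:
            obs = np.array([n_aa, n_ab, n_bb], float)
            exp = expected * total
        chi2 = float(np.sum((obs - exp) ** 2 / exp))
        p = float(stats.chi2.sf(chi2, df=len(obs) - 1))
        rows.append(
            dict(marker=marker, n_AA=n_aa, n_AB=n_ab, n_BB=n_bb,
                 chi2=chi2, p_raw=p,
                 direction="Par_excess" if n_aa >= n_bb else "other_excess",
                 underpowered=total < min_informative)
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
        df["significant"] = df["p_adj"] < alpha
    else:
        df = pd.DataFrame(columns=["marker", "n_AA", "n_AB", "n_BB", "chi2",
                                   "p_raw", "direction", "underpowered",
                                   "p_adj", "significant"])
    return df


def qc_allele_ratio(matrix: GenotypeMatrix, par_max=0.54, other_min=0.37):
    """Population-level allele-ratio quality control.

    Computes the mean per-locus homozygote fraction for each parent and a
    pooled chi-square against the generation expectation; flags populations
    whose reference-parent homozygote ratio is >= ``par_max`` or whose
    other-parent ratio is <= ``other_min`` (0.4375 expected at F4, 0.5 when
    inbred).
    """
    k = matrix.generation
    expected = genetics.marginal_selfing(k)
    calls = matrix.calls
    scored = calls != CODE_NA
    n_scored = scored.sum(axis=1)
    ok = n_scored > 0
    with np.errstate(invalid="ignore"):
        frac_aa = np.where(ok, (calls == 0).sum(axis=1) / n_scored, np.nan)
        frac_bb = np.where(ok, (calls == 2).sum(axis=1) / n_scored, np.nan)
    mean_aa = float(np.nanmean(frac_aa))
    mean_bb = float(np.nanmean(frac_bb))
    tot = np.array([(calls == g).sum() for g in (0, 1, 2)], float)
    if math.isinf(k):
        obs = tot[[0, 2]]
        exp = np.array([0.5, 0.5]) * obs.sum()
    else:
        obs = tot
        exp = expected * tot.sum()
    chi2 = float(np.sum((obs - exp) ** 2 / exp)) if tot.sum() else 0.0
    p = float(stats.chi2.sf(chi2, df=len(obs) - 1)) if tot.sum() else 1.0
    flagged = mean_aa >= par_max or mean_bb <= other_min
    return dict(population=matrix.population_id, mean_par_homozygote=mean_aa,
                mean_other_homozygote=mean_bb, chi2=chi2, p=p, flagged=flagged)


def sdl_hotspots(sdl_tables: dict, consensus: dict, min_pops=3, bin_cM=10.0):
    """Cross-population distortion hotspots on the consensus scale.

    ``sdl_tables``: {population: segdist_scan DataFrame}; ``consensus``:
    {chromosome: ConsensusMap}.  Returns (per_marker, per_bin) DataFrames;
    hotspots are markers (or 10 cM bins) significant in >= ``min_pops``
    populations.  Markers absent from the consensus are skipped.
    """
    position = {}
    for chrom, cmap in consensus.items():
        for m, p in zip(cmap.markers, cmap.positions):
            position[m] = (chrom, float(p))
    per_marker = {}
    for pop, df in sdl_tables.items():
        if not len(df):
            continue
        for _, row in df[df["significant"]].iterrows():
            loc = position.get(row["marker"])
            if loc is None:
                continue
            rec = per_marker.setdefault(
                row["marker"], dict(marker=row["marker"], chromosome=loc[0],
                                    position_cM=loc[1], n_populations=0,
                                    n_par_excess=0, n_other_excess=0))
            rec["n_populations"] += 1
            if row["direction"] == "Par_excess":
                rec["n_par_excess"] += 1
            else:
                rec["n_other_excess"] += 1
    marker_df = pd.DataFrame(per_marker.values()) if per_marker else pd.DataFrame(
        columns=["marker", "chromosome", "position_cM", "n_populations",
                 "n_par_excess", "n_other_excess"])
    if len(marker_df):
        marker_df["hotspot"] = marker_df["n_populations"] >= min_pops
        marker_df = marker_df.sort_values(
            ["chromosome", "position_cM"]).reset_index(drop=True)
        marker_df["bin"] = (marker_df["position_cM"] // bin_cM).astype(int)
        bin_df = (
            marker_df.groupby(["chromosome", "bin"])
            .agg(n_populations=("n_populations", "sum"),
                 n_markers=("marker", "count"),
                 n_par_excess=("n_par_excess", "sum"),
                 n_other_excess=("n_other_excess", "sum"))
            .reset_index()
        )
        bin_df["hotspot"] = bin_df["n_populations"] >= min_pops
    else:
        marker_df["hotspot"] = pd.Series(dtype=bool)
        bin_df = pd.DataFrame(columns=["chromosome", "bin", "n_populations",
                                       "n_markers", "n_par_excess",
                                       "n_other_excess", "hotspot"])
    return marker_df, bin_df
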