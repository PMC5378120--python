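"""Two-locus genetics for selfed recombinant inbred lines.

Everything downstream — recombination-fraction estimation, linkage grouping,
genotype imputation, segregation-distortion expectations — rests on the joint
distribution of two-locus genotypes in an F_k single-seed-descent population.
That distribution is obtained by iterating the selfing recursion on diplotype
(two-haplotype) frequencies starting from a fully heterozygous F1 in coupling
phase, with meiosis producing parental haplotypes at frequency (1-r)/2 and
recombinant haplotypes at r/2 each.

Genotype codes throughout: 0 = AA (reference-parent homozygote), 1 = AB,
2 = BB, -1 = missing.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np

__all__ = [
    "joint_selfing",
    "joint_selfing_exact",
    "marginal_selfing",
    "haldane_waddington_limit",
    "estimate_rf",
    "kosambi",
    "kosambi_inverse",
    "haldane_inverse",
]

# Haplotype indices: 0=AB, 1=Ab, 2=aB, 3=ab (uppercase = reference allele).
_HAP_A = np.array([0, 0, 1, 1])  # allele at locus 1 (0 = reference)
_HAP_B = np.array([0, 1, 0, 1])  # allele at locus 2

# Gamete distribution of an ordered diplotype (h1, h2) is linear in r:
# parental haplotypes h1, h2 each at (1-r)/2, recombinants (h1.A,h2.B) and
# (h2.A,h1.B) each at r/2.  G(r) = _G0 + r * _G1, shape (16, 4).
_G0 = np.zeros((16, 4))
_G1 = np.zeros((16, 4))
for _h1 in range(4):
    for _h2 in range(4):
        _d = 4 * _h1 + _h2
        _G0[_d, _h1] += 0.5
        _G0[_d, _h2] += 0.5
        _G1[_d, _h1] -= 0.5
        _G1[_d, _h2] -= 0.5
        _rec1 = 2 * _HAP_A[_h1] + _HAP_B[_h2]
        _rec2 = 2 * _HAP_A[_h2] + _HAP_B[_h1]
        _G1[_d, _rec1] += 0.5
        _G1[_d, _rec2] += 0.5

# Collapse ordered diplotypes to the 9 two-locus genotype classes
# (gA, gB) with g = number of non-reference alleles (0=AA, 1=AB, 2=BB).
_COLLAPSE = np.zeros((16, 9))
for _h1 in range(4):
    for _h2 in range(4):
        _gA = _HAP_A[_h1] + _HAP_A[_h2]
        _gB = _HAP_B[_h1] + _HAP_B[_h2]
        _COLLAPSE[4 * _h1 + _h2, 3 * _gA + _gB] = 1.0

_F1_STATE = 4 * 0 + 3  # ordered diplotype (AB, ab): coupling-phase F1


def _is_inf(k) -> bool:
    return k is None or (isinstance(k, float) and math.isinf(k))


def joint_selfing(r, k):
    """Joint two-locus genotype distribution at generation F_k.

    Parameters
    ----------
    r : float or array-like
        Per-meiosis recombination fraction(s) in [0, 0.5].
    k : int or inf
        Selfing generation (F1 = fully heterozygous; k-1 meioses). ``inf``
        (or None) gives the fully inbred limit, where the recombinant
        homozygote frequency is the Haldane-Waddington value 2r/(1+2r).

    Returns
    -------
    ndarray of shape r.shape + (3, 3); axes are (genotype at locus 1,
    genotype at locus 2) with codes 0=AA, 1=AB, 2=BB.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    scalar = r.ndim == 0
    rv = np.atleast_1d(r)

    if _is_inf(k):
        big_r = haldane_waddington_limit(rv)
        out = np.zeros(rv.shape + (3, 3))
        out[..., 0, 0] = (1 - big_r) / 2
        out[..., 2, 2] = (1 - big_r) / 2
        out[..., 0, 2] = big_r / 2
        out[..., 2, 0] = big_r / 2
        return out[0] if scalar else out

    if not (isinstance(k, (int, np.integer)) and k >= 2):
        raise ValueError(f"generation k must be an integer >= 2 or inf, got {k!r}")

    gam = _G0[None, :, :] + rv[:, None, None] * _G1  # (R, 16, 4)
    p = np.zeros(rv.shape + (16,))
    p[:, _F1_STATE] = 1.0
    for _ in range(k - 1):
        # selfing is within-individual: offspring diplotype distribution is
        # the p-weighted outer product of each parent's own gamete vector
        p = np.einsum("rd,rdi,rdj->rij", p, gam, gam).reshape(rv.shape + (16,))
    out = (p @ _COLLAPSE).reshape(rv.shape + (3, 3))
    return out[0] if scalar else out


def joint_selfing_exact(r, k):
    """Exact-rational version of :func:`joint_selfing` for integer k.

    ``r`` may be a :class:`fractions.Fraction` (or int); returns a 3x3 nested
    list of Fractions.  Used where printed expectations (e.g. the F4
    homozygote frequency 7/16 = 0.4375) must hold exactly.
    """
    r = Fraction(r)
    if not (0 <= r <= Fraction(1, 2)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    if not (isinstance(k, int) and k >= 2):
        raise ValueError("k must be an integer >= 2")
    half = Fraction(1, 2)
    # gamete distribution per ordered diplotype
    gam = [[Fraction(0)] * 4 for _ in range(16)]
    for h1 in range(4):
        for h2 in range(4):
            d = 4 * h1 + h2
            gam[d][h1] += (1 - r) * half
            gam[d][h2] += (1 - r) * half
            gam[d][2 * (h1 // 2) + (h2 % 2)] += r * half
            gam[d][2 * (h2 // 2) + (h1 % 2)] += r * half
    p = [Fraction(0)] * 16
    p[_F1_STATE] = Fraction(1)
    for _ in range(k - 1):
        nxt = [Fraction(0)] * 16
        for d in range(16):
            if p[d] == 0:
                continue
            g = gam[d]
            for i in range(4):
                if g[i] == 0:
                    continue
                for j in range(4):
                    nxt[4 * i + j] += p[d] * g[i] * g[j]
        p = nxt
    out = [[Fraction(0)] * 3 for _ in range(3)]
    for h1 in range(4):
        for h2 in range(4):
            gA = (h1 // 2) + (h2 // 2)
            gB = (h1 % 2) + (h2 % 2)
            out[gA][gB] += p[4 * h1 + h2]
    return out


def marginal_selfing(k):
    """One-locus genotype probabilities (AA, AB, BB) at F_k.

    Heterozygosity halves each selfing round: h = (1/2)^(k-1); the two
    homozygote classes share the remainder equally — 0.4375/0.125/0.4375
    at F4.  The inbred limit is (0.5, 0, 0.5).
    """
    if _is_inf(k):
        return np.array([0.5, 0.0, 0.5])
    if not (isinstance(k, (int, np.integer)) and k >= 2):
        raise ValueError(f"generation k must be an integer >= 2 or inf, got {k!r}")
    het = 0.5 ** (k - 1)
    return np.array([(1 - het) / 2, het, (1 - het) / 2])


def haldane_waddington_limit(r):
    """Recombinant-line frequency 2r/(1+2r) for fully inbred selfed RILs."""
    r = np.asarray(r, dtype=float)
    return 2 * r / (1 + 2 * r)


def kosambi(r):
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r)); r must be < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("Kosambi distance requires 0 <= r < 0.5")
    out = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(out) if out.ndim == 0 else out


def kosambi_inverse(d):
    """Inverse Kosambi: r = 0.5 tanh(2d/100) for d >= 0 cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    out = 0.5 * np.tanh(2 * d / 100.0)
    return float(out) if out.ndim == 0 else out


def haldane_inverse(d):
    """Haldane inverse map function r = (1 - exp(-2d/100))/2 (no interference)."""
    d = np.asarray(d, dtype=float)
    out = 0.5 * (1.0 - np.exp(-2 * d / 100.0))
    return float(out) if out.ndim == 0 else out


# --- recombination-fraction MLE ---------------------------------------------

_R_GRID = np.linspace(0.0, 0.5, 501)


@lru_cache(maxsize=32)
def _model_grid(k, collapse_a: bool, collapse_b: bool):
    """Log-probabilities of the (possibly collapsed) genotype classes on a
    fixed r grid, cached per generation.  Collapsing merges AB with BB along
    one axis — the 2x3 likelihood used for markers scored without a
    heterozygote class."""
    probs = joint_selfing(_R_GRID, k)  # (R, 3, 3)
    probs = _collapse(probs, collapse_a, collapse_b)
    with np.errstate(divide="ignore"):
        return np.log(probs.reshape(len(_R_GRID), -1))


def _collapse(p, collapse_a, collapse_b):
    if collapse_a:
        merged = p[..., 1, :] + p[..., 2, :]
        p = np.stack([p[..., 0, :], merged], axis=-2)
    if collapse_b:
        merged = p[..., :, 1] + p[..., :, 2]
        p = np.stack([p[..., :, 0], merged], axis=-1)
    return p


def _loglik(counts_flat, logp_flat):
    # observed-zero classes contribute 0 even where log p = -inf
    mask = counts_flat > 0
    ll = counts_flat[mask] @ np.where(
        np.isfinite(logp_flat[..., mask]), logp_flat[..., mask], -1e30
    ).T
    return ll


def _loglik_at(r, counts_flat, k, collapse_a, collapse_b):
    p = joint_selfing(np.atleast_1d(r), k)
    p = _collapse(p, collapse_a, collapse_b).reshape(1, -1)
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    return float(_loglik(counts_flat, logp)[0])


def estimate_rf(counts, k, collapse_a=False, collapse_b=False, tol=1e-6):
    """Maximum-likelihood recombination fraction and linkage LOD for one
    marker pair.

    Parameters
    ----------
    counts : (3, 3) array
        Two-locus genotype contingency table (rows: marker 1 genotype
        0=AA,1=AB,2=BB; columns: marker 2), individuals missing at either
        marker excluded.
    k : generation (int >= 2 or inf).
    collapse_a, collapse_b : bool
        Use the 2x3 (AA vs non-AA) likelihood along the corresponding axis,
        for markers with no scored heterozygotes.
    tol : float
        Golden-section tolerance on r.

    Returns
    -------
    (r_hat, lod) with r_hat in [0, 0.5] and lod = log10 L(r_hat) - log10 L(0.5).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3) or counts.sum() < 1:
        raise ValueError("counts must be a 3x3 table with total >= 1")
    c = _collapse(counts, collapse_a, collapse_b).ravel()

    kk = None if _is_inf(k) else int(k)
    logp = _model_grid(kk, bool(collapse_a), bool(collapse_b))
    ll = _loglik(c, logp)
    i = int(np.argmax(ll))
    lo = _R_GRID[max(i - 1, 0)]
    hi = _R_GRID[min(i + 1, len(_R_GRID) - 1)]

    # golden-section refinement within the bracketing grid cells
    invphi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1 = _loglik_at(x1, c, kk, collapse_a, collapse_b)
    f2 = _loglik_at(x2, c, kk, collapse_a, collapse_b)
    while b - a > tol:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = _loglik_at(x2, c, kk, collapse_a, collapse_b)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = _loglik_at(x1, c, kk, collapse_a, collapse_b)
    r_hat = (a + b) / 2
    ll_hat = max(f1, f2, ll[i])
    if ll[i] >= max(f1, f2):
        r_hat = _R_GRID[i]
    r_hat = min(max(r_hat, 0.0), 0.5)
    ll_null = _loglik_at(0.5, c, kk, collapse_a, collapse_b)
    lod = max((ll_hat - ll_null) / math.log(10), 0.0)
    return r_hat, lod
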