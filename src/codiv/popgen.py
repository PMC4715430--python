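"""Per-OTU diversity and differentiation statistics.

All pairwise quantities use pairwise deletion: for each sequence pair, columns
with a gap or N in either row are excluded.  Nucleotide diversity is the mean
over pairs of (differences / pair-valid sites); Watterson's theta is
S / (a1 * L_eff) with a1 = sum 1/i over i < n and L_eff the number of columns
that are not entirely gaps.  Tajima's D is tested against the classical
rescaled-beta null (mean 0, variance 1 on the [D_min, D_max] support implied
by the sample size) or, as a cross-check and fallback, against a neutral
coalescent simulation conditioned on the observed number of segregating
sites.  Haplotype-based G_ST uses the small-sample (Nei-Chesser) corrected
estimator by default, with the uncorrected variant behind a flag; its
significance comes from permuting individuals among locales.

Most functions accept an optional integer ``weights`` vector giving the
multiplicity of each alignment row, so heavily dereplicated OTUs (thousands of
reads, few haplotypes) are handled without expanding the alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .align import Alignment
from .errors import SaturationError, ValidationError
from .otu import _GAP, _N

log = logging.getLogger(__name__)

_BASES = tuple(ord(b) for b in "ACGT")
_PURINES = (ord("A"), ord("G"))
_PYRIMIDINES = (ord("C"), ord("T"))


# ---------------------------------------------------------------------------
# pairwise distances


def _base_indicators(aln: Alignment) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    mat = aln.matrix()
    valid = (mat != _GAP) & (mat != _N)
    ind = {b: ((mat == b) & valid).astype(np.float64) for b in _BASES}
    return valid.astype(np.float64), ind


def pairwise_diffs(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Raw pairwise differences and per-pair valid-site counts.

    Returns ``(diffs, valid)`` as n x n matrices.  A pair with zero valid
    columns is left at valid == 0; callers decide whether that disqualifies
    the OTU.
    """
    if aln.n_rows < 2:
        raise ValidationError("pairwise_diffs requires at least two rows")
    vmask, ind = _base_indicators(aln)
    valid = vmask @ vmask.T
    matches = np.zeros_like(valid)
    for b in _BASES:
        matches += ind[b] @ ind[b].T
    diffs = valid - matches
    np.fill_diagonal(diffs, 0.0)
    return diffs, valid


def k2p(aln: Alignment, on_saturation: str = "raise") -> np.ndarray:
    """Kimura 2-parameter distances from transition/transversion proportions.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).  Saturated pairs (non-positive
    log arguments) raise by default, or become NaN with ``on_saturation="nan"``.
    """
    vmask, ind = _base_indicators(aln)
    valid = vmask @ vmask.T
    if np.any(valid[~np.eye(aln.n_rows, dtype=bool)] < 1):
        raise ValidationError("a pair has no valid sites; K2P undefined")
    a, g = ind[_PURINES[0]], ind[_PURINES[1]]
    c, t = ind[_PYRIMIDINES[0]], ind[_PYRIMIDINES[1]]
    transitions = a @ g.T + g @ a.T + c @ t.T + t @ c.T
    matches = sum(ind[b] @ ind[b].T for b in _BASES)
    transversions = valid - matches - transitions
    with np.errstate(divide="ignore", invalid="ignore"):
        P = transitions / valid
        Q = transversions / valid
        arg1 = 1.0 - 2.0 * P - Q
        arg2 = 1.0 - 2.0 * Q
        d = -0.5 * np.log(arg1) - 0.25 * np.log(arg2)
    np.fill_diagonal(d, 0.0)
    saturated = ~np.isfinite(d)
    if saturated.any():
        if on_saturation == "raise":
            raise SaturationError("K2P distance saturated for at least one pair")
        d[saturated] = np.nan
    return d


# ---------------------------------------------------------------------------
# diversity summaries


@dataclass
class DiversityStats:
    n: int
    S: int
    L_mean: float
    L_eff: int
    k_hat: float
    pi: float
    theta_w: float
    D: float | None = None
    D_pvalue: float | None = None
    D_missing_reason: str | None = None


def _pair_weight_sums(weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Off-diagonal pair weights w_a*w_b (a<b) and total pair count C(n,2)."""
    n = int(weights.sum())
    total_pairs = n * (n - 1) / 2.0
    W = np.outer(weights, weights).astype(np.float64)
    return W, total_pairs


def diversity_summary(aln: Alignment, weights: np.ndarray | None = None) -> DiversityStats:
    """n, S, mean pairwise differences, pi and Watterson's theta for one OTU.

    ``weights`` gives per-row multiplicities (identical copies contribute
    zero-difference pairs); default is one individual per row.
    """
    if aln.n_rows < 1:
        raise ValidationError("empty alignment")
    if weights is None:
        weights = np.ones(aln.n_rows, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.int64)
    if weights.shape != (aln.n_rows,) or np.any(weights < 1):
        raise ValidationError("weights must be positive, one per row")
    n = int(weights.sum())
    if n < 2:
        raise ValidationError("diversity_summary requires n >= 2 sequences")

    mat = aln.matrix()
    valid_mask = (mat != _GAP) & (mat != _N)
    if aln.n_rows >= 2:
        diffs, valid = pairwise_diffs(aln)
        off = ~np.eye(aln.n_rows, dtype=bool)
        if np.any(valid[off] == 0):
            raise ValidationError("a sequence pair shares no valid sites")
    else:
        diffs = np.zeros((1, 1))
        valid = np.full((1, 1), valid_mask.sum(), dtype=float)

    W, total_pairs = _pair_weight_sums(weights)
    iu = np.triu_indices(aln.n_rows, k=1)
    sum_diffs = float((W[iu] * diffs[iu]).sum())
    sum_ratio = float((W[iu] * (diffs[iu] / valid[iu])).sum())
    # identical-copy pairs: zero differences, self-valid sites
    within_pairs = weights * (weights - 1) / 2.0
    self_valid = valid_mask.sum(axis=1).astype(float)
    sum_valid = float((W[iu] * valid[iu]).sum() + (within_pairs * self_valid).sum())

    k_hat = sum_diffs / total_pairs
    pi = sum_ratio / total_pairs
    L_mean = sum_valid / total_pairs

    # segregating sites: columns with >= 2 distinct non-gap, non-N states
    S = 0
    for col in range(aln.n_cols):
        states = set(mat[valid_mask[:, col], col].tolist())
        if len(states) >= 2:
            S += 1
    L_eff = int((~(mat == _GAP).all(axis=0)).sum())
    a1 = harmonic(n - 1)
    theta_w = S / (a1 * L_eff) if L_eff > 0 else 0.0
    return DiversityStats(
        n=n, S=S, L_mean=L_mean, L_eff=L_eff, k_hat=k_hat, pi=pi, theta_w=theta_w
    )


def harmonic(m: int) -> float:
    return float(np.sum(1.0 / np.arange(1, m + 1))) if m >= 1 else 0.0


# ---------------------------------------------------------------------------
# Tajima's D and its null


@dataclass
class TajimaNull:
    """Variance constants and beta-null geometry for Tajima's D at sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D_min: float
    D_max: float
    beta_alpha: float
    beta_beta: float


def tajima_constants(n: int) -> TajimaNull:
    if n < 4:
        raise ValidationError("Tajima's D requires n >= 4")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    D_min = (2.0 / n - 1.0 / a1) / np.sqrt(e2)
    if n % 2 == 0:
        D_max = (n / (2.0 * (n - 1)) - 1.0 / a1) / np.sqrt(e2)
    else:
        D_max = ((n + 1) / (2.0 * n) - 1.0 / a1) / np.sqrt(e2)
    # rescaled beta on [D_min, D_max] with mean 0 and variance 1
    span = D_max - D_min
    s = -D_min * D_max - 1.0
    if s > 0:
        mu = -D_min / span
        beta_alpha = mu * s
        beta_beta = (1.0 - mu) * s
    else:  # degenerate geometry; signals fallback to the simulation null
        beta_alpha = beta_beta = float("nan")
    return TajimaNull(
        n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2,
        D_min=float(D_min), D_max=float(D_max),
        beta_alpha=float(beta_alpha), beta_beta=float(beta_beta),
    )


def tajima_d(n: int, S: int, k_hat: float) -> tuple[float | None, TajimaNull | None, str | None]:
    """Tajima's D from (n, S, mean pairwise differences).

    Returns (D, null, missing_reason); D is None with a reason when n < 4 or
    S == 0 (never reported as 0).
    """
    if n < 4:
        return None, None, "n < 4"
    if S < 1:
        return None, None, "no segregating sites"
    null = tajima_constants(n)
    var = null.e1 * S + null.e2 * S * (S - 1)
    D = (k_hat - S / null.a1) / np.sqrt(var)
    return float(D), null, None


def tajima_pvalue(
    D: float,
    null: TajimaNull,
    S: int | None = None,
    mode: str = "beta",
    n_replicates: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-tailed p-value for Tajima's D.

    ``beta`` mode evaluates the rescaled beta null; ``simulation`` mode draws
    neutral coalescent genealogies at sample size n, places S mutations
    uniformly on branches, and uses the empirical two-tailed rank with +1
    smoothing (S is required for simulation mode).
    """
    if mode == "beta":
        if not np.isfinite(null.beta_alpha) or null.beta_alpha <= 0 or null.beta_beta <= 0:
            warnings.warn("beta-null shapes non-positive; falling back to simulation")
            mode = "simulation"
        else:
            x = (D - null.D_min) / (null.D_max - null.D_min)
            x = min(max(x, 0.0), 1.0)
            cdf = sps.beta.cdf(x, null.beta_alpha, null.beta_beta)
            return float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    if mode != "simulation":
        raise ValidationError(f"unknown mode {mode!r}")
    if S is None:
        raise ValidationError("simulation mode needs the observed S")
    if rng is None:
        rng = np.random.default_rng()
    sims = simulate_tajima_null(null.n, S, n_replicates, rng)
    lo = (1 + int(np.sum(sims <= D))) / (n_replicates + 1)
    hi = (1 + int(np.sum(sims >= D))) / (n_replicates + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def simulate_tajima_null(
    n: int, S: int, n_replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Neutral-coalescent null for D conditioned on the observed S.

    For each replicate a Kingman genealogy is drawn, S mutations are placed
    multinomially on branches proportionally to length, and D is recomputed
    from the implied pairwise differences (a mutation on a branch subtending i
    tips contributes i*(n-i) pairwise differences under infinite sites).
    """
    null = tajima_constants(n)
    denom = np.sqrt(null.e1 * S + null.e2 * S * (S - 1))
    pair_total = n * (n - 1) / 2.0
    out = np.empty(n_replicates)
    for rep in range(n_replicates):
        sizes, lengths = _kingman_branches(n, rng)
        probs = lengths / lengths.sum()
        muts = rng.multinomial(S, probs)
        k_hat = float(np.sum(muts * sizes * (n - sizes)) / pair_total)
        out[rep] = (k_hat - S / null.a1) / denom
    return out


def _kingman_branches(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Subtended-tip counts and lengths of the 2n-2 branches of one genealogy."""
    ks = np.arange(n, 1, -1)
    waits = rng.exponential(scale=2.0 / (ks * (ks - 1.0)))
    event_time = np.concatenate([[0.0], np.cumsum(waits)])
    sizes = [1] * n
    born = [0.0] * n
    out_sizes: list[int] = []
    out_lengths: list[float] = []
    active = list(range(n))
    for ev in range(n - 1):
        t = event_time[ev + 1]
        i = int(rng.integers(len(active)))
        a = active.pop(i)
        j = int(rng.integers(len(active)))
        b = active.pop(j)
        out_sizes.extend((sizes[a], sizes[b]))
        out_lengths.extend((t - born[a], t - born[b]))
        sizes.append(sizes[a] + sizes[b])
        born.append(t)
        active.append(len(sizes) - 1)
    return np.asarray(out_sizes, dtype=float), np.asarray(out_lengths, dtype=float)


# ---------------------------------------------------------------------------
# haplotype G_ST


@dataclass
class GstResult:
    H_S: float | None
    H_T: float | None
    G_ST: float | None
    p_value: float | None
    n_permutations: int
    missing_reason: str | None = None


def gst_test(
    haplotypes: np.ndarray,
    locales: np.ndarray,
    B: int = 10_000,
    seed: int | np.random.Generator | None = None,
    corrected: bool = True,
) -> GstResult:
    """Haplotype-based G_ST with a permutation test.

    ``haplotypes`` and ``locales`` are per-individual label vectors.  Distinct
    haplotypes are the alleles; the corrected estimator applies the unbiased
    within-locale diversity and the H_T small-sample correction, and the
    p-value permutes individuals among locales preserving locale sizes.
    """
    haplotypes = np.asarray(haplotypes)
    locales = np.asarray(locales)
    if haplotypes.shape != locales.shape:
        raise ValidationError("haplotypes and locales must align")
    _, hap_idx = np.unique(haplotypes, return_inverse=True)
    loc_names, loc_idx = np.unique(locales, return_inverse=True)
    if len(loc_names) < 2:
        raise ValidationError("gst_test requires >= 2 locales")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    obs = _gst_from_counts(_count_matrix(loc_idx, hap_idx, len(loc_names)), corrected)
    if obs is None:
        return GstResult(None, None, None, None, B, "monomorphic (H_T == 0)")
    hs, ht, gst = obs
    count = 0
    perm_loc = loc_idx.copy()
    for _ in range(B):
        rng.shuffle(perm_loc)
        res = _gst_from_counts(_count_matrix(perm_loc, hap_idx, len(loc_names)), corrected)
        if res is not None and res[2] >= gst:
            count += 1
    p = (1 + count) / (B + 1)
    return GstResult(hs, ht, gst, p, B)


def _count_matrix(loc_idx: np.ndarray, hap_idx: np.ndarray, n_loc: int) -> np.ndarray:
    n_hap = hap_idx.max() + 1
    counts = np.zeros((n_loc, n_hap), dtype=np.int64)
    np.add.at(counts, (loc_idx, hap_idx), 1)
    return counts


def _gst_from_counts(counts: np.ndarray, corrected: bool) -> tuple[float, float, float] | None:
    sizes = counts.sum(axis=1).astype(float)
    keep = sizes > 0
    counts, sizes = counts[keep], sizes[keep]
    n_loc = counts.shape[0]
    freqs = counts / sizes[:, None]
    if corrected:
        with np.errstate(divide="ignore", invalid="ignore"):
            h_p = np.where(
                sizes > 1,
                sizes / (sizes - 1.0) * (1.0 - (freqs**2).sum(axis=1)),
                0.0,
            )
        H_S = float(h_p.mean())
        pbar = freqs.mean(axis=0)
        H_T = float(1.0 - (pbar**2).sum())
        n_tilde = n_loc / float((1.0 / sizes).sum())  # harmonic mean locale size
        H_T += H_S / (n_tilde * n_loc)
    else:
        h_p = 1.0 - (freqs**2).sum(axis=1)
        H_S = float(h_p.mean())
        pbar = freqs.mean(axis=0)
        H_T = float(1.0 - (pbar**2).sum())
    if H_T <= 0:
        return None
    return H_S, H_T, (H_T - H_S) / H_T
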