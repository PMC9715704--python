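"""Diversity, neutrality and differentiation statistics on haploid matrices.

Within groups: segregating sites S, mean pairwise differences (MPD),
nucleotide diversity pi = MPD / L, and Tajima's D with a p-value from
coalescent simulations conditioned on S.  Between groups: one-level AMOVA on
pairwise-difference distances with its phi_ST and permutation p, pairwise
phi_ST matrices, and a classical MDS embedding with Kruskal stress-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pairwise distances


def pairwise_differences(matrix: GenotypeMatrix) -> np.ndarray:
    """Symmetric matrix of mutational differences between samples, counted
    over co-called sites and rescaled by total/co-called sites."""
    m = matrix.n_snps
    n = matrix.n_samples
    if m == 0:
        return np.zeros((n, n))
    a1 = (matrix.calls == 1).astype(np.float64)
    a0 = (matrix.calls == 0).astype(np.float64)
    diff = a1 @ a0.T + a0 @ a1.T
    called = a1 + a0
    cocalled = called @ called.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(cocalled > 0, diff * (m / np.maximum(cocalled, 1)), 0.0)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# within-group diversity


@dataclass
class DiversitySummary:
    n: int
    s: int
    mpd: float
    mpd_sd: float
    pi: float
    pi_sd: float
    pi_x1000: float
    tajimas_d: float
    p_d: float | None = None
    group: str = ""


def segregating_sites(matrix: GenotypeMatrix) -> int:
    """Sites where both alleles are observed among non-missing calls."""
    has0 = (matrix.calls == 0).any(axis=0)
    has1 = (matrix.calls == 1).any(axis=0)
    return int((has0 & has1).sum())


def mean_pairwise_differences(matrix: GenotypeMatrix) -> float:
    n = matrix.n_samples
    if n < 2:
        raise ValueError("need at least two samples")
    d = pairwise_differences(matrix)
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def _mpd_variance(mpd: float, n: int) -> float:
    """Total variance of MPD under no recombination (stochastic +
    sampling), the form reported alongside haplotype MPDs."""
    if n < 3:
        return float("nan")
    num = 3 * n * (n + 1) * mpd + 2 * (n**2 + n + 3) * mpd**2
    den = 11 * (n**2 - 7 * n + 6)
    return num / den


def _tajima_constants(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d_from_summary(n: int, s: int, mpd: float) -> float:
    """Tajima's D from sample size, segregating sites and MPD."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if s == 0:
        return float("nan")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    return float((mpd - s / a1) / np.sqrt(var))


def tajimas_d(matrix: GenotypeMatrix) -> float:
    return tajimas_d_from_summary(
        matrix.n_samples, segregating_sites(matrix), mean_pairwise_differences(matrix)
    )


def diversity(
    matrix: GenotypeMatrix, l_retained: int, group: str = ""
) -> DiversitySummary:
    """Diversity summary for one group of haplotypes over ``l_retained``
    callable sites."""
    n = matrix.n_samples
    s = segregating_sites(matrix)
    mpd = mean_pairwise_differences(matrix)
    mpd_sd = float(np.sqrt(_mpd_variance(mpd, n)))
    pi = mpd / l_retained
    d = tajimas_d_from_summary(n, s, mpd) if n >= 4 and s >= 1 else float("nan")
    return DiversitySummary(
        n=n, s=s, mpd=mpd, mpd_sd=mpd_sd, pi=pi, pi_sd=mpd_sd / l_retained,
        pi_x1000=pi * 1000.0, tajimas_d=d, group=group,
    )


# ---------------------------------------------------------------------------
# coalescent null for Tajima's D


def _simulate_null_d(n: int, s: int, n_sims: int, rng: np.random.Generator) -> np.ndarray:
    """Tajima's D under the constant-size neutral coalescent conditioned on
    the observed number of segregating sites (mutations placed on branches
    proportionally to length)."""
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    sqrt_var = np.sqrt(var)
    pair_norm = 2.0 / (n * (n - 1))
    out = np.empty(n_sims)
    for r in range(n_sims):
        sizes = [1] * n
        lens = [0.0] * n
        b_sizes: list[int] = []
        b_lens: list[float] = []
        for k in range(n, 1, -1):
            dt = rng.exponential(2.0 / (k * (k - 1)))
            for t in range(k):
                lens[t] += dt
            a, b = int(rng.integers(0, k)), int(rng.integers(0, k - 1))
            if b >= a:
                b += 1  # distinct pair, uniform
            a, b = (a, b) if a < b else (b, a)
            b_sizes.append(sizes[a])
            b_lens.append(lens[a])
            b_sizes.append(sizes[b])
            b_lens.append(lens[b])
            sizes[a] += sizes[b]
            lens[a] = 0.0
            del sizes[b], lens[b]
        bl = np.asarray(b_lens)
        counts = rng.multinomial(s, bl / bl.sum())
        bs = np.asarray(b_sizes)
        mpd = float((counts * bs * (n - bs)).sum() * pair_norm)
        out[r] = (mpd - s / a1) / sqrt_var
    return out


def tajimas_d_pvalue(
    matrix: GenotypeMatrix, n_sims: int = 100_000, seed: int = 0
) -> float:
    """Lower-tail p-value for the observed Tajima's D against constant-size
    neutral coalescent simulations with the same n and S."""
    d_obs = tajimas_d(matrix)
    if not np.isfinite(d_obs):
        raise ValueError("Tajima's D undefined (S=0 or n<4)")
    rng = np.random.default_rng(seed)
    sims = _simulate_null_d(matrix.n_samples, segregating_sites(matrix), n_sims, rng)
    return float((sims <= d_obs).mean())


# ---------------------------------------------------------------------------
# AMOVA and phi_ST


@dataclass
class AmovaResult:
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    pct_among: float
    pct_within: float
    p_value: float | None
    df_among: int
    df_within: int
    n_permutations: int = 0


def _amova_components(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """One-level variance components from a squared-distance matrix
    (pairwise differences) and group labels."""
    n = len(labels)
    groups = pd.unique(labels)
    k = len(groups)
    iu = np.triu_indices(n, k=1)
    ssd_total = d2[iu].sum() / n
    ssd_within = 0.0
    n_sizes = []
    for g in groups:
        idx = np.flatnonzero(labels == g)
        n_g = len(idx)
        n_sizes.append(n_g)
        sub = d2[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(n_g, k=1)].sum() / n_g
    ssd_among = ssd_total - ssd_within
    df_among = k - 1
    df_within = n - k
    ms_within = ssd_within / df_within
    n_prime = (n - sum(s**2 for s in n_sizes) / n) / (k - 1)
    sigma2_among = (ssd_among / df_among - ms_within) / n_prime
    return sigma2_among, ms_within


def amova(
    matrix: GenotypeMatrix,
    regions: pd.Series | list[str],
    n_permutations: int = 10_000,
    seed: int = 0,
    min_group_size: int = 2,
) -> AmovaResult:
    """One-level AMOVA on pairwise-difference distances with a permutation
    test shuffling samples across regions.  Groups below ``min_group_size``
    are excluded with a log entry."""
    labels = np.asarray(
        regions.loc[matrix.sample_ids].to_numpy()
        if isinstance(regions, pd.Series) and regions.index.name == "sample_id"
        else regions
    )
    if len(labels) != matrix.n_samples:
        raise ValueError("one region label per sample required")
    counts = pd.Series(labels).value_counts()
    small = counts[counts < min_group_size].index
    if len(small):
        logger.info("excluding groups with n < %d: %s", min_group_size, list(small))
        keep = ~np.isin(labels, small)
        matrix = matrix.subset_samples(keep)
        labels = labels[keep]
    if len(pd.unique(labels)) < 2:
        raise ValueError("AMOVA needs at least two groups of sufficient size")
    d2 = pairwise_differences(matrix)
    s_a, s_w = _amova_components(d2, labels)
    phi = s_a / (s_a + s_w) if (s_a + s_w) > 0 else 0.0
    p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        lab = labels.copy()
        for _ in range(n_permutations):
            rng.shuffle(lab)
            pa, pw = _amova_components(d2, lab)
            pphi = pa / (pa + pw) if (pa + pw) > 0 else 0.0
            if pphi >= phi:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    k = len(pd.unique(labels))
    return AmovaResult(
        sigma2_among=s_a,
        sigma2_within=s_w,
        phi_st=phi,
        pct_among=100.0 * phi,
        pct_within=100.0 * (1.0 - phi),
        p_value=p,
        df_among=k - 1,
        df_within=matrix.n_samples - k,
        n_permutations=n_permutations,
    )


def pairwise_phist(
    matrix: GenotypeMatrix,
    regions: pd.Series | list[str],
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise phi_ST (two-group AMOVA per region pair);
    negative values are retained."""
    labels = np.asarray(regions)
    if len(labels) != matrix.n_samples:
        raise ValueError("one region label per sample required")
    counts = pd.Series(labels).value_counts()
    use = sorted(counts[counts >= min_group_size].index)
    dropped = sorted(set(counts.index) - set(use))
    if dropped:
        logger.info("pairwise phi_ST: dropping small groups %s", dropped)
    d2 = pairwise_differences(matrix)
    out = pd.DataFrame(0.0, index=use, columns=use)
    for i, g1 in enumerate(use):
        for g2 in use[i + 1:]:
            idx = np.flatnonzero(np.isin(labels, [g1, g2]))
            sub = d2[np.ix_(idx, idx)]
            s_a, s_w = _amova_components(sub, labels[idx])
            phi = s_a / (s_a + s_w) if (s_a + s_w) > 0 else 0.0
            out.loc[g1, g2] = out.loc[g2, g1] = phi
    return out


# ---------------------------------------------------------------------------
# MDS


@dataclass
class MdsResult:
    coords: pd.DataFrame
    stress_pct: float       # normalized raw stress, percent
    stress1_pct: float      # Kruskal stress-1 vs raw dissimilarities, percent


def _classical_coords(delta: np.ndarray, k: int) -> np.ndarray:
    n = len(delta)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (delta**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)[None, :]


def _pair_dist(x: np.ndarray) -> np.ndarray:
    return np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))


def mds(
    dist: pd.DataFrame,
    k: int = 2,
    transformation: str = "interval",
    n_restarts: int = 8,
    max_iter: int = 1000,
    tol: float = 1e-12,
    seed: int = 0,
) -> MdsResult:
    """Metric MDS by SMACOF majorization with an optional disparity
    transformation.

    Negative dissimilarities are clamped to 0 before embedding.  With
    ``transformation='interval'`` (default) disparities are an affine
    least-squares transform of the dissimilarities re-fit each iteration —
    the flavour whose fit statistic, normalized raw stress
    sum (dhat - d)^2 / sum d^2 (reported in percent), matches how stress is
    quoted for published phi_ST MDS plots.  ``transformation='none'`` fits
    the raw dissimilarities (classical metric SMACOF).  Kruskal stress-1
    against the untransformed dissimilarities is reported alongside.
    Starts from the classical (double-centering) solution plus seeded
    random restarts; deterministic for a given seed.
    """
    if transformation not in ("interval", "none"):
        raise ValueError("transformation must be 'interval' or 'none'")
    labels = list(dist.index)
    n = len(labels)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than matrix size {n}")
    delta = np.asarray(dist, dtype=float)
    if not np.allclose(delta, delta.T):
        raise ValueError("distance matrix must be symmetric")
    delta = np.clip(delta, 0.0, None)
    np.fill_diagonal(delta, 0.0)
    iu = np.triu_indices(n, k=1)
    dvec = delta[iu]
    scale = dvec.max() if dvec.max() > 0 else 1.0

    rng = np.random.default_rng(seed)
    inits = [_classical_coords(delta, k)]
    for _ in range(n_restarts):
        inits.append(rng.normal(scale=scale, size=(n, k)))

    def run(x0: np.ndarray) -> tuple[float, np.ndarray]:
        x = x0.copy()
        prev = np.inf
        for _ in range(max_iter):
            d = _pair_dist(x)
            dv = d[iu]
            if transformation == "interval":
                a_mat = np.vstack([np.ones_like(dvec), dvec]).T
                coef, *_ = np.linalg.lstsq(a_mat, dv, rcond=None)
                dh_vec = a_mat @ coef
            else:
                dh_vec = dvec
            dhat = np.zeros_like(delta)
            dhat[iu] = dh_vec
            dhat = dhat + dhat.T
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            bmat = -ratio
            np.fill_diagonal(bmat, 0.0)
            np.fill_diagonal(bmat, -bmat.sum(axis=1))
            x = bmat @ x / n
            d = _pair_dist(x)
            dv = d[iu]
            denom = (dv**2).sum()
            stress = ((dh_vec - dv) ** 2).sum() / denom if denom > 0 else 0.0
            if abs(prev - stress) < tol:
                break
            prev = stress
        return float(stress), x

    best_stress, best_x = min((run(x0) for x0 in inits), key=lambda t: t[0])
    coords = best_x - best_x.mean(axis=0, keepdims=True)
    d = _pair_dist(coords)[iu]
    denom = (d**2).sum()
    stress1 = np.sqrt(((dvec - d) ** 2).sum() / denom) if denom > 0 else 0.0
    coords_df = pd.DataFrame(
        coords, index=labels, columns=[f"dim{i + 1}" for i in range(k)]
    )
    return MdsResult(
        coords=coords_df,
        stress_pct=100.0 * best_stress,
        stress1_pct=100.0 * float(stress1),
    )


def matrix_extremes(dist: pd.DataFrame) -> dict:
    """Largest and smallest off-diagonal entries with their region pairs;
    ties are reported together."""
    labels = list(dist.index)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least a 2x2 matrix")
    vals = np.asarray(dist, dtype=float)
    iu = np.triu_indices(n, k=1)
    flat = vals[iu]
    vmax, vmin = flat.max(), flat.min()
    pairs = [(labels[i], labels[j]) for i, j in zip(*iu)]
    max_pairs = [p for p, v in zip(pairs, flat) if v == vmax]
    min_pairs = [p for p, v in zip(pairs, flat) if v == vmin]
    return {"max": vmax, "max_pairs": max_pairs, "min": vmin, "min_pairs": min_pairs}
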