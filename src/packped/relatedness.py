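"""Pairwise relatedness estimation and the random-mating resampling null.

Two estimators are provided: the Queller-Goodnight moment estimator
(unbiased, may fall outside [0, 1]) and a dyadic maximum-likelihood estimator
over the non-inbred IBD modes (k0, k1, k2) with r = k2 + k1/2, fitted by EM
on the probability simplex.  The random-mating null draws mated pairs with
replacement from male and female genotype pools and records the mean pair
relatedness per iteration, giving the reference distribution against which
observed mated-pair relatedness is judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import AlleleFrequencyTable, as_allele_array

__all__ = [
    "RelatednessEstimate",
    "NullDistribution",
    "qg_relatedness",
    "ml_relatedness",
    "ml_relatedness_batch",
    "ibd_mode_probs",
    "random_mating_null",
    "breeder_relatedness_summary",
]


@dataclass
class RelatednessEstimate:
    id1: object
    id2: object
    estimator: str
    r: float
    k: tuple | None = None  # (k0, k1, k2) for ML estimates


def _as_pair_arrays(G1, G2):
    G1 = np.asarray(G1, dtype=np.int64)
    G2 = np.asarray(G2, dtype=np.int64)
    if G1.ndim == 2:
        G1 = G1[None]
    if G2.ndim == 2:
        G2 = G2[None]
    if G1.shape != G2.shape:
        raise ValueError("genotype arrays must have matching shapes")
    return G1, G2


def _lookup(F: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Frequencies of alleles (..., ) at loci given dense matrix F (L, A+1)."""
    L = F.shape[0]
    li = np.arange(L)
    return F[li[None, :], np.clip(alleles, 0, F.shape[1] - 1)]


def qg_relatedness(g1, g2, freqs: AlleleFrequencyTable) -> float:
    """Symmetrized Queller-Goodnight moment estimate of relatedness."""
    return float(qg_relatedness_pairs(*_as_pair_arrays(as_allele_array(g1),
                                                       as_allele_array(g2)), freqs)[0])


def qg_relatedness_pairs(G1: np.ndarray, G2: np.ndarray,
                         freqs: AlleleFrequencyTable) -> np.ndarray:
    """Vectorized Queller-Goodnight estimates for P genotype pairs (P, L, 2).

    Numerators and denominators are summed over typed loci and over both
    reference directions before dividing; loci untyped in either member are
    skipped, and monomorphic loci contribute zero to both sums.
    """
    G1, G2 = _as_pair_arrays(G1, G2)
    F = freqs.freq_matrix()
    a, b = G1[..., 0], G1[..., 1]
    c, d = G2[..., 0], G2[..., 1]
    typed = (G1 > 0).all(-1) & (G2 > 0).all(-1)

    pa, pb = _lookup(F, a), _lookup(F, b)
    pc, pd_ = _lookup(F, c), _lookup(F, d)
    s_ac, s_ad = (a == c).astype(float), (a == d).astype(float)
    s_bc, s_bd = (b == c).astype(float), (b == d).astype(float)
    delta_sum = s_ac + s_ad + s_bc + s_bd

    num1 = 0.5 * delta_sum - pa - pb
    den1 = 1.0 + (a == b) - pa - pb
    num2 = 0.5 * delta_sum - pc - pd_
    den2 = 1.0 + (c == d) - pc - pd_

    num = np.where(typed, num1 + num2, 0.0).sum(axis=1)
    den = np.where(typed, den1 + den2, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def ibd_mode_probs(G1, G2, freqs: AlleleFrequencyTable):
    """P(pair genotypes | IBD mode) for modes sharing 0, 1 and 2 alleles IBD.

    Returns (P, L, 3) probabilities and a (P, L) typed mask.  The one-IBD
    term copies a uniformly chosen allele of one member and draws the other
    from the population; the formula is symmetric in the two members.
    """
    G1, G2 = _as_pair_arrays(G1, G2)
    F = freqs.freq_matrix()
    a, b = G1[..., 0], G1[..., 1]
    c, d = G2[..., 0], G2[..., 1]
    typed = (G1 > 0).all(-1) & (G2 > 0).all(-1)

    pa, pb = _lookup(F, a), _lookup(F, b)
    pc, pd_ = _lookup(F, c), _lookup(F, d)
    hw1 = np.where(a == b, pa * pa, 2 * pa * pb)
    hw2 = np.where(c == d, pc * pc, 2 * pc * pd_)

    def t_given(x, px_unused):
        # P(g2 = {c,d} | IBD allele x)
        hom = (c == d)
        return np.where(hom, (x == c) * pc, (x == c) * pd_ + (x == d) * pc)

    p_g2_given_1ibd = 0.5 * (t_given(a, pa) + t_given(b, pb))
    P0 = hw1 * hw2
    P1 = hw1 * p_g2_given_1ibd
    same = (a == c) & (b == d)
    P2 = hw1 * same
    P = np.stack([P0, P1, P2], axis=-1)
    return P, typed


def ml_relatedness_batch(G1, G2, freqs: AlleleFrequencyTable,
                         max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """EM maximum-likelihood (k0, k1, k2) for P pairs at once; returns (P, 3).

    The per-locus likelihood is linear in k, so the log-likelihood is concave
    on the simplex and EM converges to the global maximum.
    """
    P, typed = ibd_mode_probs(G1, G2, freqs)
    n_pairs = P.shape[0]
    k = np.full((n_pairs, 3), 1.0 / 3.0)
    w = typed.astype(float)
    n_loci = np.maximum(w.sum(axis=1), 1.0)
    for _ in range(max_iter):
        mix = np.einsum("pli,pi->pl", P, k)
        mix = np.where(mix > 0, mix, 1.0)
        resp = P * k[:, None, :] / mix[..., None]   # (P, L, 3)
        new_k = np.einsum("pl,pli->pi", w, resp) / n_loci[:, None]
        new_k /= new_k.sum(axis=1, keepdims=True)
        if np.max(np.abs(new_k - k)) < tol:
            k = new_k
            break
        k = new_k
    return k


def ml_relatedness(g1, g2, freqs: AlleleFrequencyTable, error=None,
                   id1=None, id2=None) -> RelatednessEstimate:
    """Dyadic maximum-likelihood relatedness over non-inbred IBD modes.

    Consensus genotypes are treated as known (error handling lives upstream
    in the genotyping stage); ``error`` is accepted for interface symmetry
    and ignored when None.
    """
    k = ml_relatedness_batch(as_allele_array(g1)[None], as_allele_array(g2)[None], freqs)[0]
    r = float(k[2] + 0.5 * k[1])
    return RelatednessEstimate(id1, id2, "ml-dyadic", r, tuple(float(x) for x in k))


@dataclass
class NullDistribution:
    """Random-mating reference distribution of mean mated-pair relatedness."""

    iteration_means: np.ndarray
    draws: np.ndarray            # (n_iter, n_pairs) pair-level estimates
    estimator: str
    n_pairs: int
    observed: float | None = None

    @property
    def n_iter(self) -> int:
        return len(self.iteration_means)

    @property
    def grand_mean(self) -> float:
        return float(self.iteration_means.mean())

    def summary(self) -> dict:
        q = np.quantile(self.iteration_means, [0.025, 0.5, 0.975])
        out = {
            "estimator": self.estimator,
            "n_iter": self.n_iter,
            "n_pairs": self.n_pairs,
            "mean": self.grand_mean,
            "median": float(q[1]),
            "q025": float(q[0]),
            "q975": float(q[2]),
        }
        if self.observed is not None:
            out["observed"] = self.observed
            out["percentile"] = self.percentile(self.observed)
        return out

    def percentile(self, observed: float) -> float:
        """Two-sided tail position of an observed mean among iteration means."""
        lo = float(np.mean(self.iteration_means <= observed))
        hi = float(np.mean(self.iteration_means >= observed))
        return 2.0 * min(lo, hi)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.iteration_means, bins=40, color="steelblue", alpha=0.8)
        if self.observed is not None:
            ax.axvline(self.observed, color="firebrick", label="observed")
            ax.legend()
        ax.set_xlabel("mean pair relatedness per iteration")
        ax.set_ylabel("iterations")
        return ax


def random_mating_null(males: np.ndarray, females: np.ndarray,
                       freqs: AlleleFrequencyTable, n_pairs: int = 151,
                       n_iter: int = 10_000, estimator: str = "qg",
                       seed=None, observed: float | None = None) -> NullDistribution:
    """Resampling null for mated-pair relatedness under random mating.

    Each iteration draws ``n_pairs`` (male, female) pairs uniformly with
    replacement from the pools and records the mean pair relatedness.
    """
    if n_pairs <= 0 or n_iter <= 0:
        raise ValueError("n_pairs and n_iter must be positive")
    if estimator not in ("qg", "ml"):
        raise ValueError("estimator must be 'qg' or 'ml'")
    males = np.asarray(males, dtype=np.int64)
    females = np.asarray(females, dtype=np.int64)
    if males.size == 0 or females.size == 0:
        raise ValueError("pools must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    draws = np.empty((n_iter, n_pairs))
    for it in range(n_iter):
        mi = rng.integers(0, males.shape[0], size=n_pairs)
        fi = rng.integers(0, females.shape[0], size=n_pairs)
        if estimator == "qg":
            r = qg_relatedness_pairs(males[mi], females[fi], freqs)
        else:
            k = ml_relatedness_batch(males[mi], females[fi], freqs, max_iter=200)
            r = k[:, 2] + 0.5 * k[:, 1]
        draws[it] = r
    means = draws.mean(axis=1)
    return NullDistribution(means, draws, estimator, n_pairs, observed)


def breeder_relatedness_summary(r_values, related_threshold: float = 0.25) -> dict:
    """Median/range of mated-pair relatedness and the related-pair fraction."""
    r = np.asarray([e.r if isinstance(e, RelatednessEstimate) else e for e in r_values],
                   dtype=float)
    if r.size == 0:
        raise ValueError("no pair estimates supplied")
    related = r >= related_threshold
    return {
        "n_pairs": int(r.size),
        "median": float(np.median(r)),
        "min": float(r.min()),
        "max": float(r.max()),
        "n_related": int(related.sum()),
        "frac_related": float(related.mean()),
        "mean_related": float(r[related].mean()) if related.any() else float("nan"),
        "related_threshold": related_threshold,
    }
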