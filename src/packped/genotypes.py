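"""Core containers for multilocus microsatellite genotypes.

Genotypes are stored as integer allele arrays of shape ``(L, 2)`` where allele
labels are positive integers and ``0`` denotes a missing / non-amplified
allele.  A locus is *typed* when both slots are non-zero; allele pairs are
unordered and kept sorted so that array equality is genotype equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlleleFrequencyTable",
    "ErrorModel",
    "MultilocusGenotype",
    "as_allele_array",
    "sort_pairs",
]


def sort_pairs(alleles: np.ndarray) -> np.ndarray:
    """Return a copy with each allele pair sorted (missing 0 first)."""
    arr = np.asarray(alleles, dtype=np.int64)
    return np.sort(arr, axis=-1)


def as_allele_array(g) -> np.ndarray:
    """Coerce a genotype-like object to an ``(L, 2)`` int array."""
    if isinstance(g, MultilocusGenotype):
        return g.alleles
    arr = np.asarray(g, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"genotype array must have shape (L, 2), got {arr.shape}")
    return sort_pairs(arr)


@dataclass(frozen=True)
class MultilocusGenotype:
    """Diploid genotype at L codominant loci with missing-data support."""

    alleles: np.ndarray  # (L, 2) int, 0 = missing

    def __post_init__(self):
        object.__setattr__(self, "alleles", sort_pairs(self.alleles))

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[0]

    @property
    def typed_mask(self) -> np.ndarray:
        """Loci where both alleles amplified."""
        return np.all(self.alleles > 0, axis=1)

    @property
    def het_mask(self) -> np.ndarray:
        return self.typed_mask & (self.alleles[:, 0] != self.alleles[:, 1])

    def observed_heterozygosity(self) -> float:
        """Fraction of typed loci carrying two distinct alleles."""
        typed = int(self.typed_mask.sum())
        if typed == 0:
            raise ValueError("observed heterozygosity undefined: no typed loci")
        return float(self.het_mask.sum()) / typed

    def __eq__(self, other) -> bool:
        if not isinstance(other, MultilocusGenotype):
            return NotImplemented
        return np.array_equal(self.alleles, other.alleles)


class AlleleFrequencyTable:
    """Per-locus allele frequencies for L codominant loci.

    Parameters
    ----------
    frequencies
        One mapping per locus from integer allele label (>= 1) to frequency.
        Frequencies at a locus must be positive and sum to one, with at least
        two alleles per locus.
    loci
        Optional locus names; defaults to ``L01 ... Lxx``.
    """

    def __init__(self, frequencies: list[dict[int, float]], loci: list[str] | None = None):
        if not frequencies:
            raise ValueError("need at least one locus")
        self.frequencies: list[dict[int, float]] = []
        for i, f in enumerate(frequencies):
            if len(f) < 2:
                raise ValueError(f"locus {i}: need >= 2 alleles")
            if any(a < 1 for a in f):
                raise ValueError(f"locus {i}: allele labels must be positive integers")
            vals = np.array(list(f.values()), dtype=float)
            if np.any(vals <= 0):
                raise ValueError(f"locus {i}: frequencies must be > 0")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"locus {i}: frequencies sum to {vals.sum()}, not 1")
            self.frequencies.append({int(a): float(p) for a, p in sorted(f.items())})
        self.loci = list(loci) if loci is not None else [f"L{i + 1:02d}" for i in range(len(frequencies))]
        if len(self.loci) != len(self.frequencies):
            raise ValueError("loci and frequencies length mismatch")

    @property
    def n_loci(self) -> int:
        return len(self.frequencies)

    @property
    def max_allele(self) -> int:
        return max(max(f) for f in self.frequencies)

    def alleles_at(self, locus: int) -> np.ndarray:
        return np.array(sorted(self.frequencies[locus]), dtype=np.int64)

    def freq_matrix(self) -> np.ndarray:
        """Dense (L, max_allele + 1) matrix indexed by allele label (0 unused)."""
        F = np.zeros((self.n_loci, self.max_allele + 1))
        for i, f in enumerate(self.frequencies):
            for a, p in f.items():
                F[i, a] = p
        return F

    def expected_heterozygosity(self) -> np.ndarray:
        """Per-locus expected heterozygosity 1 - sum(p^2)."""
        return np.array([1.0 - sum(p * p for p in f.values()) for f in self.frequencies])

    def sample_genotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n unrelated genotypes in Hardy-Weinberg proportions, shape (n, L, 2)."""
        G = np.zeros((n, self.n_loci, 2), dtype=np.int64)
        for i, f in enumerate(self.frequencies):
            alleles = np.array(list(f), dtype=np.int64)
            probs = np.array([f[a] for a in alleles])
            G[:, i, :] = rng.choice(alleles, size=(n, 2), p=probs)
        return np.sort(G, axis=-1)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": self.loci[i], "allele": a, "frequency": p}
            for i, f in enumerate(self.frequencies)
            for a, p in f.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleFrequencyTable":
        loci = list(dict.fromkeys(df["locus"]))
        freqs = [
            dict(zip(sub["allele"].astype(int), sub["frequency"].astype(float)))
            for _, sub in ((l, df[df["locus"] == l]) for l in loci)
        ]
        return cls(freqs, loci)

    @classmethod
    def from_genotypes(cls, G: np.ndarray, loci: list[str] | None = None) -> "AlleleFrequencyTable":
        """Estimate frequencies by allele counting over genotypes (n, L, 2)."""
        G = np.asarray(G, dtype=np.int64)
        freqs = []
        for i in range(G.shape[1]):
            col = G[:, i, :].ravel()
            col = col[col > 0]
            if col.size == 0:
                raise ValueError(f"locus {i}: no typed individuals")
            alleles, counts = np.unique(col, return_counts=True)
            total = counts.sum()
            freqs.append({int(a): c / total for a, c in zip(alleles, counts)})
        return cls(freqs, loci)


@dataclass(frozen=True)
class ErrorModel:
    """Per-PCR genotyping error process for noninvasive samples.

    dropout
        Probability that a given true allele fails to amplify in one PCR
        (each allele of a heterozygote drops independently).
    false_allele
        Probability that an amplified allele is mis-scored as a different
        allele of the same locus (uniform over the other alleles).
    failure
        Probability that the whole locus yields no product in one PCR.
    """

    dropout: float = 0.01
    false_allele: float = 0.01
    failure: float = 0.0

    def __post_init__(self):
        for name in ("dropout", "false_allele", "failure"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} rate must be in [0, 1], got {v}")

    @property
    def error_free(self) -> bool:
        return self.dropout == 0.0 and self.false_allele == 0.0 and self.failure == 0.0
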