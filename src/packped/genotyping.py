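"""Consensus genotyping and individual identification from replicate PCRs.

Noninvasive (fecal) DNA yields noisy, partial genotypes, so every call is
built from replicate amplifications: a heterozygote needs the same two
alleles in at least two independent PCRs, a homozygote needs the same single
allele in at least three.  Samples amplifying at fewer than five loci in the
initial two PCRs are discarded.  Consensus genotypes are then merged into
unique individuals, tolerating one allelic-dropout mismatch per pair of
samples, and single-detection genotypes get a Bayesian reliability score.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencyTable, ErrorModel, sort_pairs

__all__ = [
    "ConsensusGenotype",
    "IndividualCatalog",
    "screen_sample",
    "call_consensus",
    "match_genotypes",
    "cluster_samples",
    "reliability_score",
    "consensus_table",
]

STATUS_MISSING = "missing"
STATUS_HET = "het-confirmed"
STATUS_HOM = "hom-confirmed"

MIN_HET_PCRS = 2
MIN_HOM_PCRS = 3
MIN_SCREEN_LOCI = 5
DEFAULT_MIN_SHARED_LOCI = 10


@dataclass
class ConsensusGenotype:
    """Per-sample consensus calls; unconfirmed loci are missing (0, 0)."""

    sample_id: object
    alleles: np.ndarray          # (L, 2), 0 = missing
    status: np.ndarray           # (L,) of STATUS_* strings
    loci: list

    @property
    def confirmed_mask(self) -> np.ndarray:
        return self.status != STATUS_MISSING

    @property
    def n_confirmed(self) -> int:
        return int(self.confirmed_mask.sum())


def _replicate_arrays(reps: pd.DataFrame, loci: list) -> dict:
    """locus -> list of observed unordered allele pairs (amplified reps only)."""
    out = {l: [] for l in loci}
    for _, row in reps.iterrows():
        a1, a2 = int(row["allele1"]), int(row["allele2"])
        if a1 <= 0 and a2 <= 0:
            continue
        out[row["locus"]].append(tuple(sorted((a1, a2))))
    return out


def screen_sample(reps: pd.DataFrame, min_loci: int = MIN_SCREEN_LOCI) -> bool:
    """Keep a sample iff >= ``min_loci`` loci amplified in its first two PCRs."""
    if reps.empty:
        raise ValueError("sample has no replicates")
    first_two = reps[reps["replicate"] < 2]
    amped = first_two[(first_two["allele1"] > 0) | (first_two["allele2"] > 0)]
    return amped["locus"].nunique() >= min_loci


def call_consensus(reps: pd.DataFrame, loci: list | None = None) -> ConsensusGenotype:
    """Consensus genotype for one screened sample from all its replicates.

    Per locus: a heterozygous pair seen in >= 2 PCRs confirms a heterozygote;
    a lone allele seen in >= 3 PCRs with no other allele replicated confirms
    a homozygote (a second allele itself seen in >= 2 PCRs vetoes the call);
    anything else is missing.  Conflicting multiply-confirmed heterozygote
    pairs also yield missing.
    """
    if loci is None:
        loci = sorted(reps["locus"].unique())
    sample_id = reps["sample_id"].iloc[0] if "sample_id" in reps else None
    by_locus = _replicate_arrays(reps, loci)

    L = len(loci)
    alleles = np.zeros((L, 2), dtype=np.int64)
    status = np.full(L, STATUS_MISSING, dtype=object)
    for i, locus in enumerate(loci):
        pairs = by_locus[locus]
        if not pairs:
            continue
        het_counts: dict[tuple, int] = {}
        allele_presence: dict[int, int] = {}   # PCRs in which each allele appeared
        hom_counts: dict[int, int] = {}        # PCRs seen as a lone allele
        for (a, b) in pairs:
            for al in {a, b} - {0}:
                allele_presence[al] = allele_presence.get(al, 0) + 1
            if a != b and a > 0:
                het_counts[(a, b)] = het_counts.get((a, b), 0) + 1
            elif a == b:
                hom_counts[a] = hom_counts.get(a, 0) + 1
        confirmed_hets = [p for p, c in het_counts.items() if c >= MIN_HET_PCRS]
        if len(confirmed_hets) == 1:
            alleles[i] = confirmed_hets[0]
            status[i] = STATUS_HET
            continue
        if confirmed_hets:
            continue  # conflicting confirmed heterozygotes -> missing
        for a, c in sorted(hom_counts.items()):
            if c >= MIN_HOM_PCRS:
                second = [al for al, n in allele_presence.items()
                          if al != a and n >= MIN_HET_PCRS]
                if not second:
                    alleles[i] = (a, a)
                    status[i] = STATUS_HOM
                break
    return ConsensusGenotype(sample_id, alleles, status, list(loci))


def match_genotypes(g1: ConsensusGenotype, g2: ConsensusGenotype,
                    min_shared_loci: int = DEFAULT_MIN_SHARED_LOCI) -> str:
    """Dropout-tolerant identity test between two consensus genotypes.

    Over jointly confirmed loci: 'same-individual' when identical except at
    most one locus where one genotype is homozygous for an allele of the
    other's heterozygote (a single-dropout pattern, e.g. 102/102 vs 102/106);
    'different' on any incompatible locus or two dropout-pattern mismatches;
    'indeterminate' with too few shared confirmed loci.  Symmetric.
    """
    shared = g1.confirmed_mask & g2.confirmed_mask
    if int(shared.sum()) < min_shared_loci:
        return "indeterminate"
    dropout_mismatches = 0
    for i in np.where(shared)[0]:
        p1, p2 = tuple(g1.alleles[i]), tuple(g2.alleles[i])
        if p1 == p2:
            continue
        hom, het = (p1, p2) if p1[0] == p1[1] else (p2, p1)
        if hom[0] == hom[1] and het[0] != het[1] and hom[0] in het:
            dropout_mismatches += 1
            if dropout_mismatches > 1:
                return "different"
        else:
            return "different"
    return "same-individual"


@dataclass
class CatalogEntry:
    individual_id: int
    genotype: ConsensusGenotype
    sample_ids: list
    members: list  # member ConsensusGenotypes


@dataclass
class IndividualCatalog:
    """Unique individuals with representative genotypes and detection counts."""

    entries: list

    def __len__(self):
        return len(self.entries)

    def genotype_array(self) -> np.ndarray:
        return np.stack([e.genotype.alleles for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"individual_id": e.individual_id,
             "n_detections": len(e.sample_ids),
             "sample_ids": ";".join(str(s) for s in e.sample_ids),
             "n_confirmed_loci": e.genotype.n_confirmed}
            for e in self.entries
        ])


def _representative(members: list, loci: list) -> ConsensusGenotype:
    """Per-locus consensus of member genotypes; het evidence overrides
    dropout homozygotes."""
    L = len(loci)
    alleles = np.zeros((L, 2), dtype=np.int64)
    status = np.full(L, STATUS_MISSING, dtype=object)
    for i in range(L):
        hets = [tuple(m.alleles[i]) for m in members if m.status[i] == STATUS_HET]
        homs = [tuple(m.alleles[i]) for m in members if m.status[i] == STATUS_HOM]
        if hets:
            # majority het pair, ties broken by allele order
            vals, counts = np.unique(np.array(hets), axis=0, return_counts=True)
            alleles[i] = vals[np.argmax(counts)]
            status[i] = STATUS_HET
        elif homs:
            vals, counts = np.unique(np.array(homs), axis=0, return_counts=True)
            alleles[i] = vals[np.argmax(counts)]
            status[i] = STATUS_HOM
    return ConsensusGenotype("representative", alleles, status, list(loci))


def cluster_samples(genotypes: list, min_shared_loci: int = DEFAULT_MIN_SHARED_LOCI) -> IndividualCatalog:
    """Greedy agglomeration of consensus genotypes into unique individuals.

    Samples are processed in order of decreasing confirmed-locus count
    (sample id ascending as tie-break); each joins the first existing entry
    it matches as 'same-individual', else founds a new entry.  Entry
    representatives are refreshed after each join.
    """
    order = sorted(genotypes, key=lambda g: (-g.n_confirmed, str(g.sample_id)))
    entries: list[CatalogEntry] = []
    for g in order:
        placed = False
        for e in entries:
            if match_genotypes(g, e.genotype, min_shared_loci) == "same-individual":
                e.members.append(g)
                e.sample_ids.append(g.sample_id)
                e.genotype = _representative(e.members, g.loci)
                placed = True
                break
        if not placed:
            entries.append(CatalogEntry(len(entries), _representative([g], g.loci),
                                        [g.sample_id], [g]))
    return IndividualCatalog(entries)


def _genotype_space(alleles: np.ndarray) -> list[tuple[int, int]]:
    return list(combinations_with_replacement(sorted(alleles), 2))


def _pcr_emission(true_pair: tuple, obs_pair: tuple, alleles: np.ndarray,
                  error: ErrorModel) -> float:
    """P(one PCR shows obs_pair | true genotype), enumerating per-allele fates.

    Each true allele: drops out (d), amplifies correctly ((1-d)(1-f)), or is
    mis-scored as each other allele ((1-d) f / (k-1)).  A lone surviving
    allele reads as an apparent homozygote; both lost reads as no product.
    """
    d, f = error.dropout, error.false_allele
    k = len(alleles)
    obs = tuple(sorted(obs_pair))
    total = 0.0
    fail = error.failure
    # locus-level failure
    if obs == (0, 0):
        total += fail
    scale = 1.0 - fail

    def fate_probs(true_allele):
        out = [(0, d)]
        out.append((int(true_allele), (1 - d) * (1 - f)))
        if k > 1 and f > 0:
            for z in alleles:
                if z != true_allele:
                    out.append((int(z), (1 - d) * f / (k - 1)))
        return out

    for x, px in fate_probs(true_pair[0]):
        for y, py in fate_probs(true_pair[1]):
            survivors = tuple(sorted(v for v in (x, y) if v != 0))
            if not survivors:
                shown = (0, 0)
            elif len(survivors) == 1:
                shown = (survivors[0], survivors[0])
            else:
                shown = survivors
            if shown == obs:
                total += scale * px * py
    return total


def reliability_score(g: ConsensusGenotype, reps: pd.DataFrame,
                      freqs: AlleleFrequencyTable, error: ErrorModel,
                      threshold: float = 0.95) -> tuple[float, bool]:
    """Posterior probability that a single-sample consensus genotype is true.

    Per confirmed locus, Bayes over all true genotypes with Hardy-Weinberg
    priors and the per-PCR emission model; the sample score is the product
    over confirmed loci.  Returns (score, score >= threshold).
    """
    by_locus = {l: [] for l in g.loci}
    for _, row in reps.iterrows():
        by_locus[row["locus"]].append((int(row["allele1"]), int(row["allele2"])))
    score = 1.0
    for i, locus in enumerate(g.loci):
        if g.status[i] == STATUS_MISSING:
            continue
        li = freqs.loci.index(locus) if locus in freqs.loci else i
        fdict = freqs.frequencies[li]
        called = tuple(g.alleles[i])
        for a in called:
            if a not in fdict:
                raise KeyError(f"allele {a} at locus {locus} absent from frequency table")
        alleles = freqs.alleles_at(li)
        posts = {}
        for t in _genotype_space(alleles):
            prior = fdict[t[0]] ** 2 if t[0] == t[1] else 2 * fdict[t[0]] * fdict[t[1]]
            lik = 1.0
            for obs in by_locus[locus]:
                lik *= _pcr_emission(t, obs, alleles, error)
            posts[t] = prior * lik
        z = sum(posts.values())
        if z == 0:
            score *= 0.0
            continue
        score *= posts.get(called, 0.0) / z
    return float(score), bool(score >= threshold)


def consensus_table(replicates: pd.DataFrame, loci: list | None = None,
                    min_screen_loci: int = MIN_SCREEN_LOCI) -> list:
    """Screen and call consensus for every sample in a replicate table."""
    if loci is None:
        loci = sorted(replicates["locus"].unique())
    out = []
    for sid, reps in replicates.groupby("sample_id"):
        if not screen_sample(reps, min_screen_loci):
            continue
        out.append(call_consensus(reps, loci))
    return out
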