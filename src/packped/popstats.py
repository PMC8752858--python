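"""Population-level summaries: heterozygosity, yearly allele frequencies,
genotype-recapture harvest rates, pair-bond histories and apparent survival.

Apparent survival of a pup is re-detection 15 months after birth: present in
the next summer's catalog means alive; detected only among that year's
harvested animals, or absent everywhere, means dead.  The annual harvest rate
is the fraction of summer-detected genotypes re-detected among harvest
tissues, matched under the same dropout-tolerant rule used for individual
identification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencyTable, as_allele_array
from .genotyping import (DEFAULT_MIN_SHARED_LOCI, ConsensusGenotype, STATUS_HET,
                         STATUS_HOM, STATUS_MISSING, match_genotypes)

__all__ = [
    "HeterozygosityRecord",
    "observed_heterozygosity",
    "heterozygosity_table",
    "yearly_allele_frequencies",
    "harvest_rate",
    "build_pair_histories",
    "apparent_survival",
    "consensus_from_array",
]


@dataclass
class HeterozygosityRecord:
    individual_id: object
    n_typed: int
    n_het: int

    @property
    def ho(self) -> float:
        return self.n_het / self.n_typed


def observed_heterozygosity(g, individual_id=None) -> HeterozygosityRecord:
    """Fraction of typed loci at which the individual is heterozygous."""
    arr = as_allele_array(g)
    typed = (arr > 0).all(axis=1)
    n_typed = int(typed.sum())
    if n_typed == 0:
        raise ValueError("observed heterozygosity undefined: no typed loci")
    n_het = int((typed & (arr[:, 0] != arr[:, 1])).sum())
    return HeterozygosityRecord(individual_id, n_typed, n_het)


def heterozygosity_table(genotypes: dict) -> pd.DataFrame:
    """Individual H_o records; the population mean weights individuals equally."""
    rows = []
    for i, g in genotypes.items():
        rec = observed_heterozygosity(g, i)
        rows.append({"individual_id": i, "n_typed": rec.n_typed,
                     "n_het": rec.n_het, "ho": rec.ho})
    return pd.DataFrame(rows)


def yearly_allele_frequencies(G, loci: list | None = None) -> AlleleFrequencyTable:
    """Allele frequencies by counting over genotypes (n, L, 2); missing
    alleles excluded.  Loci with fewer than two observed alleles are dropped
    with a warning."""
    G = np.asarray(G, dtype=np.int64)
    if loci is None:
        loci = [f"L{i + 1:02d}" for i in range(G.shape[1])]
    freqs, kept = [], []
    for i in range(G.shape[1]):
        col = G[:, i, :].ravel()
        col = col[col > 0]
        alleles, counts = (np.unique(col, return_counts=True) if col.size
                           else (np.array([]), np.array([])))
        if len(alleles) < 2:
            warnings.warn(f"locus {loci[i]} dropped: fewer than two observed alleles")
            continue
        total = counts.sum()
        freqs.append({int(a): c / total for a, c in zip(alleles, counts)})
        kept.append(loci[i])
    if not freqs:
        raise ValueError("no polymorphic loci with typed individuals")
    return AlleleFrequencyTable(freqs, kept)


def consensus_from_array(alleles, loci: list | None = None,
                         sample_id=None) -> ConsensusGenotype:
    """Wrap a plain genotype array as a fully confirmed consensus genotype."""
    arr = as_allele_array(alleles)
    if loci is None:
        loci = [f"L{i + 1:02d}" for i in range(arr.shape[0])]
    status = np.full(arr.shape[0], STATUS_MISSING, dtype=object)
    typed = (arr > 0).all(axis=1)
    status[typed & (arr[:, 0] != arr[:, 1])] = STATUS_HET
    status[typed & (arr[:, 0] == arr[:, 1])] = STATUS_HOM
    return ConsensusGenotype(sample_id, arr, status, list(loci))


def _as_consensus(g, loci=None):
    return g if isinstance(g, ConsensusGenotype) else consensus_from_array(g, loci)


def harvest_rate(summer_catalog: list, harvest_genotypes: list,
                 min_shared_loci: int = DEFAULT_MIN_SHARED_LOCI) -> float:
    """Matched harvest genotypes / summer catalog size (genetic recapture).

    Both inputs are lists of genotypes (arrays or consensus objects); a
    harvest genotype counts as matched if it is 'same-individual' with any
    summer entry under the dropout-tolerant rule.
    """
    if not summer_catalog:
        raise ValueError("harvest rate undefined: empty summer catalog")
    summer = [_as_consensus(g) for g in summer_catalog]
    matched = 0
    for h in harvest_genotypes:
        hc = _as_consensus(h)
        if any(match_genotypes(hc, s, min_shared_loci) == "same-individual"
               for s in summer):
            matched += 1
    return matched / len(summer)


def build_pair_histories(events: pd.DataFrame) -> pd.DataFrame:
    """Pair-year records from breeding events (dam_id, sire_id, year, group).

    Pair-bond duration is 1 at the pair's first breeding event and increments
    with each subsequent breeding year (a gap year does not reset the
    counter).  Polygamy is flagged when more than one female gave birth in
    the same group-year.
    """
    ev = (events[["dam_id", "sire_id", "year", "group"]]
          .drop_duplicates()
          .sort_values(["dam_id", "sire_id", "year"])
          .reset_index(drop=True))
    ev["pair_id"] = ev.dam_id.astype(str) + "x" + ev.sire_id.astype(str)
    ev["years_paired"] = ev.groupby("pair_id").cumcount() + 1
    dams_per_gy = events.groupby(["group", "year"])["dam_id"].nunique()
    ev["polygamy"] = [
        dams_per_gy.get((g, y), 1) > 1 for g, y in zip(ev["group"], ev["year"])
    ]
    return ev


def apparent_survival(pups: list, next_summer_catalog: list, harvest_genotypes: list,
                      min_shared_loci: int = DEFAULT_MIN_SHARED_LOCI) -> pd.DataFrame:
    """Alive/dead at 15 months for a pup cohort by genotype re-detection.

    ``pups`` is a list of (pup_id, genotype).  A pup re-detected in the next
    summer catalog is alive; one matched only among harvest tissues of its
    first year is dead (harvested); one absent from both is presumed dead.
    """
    summer = [_as_consensus(g) for g in next_summer_catalog]
    harvest = [_as_consensus(g) for g in harvest_genotypes]
    rows = []
    for pup_id, g in pups:
        pc = _as_consensus(g)
        in_summer = any(match_genotypes(pc, s, min_shared_loci) == "same-individual"
                        for s in summer)
        in_harvest = (not in_summer and
                      any(match_genotypes(pc, h, min_shared_loci) == "same-individual"
                          for h in harvest))
        rows.append({"pup_id": pup_id, "alive": int(in_summer),
                     "harvested": bool(in_harvest)})
    return pd.DataFrame(rows)
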