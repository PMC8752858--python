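"""End-to-end orchestration of the analysis stages on simulated data.

Runs the full chain — replicate PCRs, screening, consensus calling,
individual identification, per-year parentage, sneaker-sire reconstruction,
harvest rates by genotype recapture, apparent survival and pair histories —
against a :class:`~packped.simulate.TruePopulation`, so that every output can
be compared with the generating truth.  Sex and age of candidate parents come
from the metadata the study design supplies (here, the simulation truth).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import ErrorModel
from .genotyping import (DEFAULT_MIN_SHARED_LOCI, cluster_samples, consensus_table)
from .parentage import ParentageModel, assign_parentage, reconstruct_sneaker
from .popstats import (apparent_survival, build_pair_histories, harvest_rate,
                       yearly_allele_frequencies)
from .simulate import TruePopulation, simulate_harvest_tissues, simulate_noninvasive_samples

__all__ = ["PipelineResult", "analyze_simulation"]


@dataclass
class PipelineResult:
    catalog: object
    entry_truth: dict          # catalog individual_id -> true individual id
    pedigree: pd.DataFrame     # offspring_id (true id), dam_id, sire_id, method, year, group
    sneakers: list             # ReconstructedSire objects
    harvest_rates: dict        # year -> genetic recapture rate
    survival: pd.DataFrame     # pup_id (true id), alive, harvested
    pair_years: pd.DataFrame


def analyze_simulation(pop: TruePopulation, error: ErrorModel,
                       rng: np.random.Generator | None = None,
                       min_shared_loci: int = DEFAULT_MIN_SHARED_LOCI,
                       replicates: pd.DataFrame | None = None) -> PipelineResult:
    """Run the whole pipeline on one simulated population."""
    cfg = pop.config
    if replicates is None:
        replicates = simulate_noninvasive_samples(pop, error, cfg, rng)
    genos = consensus_table(replicates)
    catalog = cluster_samples(genos, min_shared_loci)

    # ground-truth identity of each catalog entry (majority over member samples)
    sample_truth = dict(zip(replicates["sample_id"], replicates["individual_id"]))
    entry_truth = {}
    for e in catalog.entries:
        counts = Counter(sample_truth[s] for s in e.sample_ids)
        entry_truth[e.individual_id] = counts.most_common(1)[0][0]

    # detection years per entry, from member samples
    sample_year = replicates.groupby("sample_id")["year"].first()
    entry_years: dict[int, set] = {}
    for e in catalog.entries:
        entry_years[e.individual_id] = {int(sample_year[s]) for s in e.sample_ids}

    meta = pop.individuals.set_index("id")
    freqs = pop.freqs
    model = ParentageModel(freqs, error)

    ped_rows = []
    sneakers = []
    surv_frames = []
    hr = {}
    for year in range(cfg.years):
        detected = [e for e in catalog.entries if year in entry_years[e.individual_id]]
        if not detected:
            continue
        # candidate parents: sampled adults >= 2 years old in the pup's birth year
        dams, sires = {}, {}
        for e in detected:
            tid = entry_truth[e.individual_id]
            if year - int(meta.at[tid, "birth_year"]) < 2:
                continue
            pool = dams if meta.at[tid, "sex"] == "F" else sires
            pool[tid] = e.genotype.alleles
        # pups: entries whose true individual was born this year
        pups = [(entry_truth[e.individual_id], e)
                for e in detected
                if int(meta.at[entry_truth[e.individual_id], "birth_year"]) == year]

        dam_offspring: dict[tuple, dict] = {}
        for tid, e in pups:
            a = assign_parentage(tid, e.genotype.alleles, dams, sires, freqs,
                                 error, model=model)
            group = int(meta.at[tid, "group"])
            ped_rows.append({"offspring_id": tid, "dam_id": a.dam_id,
                             "sire_id": a.sire_id, "method": a.method,
                             "score": a.score, "mismatches": a.mismatches,
                             "year": year, "group": group})
            if a.dam_id is not None and a.sire_id is None:
                dam_offspring.setdefault((a.dam_id, year, group), {})[tid] = \
                    e.genotype.alleles
        for (dam_id, y, group), off in dam_offspring.items():
            rs = reconstruct_sneaker(dams[dam_id], off, freqs,
                                     sire_id=f"sneaker-{dam_id}-{y}")
            sneakers.append(rs)

        # genetic-recapture harvest rate and pup apparent survival
        summer_genos = [e.genotype for e in detected]
        tissues = simulate_harvest_tissues(pop, year)
        t_ids = list(dict.fromkeys(tissues["id"])) if len(tissues) else []
        t_arrays = [pop.genotypes[i] for i in t_ids]
        if summer_genos:
            hr[year] = harvest_rate(summer_genos, t_arrays, min_shared_loci)
        if pups and year + 1 < cfg.years:
            next_detected = [e.genotype for e in catalog.entries
                             if year + 1 in entry_years[e.individual_id]]
            surv = apparent_survival([(tid, e.genotype) for tid, e in pups],
                                     next_detected, t_arrays, min_shared_loci)
            surv["year"] = year
            surv_frames.append(surv)

    pedigree = pd.DataFrame(ped_rows)
    survival = (pd.concat(surv_frames, ignore_index=True) if surv_frames
                else pd.DataFrame(columns=["pup_id", "alive", "harvested", "year"]))
    assigned = pedigree.dropna(subset=["dam_id"]) if len(pedigree) else pedigree
    pair_years = (build_pair_histories(assigned.fillna({"sire_id": -999}))
                  if len(assigned) else pd.DataFrame())
    return PipelineResult(catalog, entry_truth, pedigree, sneakers, hr,
                          survival, pair_years)
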