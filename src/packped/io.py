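"""CSV helpers for the pipeline's tabular interchange formats.

All genotype tables are long format with integer allele labels and 0 for a
missing / non-amplified allele: one row per (id, locus) with allele1 and
allele2 columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotyping import ConsensusGenotype, IndividualCatalog
from .simulate import TruePopulation

__all__ = [
    "genotype_frame_to_arrays",
    "arrays_to_genotype_frame",
    "consensus_to_frame",
    "catalog_genotype_frame",
    "write_truth",
]


def genotype_frame_to_arrays(df: pd.DataFrame, loci: list,
                             id_col: str = "id") -> tuple[list, np.ndarray]:
    """Pivot a long genotype frame into ids and an (n, L, 2) allele array."""
    ids = list(dict.fromkeys(df[id_col]))
    idx = {l: i for i, l in enumerate(loci)}
    G = np.zeros((len(ids), len(loci), 2), dtype=np.int64)
    pos = {v: i for i, v in enumerate(ids)}
    for _, row in df.iterrows():
        i, l = pos[row[id_col]], idx[row["locus"]]
        G[i, l] = sorted((int(row["allele1"]), int(row["allele2"])))
    return ids, G


def arrays_to_genotype_frame(ids, G: np.ndarray, loci: list,
                             id_col: str = "id") -> pd.DataFrame:
    rows = []
    for i, ident in enumerate(ids):
        for l, locus in enumerate(loci):
            rows.append({id_col: ident, "locus": locus,
                         "allele1": int(G[i, l, 0]), "allele2": int(G[i, l, 1])})
    return pd.DataFrame(rows)


def consensus_to_frame(genotypes: list[ConsensusGenotype]) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        for i, locus in enumerate(g.loci):
            rows.append({"sample_id": g.sample_id, "locus": locus,
                         "allele1": int(g.alleles[i, 0]),
                         "allele2": int(g.alleles[i, 1]),
                         "status": g.status[i]})
    return pd.DataFrame(rows)


def catalog_genotype_frame(catalog: IndividualCatalog) -> pd.DataFrame:
    rows = []
    for e in catalog.entries:
        g = e.genotype
        for i, locus in enumerate(g.loci):
            rows.append({"id": e.individual_id, "locus": locus,
                         "allele1": int(g.alleles[i, 0]),
                         "allele2": int(g.alleles[i, 1])})
    return pd.DataFrame(rows)


def write_truth(pop: TruePopulation, outdir) -> None:
    """Write truth_individuals.csv, truth_genotypes.csv and harvest.csv."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop.individuals.to_csv(outdir / "truth_individuals.csv", index=False)
    ids = sorted(pop.genotypes)
    G = np.stack([pop.genotypes[i] for i in ids])
    arrays_to_genotype_frame(ids, G, pop.freqs.loci).to_csv(
        outdir / "truth_genotypes.csv", index=False)
    pop.harvest.to_csv(outdir / "harvest.csv", index=False)
    pop.pups.to_csv(outdir / "truth_pups.csv", index=False)
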