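"""Pedigree reconstruction: likelihood parentage with an error model,
mismatch-tolerant exclusion, and reconstruction of unsampled sires.

The trio likelihood sums over true-genotype states of offspring and parents,
weighting by Hardy-Weinberg priors, a per-allele dropout / false-allele
emission model, and Mendelian transmission.  Candidate parents are all
sampled adults (>= 2 years old in the offspring's birth year); the
maximum-likelihood hypothesis is accepted when it beats the runner-up by a
configurable log-likelihood margin, otherwise exclusion with a two-allele
mismatch tolerance is tried.  Sires absent from the sample ("sneaker" males)
are reconstructed locus by locus from mother-offspring genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

from .genotypes import AlleleFrequencyTable, ErrorModel, as_allele_array
from .genotyping import _pcr_emission

__all__ = [
    "ParentageAssignment",
    "ReconstructedSire",
    "ParentageModel",
    "trio_loglik",
    "assign_parentage",
    "exclusion_check",
    "reconstruct_sneaker",
]

DEFAULT_CONFIDENCE_DELTA = 3.0
EXCLUSION_MAX_MISMATCH = 2


@dataclass
class ParentageAssignment:
    offspring_id: object
    dam_id: object = None
    sire_id: object = None
    method: str = "unassigned"      # likelihood | exclusion | unassigned
    score: float = np.nan           # log-likelihood ratio vs both-parents-unknown
    delta: float = np.nan           # margin over runner-up hypothesis
    mismatches: int | None = None


@dataclass
class ReconstructedSire:
    sire_id: object
    genotype: np.ndarray                   # (L, 2); 0 where unknown
    candidates: list = field(default_factory=list)  # per-locus candidate allele sets
    completeness: np.ndarray | None = None # per-locus fraction of alleles fixed
    offspring_ids: list = field(default_factory=list)


class _LocusModel:
    """Precomputed genotype space, HW priors, emission and transmission."""

    def __init__(self, fdict: dict, error: ErrorModel):
        self.alleles = np.array(sorted(fdict), dtype=np.int64)
        self.genos = list(combinations_with_replacement(self.alleles.tolist(), 2))
        self.index = {g: i for i, g in enumerate(self.genos)}
        G = len(self.genos)
        p = {a: fdict[a] for a in fdict}
        self.hw = np.array([p[a] ** 2 if a == b else 2 * p[a] * p[b]
                            for a, b in self.genos])
        # genotype-level emission, per-PCR error rates applied once to the
        # consensus call (amplification failure shows up as a missing locus,
        # which is skipped, so it is left out here)
        em_error = ErrorModel(error.dropout, error.false_allele, 0.0)
        if error.dropout == 0.0 and error.false_allele == 0.0:
            self.E = np.eye(G)
        else:
            self.E = np.array([[_pcr_emission(t, o, self.alleles, em_error)
                                for o in self.genos] for t in self.genos])
        # Mendelian transmission T[td, ts, to]
        T = np.zeros((G, G, G))
        for i, td in enumerate(self.genos):
            for j, ts in enumerate(self.genos):
                for m in td:
                    for f in ts:
                        T[i, j, self.index[tuple(sorted((m, f)))]] += 0.25
        self.T = T
        # single-parent transmission T1[td, to]: other allele from the population
        T1 = np.zeros((G, G))
        for i, td in enumerate(self.genos):
            for m in td:
                for a in self.alleles.tolist():
                    T1[i, self.index[tuple(sorted((m, a)))]] += 0.5 * p[a]
        self.T1 = T1


class ParentageModel:
    """Trio-likelihood machinery for a frequency table and error model."""

    def __init__(self, freqs: AlleleFrequencyTable, error: ErrorModel | None = None):
        self.freqs = freqs
        self.error = error or ErrorModel(0.0, 0.0, 0.0)
        self.loci = [_LocusModel(f, self.error) for f in freqs.frequencies]

    def _geno_idx(self, lm: _LocusModel, pair) -> int | None:
        a, b = int(pair[0]), int(pair[1])
        if a <= 0 or b <= 0:
            return None
        key = (a, b) if a <= b else (b, a)
        if key not in lm.index:
            raise KeyError(f"genotype {key} has alleles absent from frequency table")
        return lm.index[key]

    def _weights(self, lm: _LocusModel, idx: int) -> np.ndarray:
        """Posterior-unnormalized weight over true genotypes given observed one."""
        return lm.hw * lm.E[:, idx]

    def trio_loglik(self, off, dam, sire) -> float:
        """log P(observed offspring genotype | observed parent genotypes),
        accumulated over loci typed in all three members."""
        off, dam, sire = as_allele_array(off), as_allele_array(dam), as_allele_array(sire)
        total, used = 0.0, 0
        for l, lm in enumerate(self.loci):
            io, id_, is_ = (self._geno_idx(lm, off[l]), self._geno_idx(lm, dam[l]),
                            self._geno_idx(lm, sire[l]))
            if io is None or id_ is None or is_ is None:
                continue
            used += 1
            wd, ws = self._weights(lm, id_), self._weights(lm, is_)
            eo = lm.E[:, io]
            M = lm.T @ eo                      # (G, G)
            num = wd @ M @ ws
            den = wd.sum() * ws.sum()
            with np.errstate(divide="ignore"):
                total += float(np.log(num / den)) if num > 0 else -np.inf
        if used == 0:
            raise ValueError("no jointly typed loci: trio likelihood undefined")
        return total

    def hypothesis_logliks(self, off, dam_genotypes: dict, sire_genotypes: dict):
        """Log-likelihoods of every parentage hypothesis for one offspring.

        Returns (pair (n_d, n_s) matrix, dam_only (n_d,), sire_only (n_s,),
        none scalar), each the conditional log-probability of the offspring's
        observed genotype.
        """
        off = as_allele_array(off)
        dam_ids = list(dam_genotypes)
        sire_ids = list(sire_genotypes)
        nd, ns = len(dam_ids), len(sire_ids)
        ll_pair = np.zeros((nd, ns))
        ll_dam = np.zeros(nd)
        ll_sire = np.zeros(ns)
        ll_none = 0.0
        D = [as_allele_array(dam_genotypes[i]) for i in dam_ids]
        S = [as_allele_array(sire_genotypes[i]) for i in sire_ids]
        for l, lm in enumerate(self.loci):
            io = self._geno_idx(lm, off[l])
            if io is None:
                continue
            eo = lm.E[:, io]
            p_none = float(lm.hw @ eo)
            M = lm.T @ eo       # (G, G): P(obs_o | td, ts) premarginalized
            m1 = lm.T1 @ eo     # (G,): P(obs_o | td, unknown)

            # a parent untyped at this locus carries its HW prior as weight,
            # which reduces its transmission term exactly to p_none
            def weight_matrix(genos):
                W = np.empty((len(genos), len(lm.hw)))
                for i, g in enumerate(genos):
                    idx = self._geno_idx(lm, g[l])
                    W[i] = lm.hw if idx is None else self._weights(lm, idx)
                return W

            Wd, Ws = weight_matrix(D), weight_matrix(S)
            sd, ss = Wd.sum(axis=1), Ws.sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll_none += np.log(p_none)
                if nd:
                    ll_dam += np.log((Wd @ m1) / sd)
                if ns:
                    ll_sire += np.log((Ws @ m1) / ss)
                if nd and ns:
                    ll_pair += np.log((Wd @ M @ Ws.T) / np.outer(sd, ss))
        return ll_pair, ll_dam, ll_sire, ll_none


def trio_loglik(off, dam, sire, freqs: AlleleFrequencyTable,
                error: ErrorModel | None = None) -> float:
    """Convenience wrapper; see :meth:`ParentageModel.trio_loglik`."""
    return ParentageModel(freqs, error).trio_loglik(off, dam, sire)


def exclusion_check(off, dam, sire) -> tuple[int, bool]:
    """Count offspring alleles unexplainable by the proposed parents.

    Per jointly typed locus, the minimum over the two maternal/paternal
    assignments of (maternal allele not in dam) + (paternal allele not in
    sire); summed over loci.  Accept when the total is <= 2, tolerating
    allelic dropout.
    """
    off, dam, sire = as_allele_array(off), as_allele_array(dam), as_allele_array(sire)
    total = 0
    for l in range(off.shape[0]):
        if min(off[l].min(), dam[l].min(), sire[l].min()) <= 0:
            continue
        o1, o2 = int(off[l, 0]), int(off[l, 1])
        d, s = set(dam[l].tolist()), set(sire[l].tolist())
        m1 = (o1 not in d) + (o2 not in s)
        m2 = (o2 not in d) + (o1 not in s)
        total += min(m1, m2)
    return total, total <= EXCLUSION_MAX_MISMATCH


def assign_parentage(offspring_id, off, dam_genotypes: dict, sire_genotypes: dict,
                     freqs: AlleleFrequencyTable, error: ErrorModel | None = None,
                     confidence_delta: float = DEFAULT_CONFIDENCE_DELTA,
                     model: ParentageModel | None = None) -> ParentageAssignment:
    """Assign dam and sire to one offspring among candidate parents.

    Evaluates all dam x sire pairs plus dam-only, sire-only and no-parent
    hypotheses (unknown parents integrated over Hardy-Weinberg genotype
    frequencies).  The top hypothesis is accepted when it leads the runner-up
    by ``confidence_delta`` log-units; otherwise a unique dam x sire pair
    surviving exclusion with <= 2 mismatching alleles is accepted; otherwise
    unassigned.
    """
    if model is None:
        model = ParentageModel(freqs, error)
    dam_ids, sire_ids = list(dam_genotypes), list(sire_genotypes)
    if not dam_ids and not sire_ids:
        return ParentageAssignment(offspring_id)

    ll_pair, ll_dam, ll_sire, ll_none = model.hypothesis_logliks(
        off, dam_genotypes, sire_genotypes)

    hyps = [((None, None), ll_none)]
    hyps += [((d, None), ll_dam[i]) for i, d in enumerate(dam_ids)]
    hyps += [((None, s), ll_sire[j]) for j, s in enumerate(sire_ids)]
    hyps += [((d, s), ll_pair[i, j])
             for i, d in enumerate(dam_ids) for j, s in enumerate(sire_ids)]
    order = sorted(range(len(hyps)), key=lambda k: hyps[k][1], reverse=True)
    (best_pair, best_ll) = hyps[order[0]]
    runner_ll = hyps[order[1]][1] if len(hyps) > 1 else -np.inf
    delta = best_ll - runner_ll
    score = best_ll - ll_none

    if np.isfinite(best_ll) and delta >= confidence_delta:
        mism = None
        if best_pair[0] is not None and best_pair[1] is not None:
            mism, _ = exclusion_check(off, dam_genotypes[best_pair[0]],
                                      sire_genotypes[best_pair[1]])
        return ParentageAssignment(offspring_id, best_pair[0], best_pair[1],
                                   "likelihood", score, delta, mism)

    # exclusion fallback over full pairs
    passing = []
    for d in dam_ids:
        for s in sire_ids:
            mism, ok = exclusion_check(off, dam_genotypes[d], sire_genotypes[s])
            if ok:
                passing.append((mism, d, s))
    if len(passing) == 1:
        mism, d, s = passing[0]
        i, j = dam_ids.index(d), sire_ids.index(s)
        return ParentageAssignment(offspring_id, d, s, "exclusion",
                                   ll_pair[i, j] - ll_none, delta, mism)
    return ParentageAssignment(offspring_id, None, None, "unassigned",
                               score, delta, None)


def reconstruct_sneaker(dam, offspring: dict, freqs: AlleleFrequencyTable,
                        sire_id="reconstructed") -> ReconstructedSire:
    """Reconstruct an unsampled sire from a dam and her offspring.

    Per locus each offspring contributes the allele not attributable to the
    dam (ambiguous when both could be maternal); singleton contributions fix
    paternal alleles and ambiguous sets are intersected across full siblings.
    Offspring incompatible with the dam at more than two alleles raise.
    """
    dam = as_allele_array(dam)
    off_ids = list(offspring)
    offs = {i: as_allele_array(offspring[i]) for i in off_ids}
    L = dam.shape[0]

    for oid, og in offs.items():
        incompat = 0
        for l in range(L):
            if min(og[l].min(), dam[l].min()) <= 0:
                continue
            if not (set(og[l].tolist()) & set(dam[l].tolist())):
                incompat += 1
        if incompat > 2:
            raise ValueError(f"offspring {oid} incompatible with dam at {incompat} loci")

    genotype = np.zeros((L, 2), dtype=np.int64)
    completeness = np.zeros(L)
    candidates: list[list[set]] = []
    for l in range(L):
        fixed: list[int] = []
        ambiguous: list[set] = []
        dset = set(int(a) for a in dam[l] if a > 0)
        if not dset:
            candidates.append([])
            continue
        for og in offs.values():
            o1, o2 = int(og[l, 0]), int(og[l, 1])
            if o1 <= 0 or o2 <= 0:
                continue
            cand = set()
            if o1 in dset:
                cand.add(o2)
            if o2 in dset:
                cand.add(o1)
            if not cand:
                continue  # dam-incompatible locus (tolerated above), skip
            if len(cand) == 1:
                a = next(iter(cand))
                if a not in fixed:
                    fixed.append(a)
            else:
                ambiguous.append(cand)
        fixed = sorted(fixed)[:2]
        if len(fixed) == 2:
            genotype[l] = fixed
            completeness[l] = 1.0
            candidates.append([set(fixed)])
        elif len(fixed) == 1:
            rest = [c - set(fixed) for c in ambiguous if not (set(fixed) & c)]
            second = set.intersection(*rest) if rest else set()
            genotype[l] = (fixed[0], next(iter(second)) if len(second) == 1 else 0)
            genotype[l] = np.sort(genotype[l])
            completeness[l] = 1.0 if len(second) == 1 else 0.5
            candidates.append([set(fixed), second])
        else:
            inter = set.intersection(*ambiguous) if ambiguous else set()
            candidates.append([inter])
            completeness[l] = 0.0
    return ReconstructedSire(sire_id, np.sort(genotype, axis=-1), candidates,
                             completeness, off_ids)
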