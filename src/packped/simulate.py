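"""Synthetic pack-living populations with noninvasive and harvest sampling.

The generator emulates a monitored, socially structured canid population:
each group holds a bonded breeding pair whose litters may instead be sired by
an unsampled "sneaker" male; pups survive their first 15 months according to
a logistic model on standardized covariates with a pair-level random
intercept; fall/winter harvest removes animals at a per-year rate; summer
fecal sampling yields replicate PCRs subject to allelic dropout, false
alleles and amplification failure.  Every downstream stage of the pipeline
can therefore be checked against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencyTable, ErrorModel

__all__ = [
    "SimulationConfig",
    "TruePopulation",
    "DEFAULT_SURVIVAL_COEFFS",
    "MIXED_SURVIVAL_COEFFS",
    "SURVIVAL_COVARIATES",
    "generate_allele_frequencies",
    "simulate_population",
    "simulate_noninvasive_samples",
    "simulate_harvest_tissues",
    "simulate_survival_dataset",
    "simulate_dyads",
]

SURVIVAL_COVARIATES = ["harvest_rate", "n_adults", "pair_ho", "density", "years_paired"]

# Default generating truth for pup survival (standardized logit scale): strong
# negative harvest effect, positive pair-tenure effect, weak diversity and
# density effects — the regime a harvested wolf population exhibits.
DEFAULT_SURVIVAL_COEFFS = {
    "harvest_rate": -0.56,
    "n_adults": 0.19,
    "pair_ho": -0.12,
    "density": -0.18,
    "years_paired": 0.28,
}
# Conditional (pair-random-intercept) scale analog used when simulating with
# a pair random effect.
MIXED_SURVIVAL_COEFFS = {
    "harvest_rate": -0.61,
    "n_adults": 0.19,
    "pair_ho": -0.01,
    "density": -0.13,
    "years_paired": 0.26,
}
DEFAULT_PAIR_RE_SD = 0.85

# Reference moments used to standardize covariates inline while the
# population is being generated (realized z-scoring would need the finished
# table, but survival feeds back into next year's group composition).
DEFAULT_COVARIATE_REFERENCE = {
    "harvest_rate": (0.12, 0.10),
    "n_adults": (6.0, 2.5),
    "pair_ho": (0.75, 0.07),
    "density": (15.0, 4.0),
    "years_paired": (2.0, 1.5),
}


def _default_harvest_schedule(years: int) -> tuple[float, ...]:
    # No harvest the first year, a pause in year 2, then sustained moderate
    # harvest — the on/off/on pattern of a newly opened public hunt.
    base = [0.0, 0.10, 0.0] + [0.22, 0.18, 0.25, 0.20, 0.24, 0.18, 0.22] * 4
    return tuple(base[:years])


@dataclass
class SimulationConfig:
    """Knobs for the population and sampling generator.

    Counts must be positive and probabilities lie in [0, 1]; litters are
    Poisson with the given mean; ``harvest_rates`` has one entry per year.
    """

    n_groups: int = 16
    years: int = 10
    n_loci: int = 18
    n_alleles: int = 8
    extra_adults_per_group: int = 2
    mean_litter: float = 4.3
    sneaker_prob: float = 0.12
    polygyny_prob: float = 0.05
    breeder_turnover: float = 0.12
    immigrant_prob: float = 0.7
    sneaker_hom_boost: float = 0.25
    survival_intercept: float = 0.02
    survival_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_SURVIVAL_COEFFS))
    pair_re_sd: float = DEFAULT_PAIR_RE_SD
    harvest_rates: tuple | None = None
    area_1000km2: float = 10.4
    samples_per_group_year: int = 65
    pcr_replicates: int = 4
    covariate_reference: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_REFERENCE))
    seed: int | None = None

    def __post_init__(self):
        for name in ("n_groups", "years", "n_loci", "n_alleles", "mean_litter",
                     "samples_per_group_year", "pcr_replicates", "area_1000km2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_alleles < 2:
            raise ValueError("need >= 2 alleles per locus")
        for name in ("sneaker_prob", "polygyny_prob", "breeder_turnover", "immigrant_prob",
                     "sneaker_hom_boost"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.harvest_rates is None:
            self.harvest_rates = _default_harvest_schedule(self.years)
        self.harvest_rates = tuple(float(h) for h in self.harvest_rates)
        if len(self.harvest_rates) != self.years:
            raise ValueError("harvest_rates must have one entry per year")
        if any(not 0.0 <= h <= 1.0 for h in self.harvest_rates):
            raise ValueError("harvest rates must be in [0, 1]")


def generate_allele_frequencies(
    L: int, k: int, seed=None, concentration: float = 1.0
) -> AlleleFrequencyTable:
    """Draw per-locus allele frequencies from a symmetric Dirichlet.

    Alleles are labeled 1..k at every locus.  Deterministic given the seed.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if k < 2:
        raise ValueError("need >= 2 alleles per locus")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freqs = []
    for _ in range(L):
        p = rng.dirichlet(np.full(k, concentration))
        p = np.clip(p, 1e-6, None)
        p = p / p.sum()
        freqs.append({a + 1: float(p[a]) for a in range(k)})
    return AlleleFrequencyTable(freqs)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class _Individual:
    __slots__ = ("id", "sex", "birth_year", "death_year", "group", "natal_group",
                 "dam", "sire", "is_sneaker", "is_founder")

    def __init__(self, id, sex, birth_year, group, dam=-1, sire=-1,
                 is_sneaker=False, is_founder=False):
        self.id = id
        self.sex = sex
        self.birth_year = birth_year
        self.death_year = None
        self.group = group
        self.natal_group = group
        self.dam = dam
        self.sire = sire
        self.is_sneaker = is_sneaker
        self.is_founder = is_founder


@dataclass
class TruePopulation:
    """Ground-truth population state produced by :func:`simulate_population`."""

    individuals: pd.DataFrame
    genotypes: dict  # id -> (L, 2) int array
    pups: pd.DataFrame
    breeding_events: pd.DataFrame
    harvest: pd.DataFrame
    members_by_year: dict  # (group, year) -> list of ids present in summer
    density_by_year: dict
    freqs: AlleleFrequencyTable
    config: SimulationConfig

    def genotype_array(self, ids) -> np.ndarray:
        return np.stack([self.genotypes[i] for i in ids])

    def alive_in_summer(self, year: int) -> list:
        df = self.individuals
        alive = df[(df.birth_year <= year) & (df.death_year.isna() | (df.death_year >= year))]
        return list(alive.id)


def _mendelian_offspring(dam_g: np.ndarray, sire_g: np.ndarray, rng) -> np.ndarray:
    L = dam_g.shape[0]
    mi = rng.integers(0, 2, size=L)
    pi = rng.integers(0, 2, size=L)
    off = np.stack([dam_g[np.arange(L), mi], sire_g[np.arange(L), pi]], axis=1)
    return np.sort(off, axis=-1)


def simulate_population(config: SimulationConfig, freqs: AlleleFrequencyTable | None = None,
                        rng: np.random.Generator | None = None) -> TruePopulation:
    """Run the multi-year pack demography and return full ground truth.

    Founders are drawn in Hardy-Weinberg proportions; each group's bonded
    pair breeds yearly (litter ~ Poisson), with sneaker siring and polygyny
    at the configured probabilities; pup survival to 15 months follows the
    configured logistic truth; harvest and breeder turnover create vacancies
    filled by immigrants or floaters.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if freqs is None:
        freqs = generate_allele_frequencies(config.n_loci, config.n_alleles, rng)

    inds: dict[int, _Individual] = {}
    genotypes: dict[int, np.ndarray] = {}
    next_id = [0]

    def new_individual(sex, birth_year, group, dam=-1, sire=-1, genotype=None,
                       is_sneaker=False, is_founder=False):
        i = next_id[0]
        next_id[0] += 1
        inds[i] = _Individual(i, sex, birth_year, group, dam, sire, is_sneaker, is_founder)
        if genotype is None:
            genotype = freqs.sample_genotypes(1, rng)[0]
        genotypes[i] = genotype
        return i

    def sneaker_genotype():
        g = freqs.sample_genotypes(1, rng)[0]
        if config.sneaker_hom_boost > 0:
            force = rng.random(config.n_loci) < config.sneaker_hom_boost
            for l in np.where(force)[0]:
                alleles = freqs.alleles_at(l)
                probs = np.array([freqs.frequencies[l][a] for a in alleles])
                a = rng.choice(alleles, p=probs)
                g[l] = (a, a)
        return g

    # group state
    groups = {}
    floaters: list[int] = []
    for g in range(config.n_groups):
        dam = new_individual("F", -3, g, is_founder=True)
        sire = new_individual("M", -3, g, is_founder=True)
        helpers = [new_individual("F" if rng.random() < 0.5 else "M", -2, g, is_founder=True)
                   for _ in range(config.extra_adults_per_group)]
        groups[g] = {"dam": dam, "sire": sire, "helpers": helpers, "yearlings": []}

    pair_years: dict[tuple, int] = {}
    pair_re: dict[tuple, float] = {}
    betas = np.array([config.survival_coefficients.get(c, 0.0) for c in SURVIVAL_COVARIATES])
    ref = config.covariate_reference

    pup_rows, event_rows, harvest_rows = [], [], []
    members_by_year: dict[tuple, list] = {}
    density_by_year: dict[int, float] = {}

    def is_alive(i, year):
        d = inds[i].death_year
        return inds[i].birth_year <= year and (d is None or d >= year)

    for year in range(config.years):
        h_rate = config.harvest_rates[year]

        # fill breeder vacancies
        for g, st in groups.items():
            for role, sex in (("dam", "F"), ("sire", "M")):
                cur = st[role]
                if cur is not None and is_alive(cur, year):
                    continue
                cand = [f for f in floaters
                        if inds[f].sex == sex and is_alive(f, year)
                        and year - inds[f].birth_year >= 2]
                if cand and rng.random() >= config.immigrant_prob:
                    chosen = cand[rng.integers(len(cand))]
                    floaters.remove(chosen)
                    inds[chosen].group = g
                else:
                    chosen = new_individual(sex, year - 3, g)
                st[role] = chosen

        # density from summer abundance (before this year's litters, pragmatic)
        alive_now = [i for i in inds if is_alive(i, year) and not inds[i].is_sneaker]
        density = len(alive_now) / config.area_1000km2
        density_by_year[year] = density

        # breeding
        new_pups_by_group = {}
        for g, st in groups.items():
            dam, pair_male = st["dam"], st["sire"]
            adults_present = 2 + len([h for h in st["helpers"] if is_alive(h, year)]) \
                + len([yl for yl in st["yearlings"] if is_alive(yl, year)])
            litters = []
            n = rng.poisson(config.mean_litter)
            if n > 0:
                if rng.random() < config.sneaker_prob:
                    sire = new_individual("M", year - 3, -1, genotype=sneaker_genotype(),
                                          is_sneaker=True)
                    sneaky = True
                else:
                    sire, sneaky = pair_male, False
                litters.append((dam, sire, n, sneaky))
            # polygyny: a second resident female also gives birth, sired by the pair male
            extra_f = [h for h in st["helpers"]
                       if inds[h].sex == "F" and is_alive(h, year) and year - inds[h].birth_year >= 2]
            if extra_f and rng.random() < config.polygyny_prob:
                n2 = rng.poisson(config.mean_litter)
                if n2 > 0:
                    litters.append((extra_f[rng.integers(len(extra_f))], pair_male, n2, False))

            group_pups = []
            for dam_i, sire_i, n, sneaky in litters:
                key = (dam_i, sire_i)
                pair_years[key] = pair_years.get(key, 0) + 1
                if key not in pair_re:
                    pair_re[key] = rng.normal(0.0, config.pair_re_sd) if config.pair_re_sd > 0 else 0.0
                event_rows.append({"year": year, "group": g, "dam_id": dam_i, "sire_id": sire_i,
                                   "sneaker_sire": sneaky,
                                   "polygynous": len(litters) > 1})
                dam_g, sire_g = genotypes[dam_i], genotypes[sire_i]
                ho_dam = float(np.mean(dam_g[:, 0] != dam_g[:, 1]))
                ho_sire = float(np.mean(sire_g[:, 0] != sire_g[:, 1]))
                cov = {
                    "harvest_rate": h_rate,
                    "n_adults": float(adults_present),
                    "pair_ho": 0.5 * (ho_dam + ho_sire),
                    "density": density,
                    "years_paired": float(pair_years[key]),
                }
                z = np.array([(cov[c] - ref[c][0]) / ref[c][1] for c in SURVIVAL_COVARIATES])
                eta = config.survival_intercept + float(betas @ z) + pair_re[key]
                p_surv = _sigmoid(eta)
                for _ in range(n):
                    sex = "F" if rng.random() < 0.5 else "M"
                    pup = new_individual(sex, year, g, dam=dam_i, sire=sire_i,
                                         genotype=_mendelian_offspring(dam_g, sire_g, rng))
                    survived = bool(rng.random() < p_surv)
                    pup_rows.append({"pup_id": pup, "year": year, "group": g,
                                     "dam_id": dam_i, "sire_id": sire_i,
                                     "pair_id": f"{dam_i}x{sire_i}",
                                     "survived": survived, **cov})
                    group_pups.append((pup, survived))
            new_pups_by_group[g] = group_pups

        # summer membership (what fecal sampling can see)
        for g, st in groups.items():
            members = [st["dam"], st["sire"]]
            members += [h for h in st["helpers"] if is_alive(h, year)]
            members += [yl for yl in st["yearlings"] if is_alive(yl, year)]
            members += [p for p, _ in new_pups_by_group[g]]
            members_by_year[(g, year)] = members

        # fall/winter harvest of adults and yearlings
        for i in list(inds):
            ind = inds[i]
            if ind.is_sneaker or not is_alive(i, year) or ind.birth_year == year:
                continue
            if rng.random() < h_rate:
                ind.death_year = year
                harvest_rows.append({"id": i, "year": year, "in_study_area": True})

        # pup fates: non-survivors die this year, some via harvest
        for g, st in groups.items():
            for pup, survived in new_pups_by_group[g]:
                if not survived:
                    inds[pup].death_year = year
                    if rng.random() < h_rate:
                        harvest_rows.append({"id": pup, "year": year, "in_study_area": True})

        # extra natural breeder turnover
        for g, st in groups.items():
            for role in ("dam", "sire"):
                b = st[role]
                if is_alive(b, year) and rng.random() < config.breeder_turnover:
                    inds[b].death_year = year

        # aging: surviving pups become next year's yearlings; yearlings disperse
        for g, st in groups.items():
            for yl in st["yearlings"]:
                if is_alive(yl, year + 1):
                    inds[yl].group = -1
                    floaters.append(yl)
            st["yearlings"] = [p for p, s in new_pups_by_group[g] if s and is_alive(p, year + 1)]
        # floater natural mortality
        for f in list(floaters):
            if is_alive(f, year) and rng.random() < 0.2:
                inds[f].death_year = year
                floaters.remove(f)

    ind_rows = [{"id": i.id, "sex": i.sex, "birth_year": i.birth_year,
                 "death_year": np.nan if i.death_year is None else float(i.death_year),
                 "group": i.natal_group, "dam_id": i.dam, "sire_id": i.sire,
                 "is_sneaker": i.is_sneaker, "is_founder": i.is_founder}
                for i in inds.values()]

    return TruePopulation(
        individuals=pd.DataFrame(ind_rows),
        genotypes=genotypes,
        pups=pd.DataFrame(pup_rows),
        breeding_events=pd.DataFrame(event_rows),
        harvest=pd.DataFrame(harvest_rows, columns=["id", "year", "in_study_area"]),
        members_by_year=members_by_year,
        density_by_year=density_by_year,
        freqs=freqs,
        config=config,
    )


def _apply_pcr_errors(true_g: np.ndarray, n_reps: int, error: ErrorModel,
                      freqs: AlleleFrequencyTable, rng) -> np.ndarray:
    """Observed replicate calls (n_reps, L, 2) for one sample; 0 = no product."""
    L = true_g.shape[0]
    obs = np.repeat(true_g[None, :, :], n_reps, axis=0).astype(np.int64)

    # false alleles: each amplified allele mis-scored with prob f
    if error.false_allele > 0:
        flip = rng.random((n_reps, L, 2)) < error.false_allele
        for r, l in zip(*np.nonzero(flip.any(axis=2))):
            for s in range(2):
                if flip[r, l, s]:
                    alleles = freqs.alleles_at(l)
                    others = alleles[alleles != obs[r, l, s]]
                    if others.size:
                        obs[r, l, s] = others[rng.integers(others.size)]
    # dropout: each allele independently fails
    if error.dropout > 0:
        drop = rng.random((n_reps, L, 2)) < error.dropout
        obs[drop] = 0
    # whole-locus failure
    if error.failure > 0:
        fail = rng.random((n_reps, L)) < error.failure
        obs[fail] = 0

    # single surviving allele reads as an apparent homozygote
    obs = np.sort(obs, axis=-1)
    single = (obs[:, :, 0] == 0) & (obs[:, :, 1] > 0)
    obs[:, :, 0][single] = obs[:, :, 1][single]
    return obs


def simulate_noninvasive_samples(pop: TruePopulation, error: ErrorModel,
                                 config: SimulationConfig | None = None,
                                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Summer fecal sampling with replicate PCRs under the error model.

    Every group member present in a summer yields at least one scat; extra
    scats are spread multinomially up to ``samples_per_group_year``.  Returns
    a tidy frame: sample_id, individual_id, group, year, locus, replicate,
    allele1, allele2 (0 = no amplification).
    """
    if config is None:
        config = pop.config
    if rng is None:
        rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    freqs = pop.freqs
    L = freqs.n_loci
    R = config.pcr_replicates

    sample_meta = []  # (sample_id, individual, group, year)
    sid = 0
    for (g, year), members in sorted(pop.members_by_year.items()):
        n = len(members)  # sneakers are never group members, so never sampled
        if n == 0:
            continue
        counts = np.ones(n, dtype=int)
        extra = config.samples_per_group_year - n
        if extra > 0:
            counts += rng.multinomial(extra, np.full(n, 1.0 / n))
        for m, c in zip(members, counts):
            for _ in range(int(c)):
                sample_meta.append((sid, m, g, year))
                sid += 1

    frames = []
    for sample_id, ind, g, year in sample_meta:
        obs = _apply_pcr_errors(pop.genotypes[ind], R, error, freqs, rng)
        rep_idx = np.repeat(np.arange(R), L)
        loc_idx = np.tile(np.arange(L), R)
        frames.append(pd.DataFrame({
            "sample_id": sample_id,
            "individual_id": ind,
            "group": g,
            "year": year,
            "locus": [freqs.loci[l] for l in loc_idx],
            "replicate": rep_idx,
            "allele1": obs[rep_idx, loc_idx, 0],
            "allele2": obs[rep_idx, loc_idx, 1],
        }))
    if not frames:
        return pd.DataFrame(columns=["sample_id", "individual_id", "group", "year",
                                     "locus", "replicate", "allele1", "allele2"])
    return pd.concat(frames, ignore_index=True)


def simulate_harvest_tissues(pop: TruePopulation, year: int, n_outside: int = 0,
                             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Error-free tissue genotypes of animals harvested in ``year``.

    Optionally appends ``n_outside`` unrelated genotypes representing
    harvested animals from outside the study areas (they carry negative ids).
    Long format: id, year, in_study_area, locus, allele1, allele2.
    """
    rows = pop.harvest[pop.harvest.year == year]
    loci = pop.freqs.loci
    frames = []
    for _, r in rows.iterrows():
        g = pop.genotypes[r["id"]]
        frames.append(pd.DataFrame({
            "id": r["id"], "year": year, "in_study_area": bool(r["in_study_area"]),
            "locus": loci, "allele1": g[:, 0], "allele2": g[:, 1],
        }))
    if n_outside > 0:
        if rng is None:
            rng = np.random.default_rng(year)
        G = pop.freqs.sample_genotypes(n_outside, rng)
        for j in range(n_outside):
            frames.append(pd.DataFrame({
                "id": -(j + 1), "year": year, "in_study_area": False,
                "locus": loci, "allele1": G[j, :, 0], "allele2": G[j, :, 1],
            }))
    if not frames:
        return pd.DataFrame(columns=["id", "year", "in_study_area", "locus", "allele1", "allele2"])
    return pd.concat(frames, ignore_index=True)


def simulate_survival_dataset(rng: np.random.Generator, n_pair_years: int = 83,
                              mean_litter: float = 4.3,
                              coefficients: dict | None = None,
                              intercept: float = 0.02,
                              pair_re_sd: float = 0.0) -> pd.DataFrame:
    """Pup-survival table for parameter-recovery studies (no demographic feedback).

    Draws pair-year covariates at realistic scales, a Poisson litter per
    pair-year (mean 4.3, so 83 pair-years give ~357 pups), z-scores the
    realized pup-level covariates, and draws survival from the logistic truth
    (plus an optional pair random intercept).  Returns pup-level records with
    raw covariates, z-scored columns (suffix ``_z``) and ``alive``.
    """
    if coefficients is None:
        coefficients = DEFAULT_SURVIVAL_COEFFS
    cov = pd.DataFrame({
        "harvest_rate": np.clip(rng.normal(0.15, 0.10, n_pair_years), 0.0, 0.6),
        "n_adults": 2.0 + rng.poisson(4.0, n_pair_years),
        "pair_ho": np.clip(rng.normal(0.75, 0.07, n_pair_years), 0.3, 1.0),
        "density": np.clip(rng.normal(15.0, 4.0, n_pair_years), 1.0, None),
        "years_paired": 1.0 + rng.poisson(1.3, n_pair_years),
    })
    litters = np.maximum(1, rng.poisson(mean_litter, n_pair_years))
    pair_idx = np.repeat(np.arange(n_pair_years), litters)
    table = cov.iloc[pair_idx].reset_index(drop=True)
    table.insert(0, "pair_id", pair_idx)

    Z = np.empty((len(table), len(SURVIVAL_COVARIATES)))
    for j, c in enumerate(SURVIVAL_COVARIATES):
        x = table[c].to_numpy(float)
        Z[:, j] = (x - x.mean()) / x.std(ddof=1)
        table[c + "_z"] = Z[:, j]
    beta = np.array([coefficients.get(c, 0.0) for c in SURVIVAL_COVARIATES])
    b = rng.normal(0.0, pair_re_sd, n_pair_years) if pair_re_sd > 0 else np.zeros(n_pair_years)
    eta = intercept + Z @ beta + b[pair_idx]
    table["alive"] = (rng.random(len(table)) < _sigmoid(eta)).astype(int)
    table.insert(0, "pup_id", np.arange(len(table)))
    return table


def simulate_dyads(freqs: AlleleFrequencyTable, n: int, kind: str,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Pairs of genotypes with a known relationship.

    kind: 'unrelated', 'parent-offspring', 'full-sib', or 'half-sib'.
    Returns two (n, L, 2) arrays.
    """
    if kind == "unrelated":
        return freqs.sample_genotypes(n, rng), freqs.sample_genotypes(n, rng)
    P1 = freqs.sample_genotypes(n, rng)
    P2 = freqs.sample_genotypes(n, rng)
    if kind == "parent-offspring":
        kids = np.stack([_mendelian_offspring(P1[i], P2[i], rng) for i in range(n)])
        return P1, kids
    if kind == "full-sib":
        s1 = np.stack([_mendelian_offspring(P1[i], P2[i], rng) for i in range(n)])
        s2 = np.stack([_mendelian_offspring(P1[i], P2[i], rng) for i in range(n)])
        return s1, s2
    if kind == "half-sib":
        P3 = freqs.sample_genotypes(n, rng)
        s1 = np.stack([_mendelian_offspring(P1[i], P2[i], rng) for i in range(n)])
        s2 = np.stack([_mendelian_offspring(P1[i], P3[i], rng) for i in range(n)])
        return s1, s2
    raise ValueError(f"unknown dyad kind: {kind}")
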