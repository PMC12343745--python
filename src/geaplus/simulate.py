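"""Forward-in-time non-Wright-Fisher simulation of a selfing crop adapting
to a spatially varying environment.

The life cycle per generation is reproduction (selfing with probability
1 - outcrossing_rate, otherwise a uniformly drawn same-site mate), per-locus
symmetric mutation, stepping-stone migration of the new offspring, Gaussian
viability selection toward the local optimum phenotype, and density
regulation truncating each site to its carrying capacity.  Generations are
non-overlapping: the surviving offspring replace their parents.

A burn-in phase confines the population to the refugium site(s) with an
enlarged carrying capacity and no migration; the post-burn-in phase opens
migration and caps every site at K_site, so the range expansion and
isolation-by-distance structure emerge from the stepping-stone graph.

Phenotype is the additive sum of QTL allele effects plus a per-individual
environmental noise drawn once at birth.  Fitness follows the Gaussian
density N(y_opt, sigma_plasticity); survival probability is that density
rescaled by its mode so an individual at the optimum survives with
probability 1.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import Landscape

logger = logging.getLogger(__name__)

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


def fitness_of(phenotype, y_opt, sigma_plasticity: float):
    """Gaussian fitness: probability density of N(y_opt, sigma_plasticity)
    evaluated at the phenotype.  Symmetric about y_opt and strictly
    decreasing in |phenotype - y_opt|."""
    if sigma_plasticity <= 0:
        raise ValueError("sigma_plasticity must be positive")
    return stats.norm.pdf(np.asarray(phenotype, dtype=float), loc=y_opt, scale=sigma_plasticity)


@dataclass
class SimConfig:
    """Simulation parameters.  Defaults are the full-scale study conditions;
    see :func:`desk_profile` and :func:`mini_profile` for reduced profiles."""

    n_sites: int = 312
    n_neutral_loci: int = 999_900
    n_qtl: int = 100
    n_linkage_groups: int = 10
    mu: float = 6.5e-7  # mutations / locus / generation (100x-scaled rate)
    outcrossing_rate: float = 0.01
    qtl_effect_sd: float = 0.45
    env_noise_sd: float = 0.5
    sigma_plasticity: float = 2.85
    burnin_gens: int = 10_000
    postburnin_gens: int = 10_000
    K_refugium: int = 5_000
    K_site: int = 250
    refugia: tuple[int, ...] = (0,)
    n_sample_per_site: int = 50
    mean_offspring: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("mu", "outcrossing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("qtl_effect_sd", "env_noise_sd", "sigma_plasticity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_qtl > self.n_neutral_loci + self.n_qtl:
            raise ValueError("n_qtl exceeds total loci")
        if isinstance(self.refugia, list):
            self.refugia = tuple(self.refugia)
        if len(self.refugia) not in (1, 2):
            raise ValueError("refugia must name 1 or 2 sites")

    @property
    def n_loci(self) -> int:
        return self.n_neutral_loci + self.n_qtl


def desk_profile(**overrides) -> SimConfig:
    """Desk-scale profile: 50 sites, 10,000 neutral + 100 QTL loci, 500+500
    generations, K_site 100, 25 sampled per site.  Mutation rate is raised to
    keep per-locus diversity realistic at the reduced population and locus
    numbers."""
    base = dict(
        n_sites=50,
        n_neutral_loci=10_000,
        n_qtl=100,
        mu=1e-4,
        burnin_gens=500,
        postburnin_gens=500,
        K_refugium=1_000,
        K_site=100,
        n_sample_per_site=25,
    )
    base.update(overrides)
    return SimConfig(**base)


def mini_profile(**overrides) -> SimConfig:
    """Reduced profile used by the test suite and the acceptance script:
    50 sites, 2,500 neutral + 100 QTL loci, 1,000 burn-in + 400 expansion
    generations, K_site 60, 15 sampled per site."""
    base = dict(
        n_sites=50,
        n_neutral_loci=2_500,
        n_qtl=100,
        mu=2.5e-4,
        burnin_gens=1_000,
        postburnin_gens=400,
        K_refugium=600,
        K_site=60,
        n_sample_per_site=15,
    )
    base.update(overrides)
    return SimConfig(**base)


PROFILES = {"full": SimConfig, "desk": desk_profile, "mini": mini_profile}


@dataclass
class SimResult:
    """Sampled genotypes plus locus and individual annotations."""

    genotypes: np.ndarray  # (n_individuals, n_loci) dosages 0/1/2
    locus_table: pd.DataFrame  # chrom, pos, is_qtl, effect
    sample_table: pd.DataFrame  # id, site, lon, lat
    config: SimConfig
    seed: int
    phenotypes: np.ndarray | None = None
    site_census: dict[int, int] = field(default_factory=dict)
    history: list[dict] = field(default_factory=list)  # optional per-generation site summaries

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.locus_table["is_qtl"].to_numpy())

    @property
    def neutral_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.locus_table["is_qtl"].to_numpy())


def maf_filter(genotypes, maf_min: float):
    """Keep loci with minor allele frequency >= maf_min.

    Returns (filtered matrix, kept locus indices into the input).
    """
    G = np.asarray(genotypes)
    if G.size == 0:
        raise ValueError("empty genotype matrix")
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-D")
    f = G.mean(axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    kept = np.flatnonzero(maf >= maf_min)
    return G[:, kept], kept


class ForwardSimulator:
    """Runs the spatial nonWF simulation for one (landscape, config) pair.

    All randomness comes from one ``numpy.random.Generator`` seeded from
    ``config.seed``; identical inputs give identical results.
    """

    def __init__(self, landscape: Landscape, config: SimConfig):
        for r in config.refugia:
            if r not in {s.id for s in landscape.sites}:
                raise ValueError(f"refugium site {r} not in landscape")
        if len(landscape) != config.n_sites:
            # informative but not fatal: config.n_sites documents the intent
            logger.info(
                "landscape has %d sites, config.n_sites=%d; using the landscape",
                len(landscape),
                config.n_sites,
            )
        self.landscape = landscape
        self.config = config
        self._build_genome_map()
        self._build_migration_tables()

    # -- setup --------------------------------------------------------------
    def _build_genome_map(self):
        cfg = self.config
        L = cfg.n_loci
        n_chrom = cfg.n_linkage_groups
        per = np.full(n_chrom, L // n_chrom, dtype=int)
        per[: L % n_chrom] += 1
        self.chrom_of = np.repeat(np.arange(n_chrom), per)
        self.pos_within = np.concatenate([np.arange(n) for n in per])
        self.chrom_sizes = per
        self.chrom_slices = []
        start = 0
        for n in per:
            self.chrom_slices.append(slice(start, start + n))
            start += n
        # QTLs evenly spread over the genome
        qtl_idx = np.linspace(0, L - 1, cfg.n_qtl).round().astype(int)
        qtl_idx = np.unique(qtl_idx)
        self.qtl_idx = qtl_idx
        self.is_qtl = np.zeros(L, dtype=bool)
        self.is_qtl[qtl_idx] = True

    def _build_migration_tables(self):
        n = len(self.landscape)
        self._mig_dst: list[np.ndarray] = []
        self._mig_cum: list[np.ndarray] = []
        for s in self.landscape.sites:
            nbrs = self.landscape.neighbors(s.id)
            if nbrs:
                dst = np.array([self.landscape.site_index(d) for d, _ in nbrs], dtype=int)
                p = np.array([m for _, m in nbrs], dtype=float)
                self._mig_dst.append(dst)
                self._mig_cum.append(np.cumsum(p))
            else:
                self._mig_dst.append(np.empty(0, dtype=int))
                self._mig_cum.append(np.empty(0))
        self.n_sites_land = n

    # -- generation step ----------------------------------------------------
    def _reproduce(self, rng, H, site, migrate: bool):
        cfg = self.config
        N = H.shape[0]
        counts = rng.poisson(cfg.mean_offspring, N)
        p1 = np.repeat(np.arange(N), counts)
        n_off = p1.size
        if n_off == 0:
            return None

        # mates: selfing by default, same-site uniform mate otherwise
        p2 = p1.copy()
        cross = rng.random(n_off) < cfg.outcrossing_rate
        if np.any(cross):
            order = np.argsort(site, kind="stable")
            site_sorted = site[order]
            starts = np.searchsorted(site_sorted, np.arange(self.n_sites_land))
            ends = np.searchsorted(site_sorted, np.arange(self.n_sites_land), side="right")
            cs = site[p1[cross]]
            u = rng.random(cross.sum())
            pick = starts[cs] + np.floor(u * (ends[cs] - starts[cs])).astype(int)
            p2[cross] = order[pick]

        child = np.empty((n_off, 2, H.shape[2]), dtype=np.int8)
        for g, par in enumerate((p1, p2)):
            P = H[par]  # one gather per gamete
            bp = rng.integers(0, self.chrom_sizes.max() + 1, size=(n_off, len(self.chrom_sizes)))
            phase = rng.integers(0, 2, size=(n_off, len(self.chrom_sizes)), dtype=np.int8).astype(bool)
            for c, sl in enumerate(self.chrom_slices):
                take_first = (self.pos_within[sl][None, :] < bp[:, c, None]) ^ phase[:, c, None]
                child[:, g, sl] = np.where(take_first, P[:, 0, sl], P[:, 1, sl])

        # mutation: symmetric 0 <-> 1 flips, Poisson-approximated binomial
        n_slots = child.size
        n_mut = rng.poisson(n_slots * cfg.mu)
        if n_mut > 0:
            idx = rng.integers(0, n_slots, n_mut)
            flat = child.reshape(-1)
            flat[idx] ^= 1

        child_site = site[p1].copy()
        if migrate:
            u = rng.random(n_off)
            for s_idx in range(self.n_sites_land):
                cum = self._mig_cum[s_idx]
                if cum.size == 0:
                    continue
                here = np.flatnonzero(child_site == s_idx)
                here = here[site[p1[here]] == s_idx]  # keep original residents only
                if here.size == 0:
                    continue
                us = u[here]
                moving = us < cum[-1]
                if np.any(moving):
                    dest = self._mig_dst[s_idx][np.searchsorted(cum, us[moving], side="right")]
                    child_site[here[moving]] = dest
        return child, child_site

    def _select_and_regulate(self, rng, child, child_site, noise, K_map):
        cfg = self.config
        y_opt = self.landscape.y_opt
        dos_q = child[:, 0, self.qtl_idx].astype(np.float32) + child[:, 1, self.qtl_idx].astype(np.float32)
        phen = dos_q @ self._qtl_effects + noise
        dev = phen - y_opt[child_site]
        # survival = fitness density rescaled to 1 at the optimum
        p_surv = np.exp(-(dev**2) / (2.0 * cfg.sigma_plasticity**2))
        alive = rng.random(child.shape[0]) < p_surv
        child, child_site, phen = child[alive], child_site[alive], phen[alive]
        if child.shape[0] == 0:
            return child, child_site, phen

        # density regulation: uniform random truncation to K per site
        key = rng.random(child.shape[0])
        order = np.lexsort((key, child_site))
        s_sorted = child_site[order]
        starts = np.searchsorted(s_sorted, np.arange(self.n_sites_land))
        rank = np.arange(child.shape[0]) - starts[s_sorted]
        keep_sorted = rank < K_map[s_sorted]
        keep = order[keep_sorted]
        return child[keep], child_site[keep], phen[keep]

    # -- main loop ----------------------------------------------------------
    def run(self, record_every: int | None = None) -> SimResult:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        L = cfg.n_loci
        land = self.landscape

        self._qtl_effects = rng.normal(0.0, cfg.qtl_effect_sd, self.qtl_idx.size).astype(np.float32)

        refug_idx = np.array([land.site_index(r) for r in cfg.refugia], dtype=int)
        K_burn = np.zeros(self.n_sites_land, dtype=int)
        K_burn[refug_idx] = cfg.K_refugium
        K_post = np.full(self.n_sites_land, cfg.K_site, dtype=int)

        # founders: all-reference genomes at the refugium site(s)
        n0 = cfg.K_refugium * refug_idx.size
        H = np.zeros((n0, 2, L), dtype=np.int8)
        site = np.repeat(refug_idx, cfg.K_refugium)

        history: list[dict] = []
        for gen in range(cfg.burnin_gens + cfg.postburnin_gens):
            post = gen >= cfg.burnin_gens
            rep = self._reproduce(rng, H, site, migrate=post)
            if rep is None:
                raise RuntimeError(f"global extinction at generation {gen} (no offspring)")
            child, child_site = rep
            noise = rng.normal(0.0, cfg.env_noise_sd, child.shape[0]).astype(np.float32)
            H, site, phen = self._select_and_regulate(
                rng, child, child_site, noise, K_post if post else K_burn
            )
            if H.shape[0] == 0:
                raise RuntimeError(f"global extinction at generation {gen}")
            if record_every and (gen + 1) % record_every == 0:
                dev = np.abs(phen - self.landscape.y_opt[site])
                occupied = np.unique(site)
                mean_dev = {
                    int(s): float(dev[site == s].mean()) for s in occupied
                }
                history.append({"gen": gen + 1, "mean_abs_dev": mean_dev})

        # sample up to n_sample_per_site individuals per occupied site
        samp_idx: list[np.ndarray] = []
        for s_idx in range(self.n_sites_land):
            members = np.flatnonzero(site == s_idx)
            if members.size == 0:
                continue
            take = min(cfg.n_sample_per_site, members.size)
            samp_idx.append(rng.choice(members, take, replace=False))
        samp = np.concatenate(samp_idx)

        genotypes = (H[samp, 0, :].astype(np.int16) + H[samp, 1, :].astype(np.int16)).astype(np.int8)
        effects = np.zeros(L, dtype=float)
        effects[self.qtl_idx] = self._qtl_effects
        locus_table = pd.DataFrame(
            {
                "chrom": self.chrom_of + 1,
                "pos": self.pos_within + 1,
                "is_qtl": self.is_qtl,
                "effect": effects,
            }
        )
        lon, lat = land.lon, land.lat
        sample_table = pd.DataFrame(
            {
                "id": [f"ind_{i}" for i in range(samp.size)],
                "site": [land.sites[s].id for s in site[samp]],
                "lon": lon[site[samp]],
                "lat": lat[site[samp]],
            }
        )
        census = {land.sites[s].id: int((site == s).sum()) for s in range(self.n_sites_land)}
        return SimResult(
            genotypes=genotypes,
            locus_table=locus_table,
            sample_table=sample_table,
            config=copy.deepcopy(cfg),
            seed=cfg.seed,
            phenotypes=phen[samp].astype(float),
            site_census=census,
            history=history,
        )


def simulate(landscape: Landscape, config: SimConfig) -> SimResult:
    """Run the forward simulation (thin wrapper over :class:`ForwardSimulator`)."""
    return ForwardSimulator(landscape, config).run()
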