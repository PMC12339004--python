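"""Synthetic haplodiploid Wright-Fisher data with known ground truth.

This module generates every input the analysis pipeline consumes:

* forward-in-time haplodiploid Wright-Fisher populations (diploid
  females, haploid males) with viability selection and recurrent
  one-way mutation at target sites;
* pooled read counts over the simulated sites (two-stage binomial
  sampling: individuals into the pool, reads from the pool);
* Sanger-style unphased genotype tables drawn from a haplotype pool;
* binomial bioassay mortality tables under a probit dose-response.

Spider mites are haplodiploid: females are diploid, males develop from
unfertilized eggs and are haploid, so a mating pair carries three genome
copies.  Female genotype fitnesses are ``1 : 1+hs : 1+s`` and hemizygous
males ``1 : 1+s``; selection acts in both sexes by default (a config
switch disables it in males).  All randomness flows through one numpy
Generator; the seed fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sync import BASE_INDEX, SiteCounts

__all__ = [
    "SimConfig",
    "PopulationState",
    "PopulationTrajectory",
    "PoolSeqSample",
    "ScanDataset",
    "simulate_wf",
    "wright_fisher_frequencies",
    "deterministic_trajectory",
    "sample_pool_reads",
    "combine_pools",
    "generate_bioassay",
    "generate_sanger_genotypes",
    "simulate_scan_dataset",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the Wright-Fisher simulator.

    Parameters mirror the field system: ``mu`` defaults to the
    Drosophila-derived per-bp per-generation mutation rate 2.8e-9, the
    ploidy factor ``c`` is 3 (haplodiploid mating pair), and 20
    generations elapse per year.  ``n_target_sites`` sites receive
    recurrent mutation at rate ``mu`` and selection ``s_true`` on the
    derived (resistant) allele; ``n_neutral_sites`` sites drift from a
    standing initial frequency with neither mutation nor selection.
    """

    n_populations: int = 1
    n_females: int = 10_000
    c: int = 3
    mu: float = 2.8e-9
    s_true: float = 0.0
    h: float = 0.5
    generations: int = 60
    gens_per_year: int = 20
    genome_length: int = 100_000
    n_target_sites: int = 1
    n_neutral_sites: int = 0
    p0_target: float = 0.0
    p0_neutral: float = 0.5
    male_selection: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.s_true <= -1.0:
            raise ValueError("s_true <= -1 gives non-positive fitness")
        if not 0.0 <= self.p0_target <= 1.0 or not 0.0 <= self.p0_neutral <= 1.0:
            raise ValueError("initial frequencies must lie in [0, 1]")
        if self.generations < 0 or self.gens_per_year < 1:
            raise ValueError("generations >= 0 and gens_per_year >= 1 required")
        if self.n_target_sites + self.n_neutral_sites < 1:
            raise ValueError("at least one site is required")
        if self.genome_length < self.n_target_sites + self.n_neutral_sites:
            raise ValueError("genome_length smaller than the number of sites")


@dataclass
class PopulationState:
    """Marginal per-site genotype counts of one population at one generation.

    ``female_geno`` has shape (3, S): counts of ancestral-homozygote,
    heterozygote and derived-homozygote females per site.  ``male_geno``
    has shape (2, S): ancestral and derived hemizygote counts.
    """

    generation: int
    female_geno: np.ndarray
    male_geno: np.ndarray

    @property
    def n_females(self) -> int:
        return int(self.female_geno[:, 0].sum())

    @property
    def n_males(self) -> int:
        return int(self.male_geno[:, 0].sum())

    @property
    def allele_copies(self) -> int:
        """Total allele copies: 2 per female plus 1 per male."""
        return 2 * self.n_females + self.n_males

    @property
    def freq(self) -> np.ndarray:
        """Derived-allele frequency: copy-weighted mean over sexes."""
        derived = self.female_geno[1] + 2 * self.female_geno[2] + self.male_geno[1]
        return derived / self.allele_copies


@dataclass
class PopulationTrajectory:
    """Every-generation record of one simulated population."""

    population: str
    states: list[PopulationState]
    freq: np.ndarray  # (generations + 1, S)
    gens_per_year: int = 20

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.freq.shape[0]) / self.gens_per_year


# ---------------------------------------------------------------------------
# Wright-Fisher engine


def _init_population(p0: np.ndarray, n_f: int, n_m: int, rng: np.random.Generator):
    probs = np.stack([(1 - p0) ** 2, 2 * p0 * (1 - p0), p0**2], axis=-1)
    fem = rng.multinomial(n_f, probs).T  # (3, S)
    male_derived = rng.binomial(n_m, p0)
    male = np.stack([n_m - male_derived, male_derived])
    return fem, male


def _step(
    fem: np.ndarray,
    male: np.ndarray,
    s: np.ndarray,
    h: float,
    mu: np.ndarray,
    n_f: int,
    n_m: int,
    rng: np.random.Generator,
    male_selection: bool = True,
):
    """One generation: viability selection, gamete pools, mutation, sampling.

    Females arise from the random union of an egg and a sperm; males
    arise from unfertilized eggs.
    """
    w_f = np.stack([np.ones_like(s), 1 + h * s, 1 + s])  # (3, S)
    fem_w = fem * w_f
    p_egg = (0.5 * fem_w[1] + fem_w[2]) / fem_w.sum(axis=0)
    if male_selection:
        male_w = male * np.stack([np.ones_like(s), 1 + s])
    else:
        male_w = male.astype(float)
    p_sperm = male_w[1] / male_w.sum(axis=0)

    # one-way recurrent mutation toward the derived allele, per gamete
    p_egg = p_egg + (1 - p_egg) * mu
    p_sperm = p_sperm + (1 - p_sperm) * mu

    geno_probs = np.stack(
        [
            (1 - p_egg) * (1 - p_sperm),
            p_egg * (1 - p_sperm) + (1 - p_egg) * p_sperm,
            p_egg * p_sperm,
        ],
        axis=-1,
    )
    fem_next = rng.multinomial(n_f, geno_probs).T
    male_derived = rng.binomial(n_m, p_egg)
    male_next = np.stack([n_m - male_derived, male_derived])
    return fem_next, male_next


def wright_fisher_frequencies(
    p0,
    n_females: int,
    generations: int,
    *,
    s=0.0,
    h: float = 0.5,
    mu=0.0,
    rng: np.random.Generator,
    n_males: int | None = None,
    male_selection: bool = True,
    full: bool = False,
) -> np.ndarray:
    """Simulate derived-allele frequencies at independent sites.

    Returns the final frequency vector, or the full ``(generations+1, S)``
    trajectory when ``full=True``.  This is the low-level engine behind
    :func:`simulate_wf`; sites are unlinked.
    """
    p0 = np.atleast_1d(np.asarray(p0, dtype=float))
    S = p0.shape[0]
    s_vec = np.broadcast_to(np.asarray(s, dtype=float), (S,)).copy()
    mu_vec = np.broadcast_to(np.asarray(mu, dtype=float), (S,)).copy()
    if np.any(s_vec <= -1.0):
        raise ValueError("selection coefficients must exceed -1")
    n_m = n_females if n_males is None else n_males
    fem, male = _init_population(p0, n_females, n_m, rng)
    copies = 2 * n_females + n_m

    def _freq(f, m):
        return (f[1] + 2 * f[2] + m[1]) / copies

    traj = np.empty((generations + 1, S)) if full else None
    if full:
        traj[0] = _freq(fem, male)
    for g in range(generations):
        fem, male = _step(fem, male, s_vec, h, mu_vec, n_females, n_m, rng, male_selection)
        if full:
            traj[g + 1] = _freq(fem, male)
    return traj if full else _freq(fem, male)


def simulate_wf(config: SimConfig, rng: np.random.Generator | None = None) -> list[PopulationTrajectory]:
    """Forward-simulate ``config.n_populations`` independent populations.

    Target sites come first in the site axis (selection ``s_true`` and
    recurrent mutation ``mu``), followed by neutral sites drifting from
    ``p0_neutral``.  Every generation's genotype tables and allele
    frequencies are recorded.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    S = config.n_target_sites + config.n_neutral_sites
    s_vec = np.zeros(S)
    mu_vec = np.zeros(S)
    s_vec[: config.n_target_sites] = config.s_true
    mu_vec[: config.n_target_sites] = config.mu
    p0 = np.full(S, config.p0_neutral)
    p0[: config.n_target_sites] = config.p0_target

    n_f = config.n_females
    n_m = config.n_females  # constant 1:1 sex ratio
    out = []
    for ipop in range(config.n_populations):
        fem, male = _init_population(p0, n_f, n_m, rng)
        states = [PopulationState(0, fem, male)]
        for g in range(1, config.generations + 1):
            fem, male = _step(
                fem, male, s_vec, config.h, mu_vec, n_f, n_m, rng, config.male_selection
            )
            states.append(PopulationState(g, fem, male))
        freq = np.stack([st.freq for st in states])
        out.append(
            PopulationTrajectory(
                population=f"pop{ipop}",
                states=states,
                freq=freq,
                gens_per_year=config.gens_per_year,
            )
        )
    return out


def deterministic_trajectory(p0: float, s: float, h: float = 0.5, generations: int = 50,
                             mu: float = 0.0, male_selection: bool = True) -> np.ndarray:
    """Infinite-population haplodiploid selection recursion.

    Iterates the deterministic selection equations (no drift) and returns
    the copy-weighted newborn allele frequency per generation, length
    ``generations + 1``.  Serves as the N = infinity reference for the
    stochastic simulator and as the estimand for trajectory-slope
    recovery checks.
    """
    if s <= -1:
        raise ValueError("s must exceed -1")
    f = np.array([(1 - p0) ** 2, 2 * p0 * (1 - p0), p0**2], dtype=float)
    m = float(p0)
    out = [p0]
    w = np.array([1.0, 1 + h * s, 1 + s])
    for _ in range(generations):
        fw = f * w
        e = (0.5 * fw[1] + fw[2]) / fw.sum()
        if male_selection:
            mm = m * (1 + s) / (m * (1 + s) + (1 - m))
        else:
            mm = m
        e = e + (1 - e) * mu
        mm = mm + (1 - mm) * mu
        f = np.array([(1 - e) * (1 - mm), e * (1 - mm) + (1 - e) * mm, e * mm])
        m = e
        # newborn females carry (e + mm)/2, newborn males carry e
        out.append((2 * (e + mm) / 2 + e) / 3)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# pooled resequencing


@dataclass
class PoolSeqSample:
    """Pooled read counts for one population sample.

    Two-stage sampling: allele counts of the pooled females are binomial
    in ``2 * pool_size`` chromosomes, then reads are binomial in the
    pool's allele proportion at the drawn per-site depth.
    """

    population: str
    year: int | None
    pool_size: int
    chrom: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    depth: np.ndarray
    counts: np.ndarray  # (S, 6)

    def sites(self) -> list[SiteCounts]:
        return [
            SiteCounts(str(self.chrom[i]), int(self.positions[i]), str(self.ref[i]),
                       self.counts[i])
            for i in range(len(self.positions))
        ]


def sample_pool_reads(
    freqs,
    pool_size: int,
    depth: float,
    rng: np.random.Generator,
    *,
    population: str = "pool",
    year: int | None = None,
    chrom: str | Sequence[str] = "chr1",
    positions=None,
    ref=None,
    alt=None,
    depth_mode: str = "poisson",
) -> PoolSeqSample:
    """Draw pooled read counts from per-site derived-allele frequencies.

    ``depth_mode='poisson'`` draws per-site depths around the mean
    coverage (standard shotgun approximation); ``'fixed'`` uses exactly
    ``depth`` reads at every site.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    S = freqs.shape[0]
    if positions is None:
        positions = np.arange(1, S + 1)
    positions = np.asarray(positions)
    chrom_arr = np.full(S, chrom) if np.isscalar(chrom) or isinstance(chrom, str) else np.asarray(chrom)
    ref = np.full(S, "A") if ref is None else np.asarray(ref)
    alt = np.full(S, "T") if alt is None else np.asarray(alt)
    if np.any(ref == alt):
        raise ValueError("ref and alt bases must differ at every site")

    pool_alt = rng.binomial(2 * pool_size, freqs)
    pool_freq = pool_alt / (2 * pool_size)
    if depth_mode == "poisson":
        d = rng.poisson(depth, S)
    elif depth_mode == "fixed":
        d = np.full(S, int(depth))
    else:
        raise ValueError("depth_mode must be 'poisson' or 'fixed'")
    alt_reads = rng.binomial(d, pool_freq)

    counts = np.zeros((S, 6), dtype=np.int64)
    ref_idx = np.array([BASE_INDEX[b] for b in ref])
    alt_idx = np.array([BASE_INDEX[b] for b in alt])
    counts[np.arange(S), ref_idx] = d - alt_reads
    counts[np.arange(S), alt_idx] += alt_reads
    return PoolSeqSample(
        population=population,
        year=year,
        pool_size=pool_size,
        chrom=chrom_arr,
        positions=positions,
        ref=ref,
        alt=alt,
        depth=d,
        counts=counts,
    )


def combine_pools(samples: Sequence[PoolSeqSample]) -> tuple[list[SiteCounts], list[str]]:
    """Stack per-population pool samples over identical sites into sync rows."""
    first = samples[0]
    for s in samples[1:]:
        if not (np.array_equal(s.positions, first.positions)
                and np.array_equal(s.chrom, first.chrom)
                and np.array_equal(s.ref, first.ref)):
            raise ValueError("pool samples do not share a common site list")
    sites = []
    for i in range(len(first.positions)):
        counts = np.stack([s.counts[i] for s in samples])
        sites.append(SiteCounts(str(first.chrom[i]), int(first.positions[i]),
                                str(first.ref[i]), counts))
    return sites, [s.population for s in samples]


# ---------------------------------------------------------------------------
# bioassay and Sanger generators


def generate_bioassay(
    lc50: float,
    slope: float,
    doses: Sequence[float],
    n_per_dose: int = 30,
    control_mortality: float = 0.0,
    rng: np.random.Generator | None = None,
    *,
    population: str = "pop",
    compound: str = "cyetpyrafen",
    include_control: bool = True,
) -> pd.DataFrame:
    """Binomial mortality table under a probit dose-response.

    Mortality probability is ``c0 + (1-c0) * Phi(slope * (log10 d -
    log10 LC50))``.  A control row (concentration recorded as 0) is
    included by default.  Thirty mites per cup is the assay convention.
    """
    if rng is None:
        rng = np.random.default_rng()
    doses = np.asarray(list(doses), dtype=float)
    if doses.size == 0:
        raise ValueError("dose list is empty")
    if lc50 <= 0 or slope <= 0 or np.any(doses <= 0):
        raise ValueError("lc50, slope and doses must be positive")
    if not 0.0 <= control_mortality < 1.0:
        raise ValueError("control_mortality must lie in [0, 1)")
    p = control_mortality + (1 - control_mortality) * norm.cdf(
        slope * (np.log10(doses) - np.log10(lc50))
    )
    dead = rng.binomial(n_per_dose, p)
    rows = []
    if include_control:
        rows.append(
            dict(population=population, compound=compound, conc_mg_L=0.0,
                 n=n_per_dose, dead=int(rng.binomial(n_per_dose, control_mortality)))
        )
    for d, k in zip(doses, dead):
        rows.append(dict(population=population, compound=compound, conc_mg_L=float(d),
                         n=n_per_dose, dead=int(k)))
    return pd.DataFrame(rows)


def generate_sanger_genotypes(
    haplotypes: Sequence[str],
    frequencies,
    n_individuals: int,
    rng: np.random.Generator,
    *,
    population: str = "pop",
    year: int = 2024,
    snp_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw unphased diploid genotypes from a haplotype pool.

    Each individual is two independent haplotype draws (Hardy-Weinberg).
    Genotypes are recorded per SNP as the homozygous base or an unphased
    ``X/Y`` pair; the true phase is returned separately for round-trip
    tests.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if len(haplotypes) != len(freqs):
        raise ValueError("haplotypes and frequencies differ in length")
    if abs(freqs.sum() - 1.0) > 1e-8 or np.any(freqs < 0):
        raise ValueError("haplotype frequencies must be non-negative and sum to 1")
    L = len(haplotypes[0])
    if any(len(h) != L for h in haplotypes):
        raise ValueError("haplotypes differ in length")
    if snp_names is None:
        snp_names = [f"snp{i + 1}" for i in range(L)]

    idx = rng.choice(len(haplotypes), size=(n_individuals, 2), p=freqs)
    records = []
    truth = []
    for i, (a, b) in enumerate(idx):
        ha, hb = haplotypes[a], haplotypes[b]
        row: dict = {"individual": f"{population}_{i + 1}", "population": population,
                     "year": year}
        for j, name in enumerate(snp_names):
            if ha[j] == hb[j]:
                row[name] = ha[j]
            else:
                row[name] = "/".join(sorted((ha[j], hb[j])))
        records.append(row)
        truth.append({"individual": row["individual"], "hap_a": ha, "hap_b": hb})
    return pd.DataFrame(records), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# whole-scan dataset for the sweep pipeline


@dataclass
class ScanDataset:
    """A synthetic three-population genome scan with known sweep truth."""

    samples: dict[str, PoolSeqSample]
    sites: list[SiteCounts]
    pools: list[str]
    gene_regions: dict[str, tuple[str, int, int]]
    selected_genes: tuple[str, ...]
    window_size: int
    n_windows: int
    truth: dict


def simulate_scan_dataset(
    rng: np.random.Generator,
    *,
    n_windows: int = 100,
    snps_per_window: int = 8,
    window_size: int = 5_000,
    n_females: int = 500,
    generations: int = 30,
    s: float = 0.5,
    h: float = 0.5,
    p0_resistant: float = 0.05,
    focal: str = "RES1",
    nonfocal: tuple[str, str] = ("SUS1", "SUS2"),
    selected_genes: tuple[str, ...] = ("sdhB",),
    pool_size: int = 100,
    depth: float = 60.0,
    chrom: str = "chr1",
    freq_spectrum: str = "neutral",
) -> ScanDataset:
    """Simulate pooled counts for one focal and two reference populations.

    Three populations drift independently from shared ancestral
    frequencies.  In the focal population a resistant allele sweeps
    (coefficient ``s``) at each gene named in ``selected_genes``; sites
    within the swept 5-kb window hitchhike under complete linkage (the
    derived haplotype carries one fixed background allele per site),
    which reproduces the local diversity trough and high focal-branch
    differentiation of a hard sweep.  Windows elsewhere are neutral.

    Two gene regions ("sdhB" at a quarter and "sdhD" at three quarters of
    the genome) are always annotated; only those listed in
    ``selected_genes`` actually sweep, so susceptible-population and
    single-gene scenarios are expressible with the same generator.
    """
    gene_windows = {"sdhB": n_windows // 4, "sdhD": (3 * n_windows) // 4}
    unknown = set(selected_genes) - set(gene_windows)
    if unknown:
        raise ValueError(f"unknown selected genes: {sorted(unknown)}")

    S = n_windows * snps_per_window
    offsets = np.round((np.arange(snps_per_window) + 0.5) * window_size / snps_per_window)
    positions = (np.repeat(np.arange(n_windows), snps_per_window) * window_size
                 + np.tile(offsets, n_windows)).astype(int) + 1
    window_of = np.repeat(np.arange(n_windows), snps_per_window)
    if freq_spectrum == "neutral":
        # standing variation with density proportional to 1/p (neutral SFS)
        lo, hi = 0.01, 0.98
        p_anc = lo * (hi / lo) ** rng.random(S)
    elif freq_spectrum == "uniform":
        p_anc = rng.uniform(0.1, 0.9, S)
    else:
        raise ValueError("freq_spectrum must be 'neutral' or 'uniform'")

    bases = np.array(list("ATCG"))
    ref_i = rng.integers(0, 4, S)
    alt_i = (ref_i + rng.integers(1, 4, S)) % 4
    ref = bases[ref_i]
    alt = bases[alt_i]

    pops = [focal, *nonfocal]
    drifted = {
        p: wright_fisher_frequencies(p_anc, n_females, generations, rng=rng)
        for p in pops
    }

    truth: dict = {"selected_windows": {}, "p_resistant": {}, "s": s}
    extra_pos, extra_focal_freq = [], []
    for gene in selected_genes:
        w = gene_windows[gene]
        p_r = float(
            wright_fisher_frequencies(
                np.array([p0_resistant]), n_females, generations, s=s, h=h, rng=rng
            )[0]
        )
        carried = (rng.random(snps_per_window) < p_anc[window_of == w]).astype(float)
        in_w = window_of == w
        drifted[focal][in_w] = p_r * carried + (1 - p_r) * drifted[focal][in_w]
        # the resistance mutation itself: at frequency p_r in the focal
        # population, absent from the references
        extra_pos.append(w * window_size + window_size // 2)
        extra_focal_freq.append(p_r)
        truth["selected_windows"][gene] = int(w)
        truth["p_resistant"][gene] = p_r

    if extra_pos:
        order = np.argsort(np.concatenate([positions, extra_pos]))
        positions = np.concatenate([positions, extra_pos])[order]
        ref = np.concatenate([ref, ["A"] * len(extra_pos)])[order]
        alt = np.concatenate([alt, ["T"] * len(extra_pos)])[order]
        for p in pops:
            extra = extra_focal_freq if p == focal else [0.0] * len(extra_pos)
            drifted[p] = np.concatenate([drifted[p], extra])[order]

    samples = {
        p: sample_pool_reads(
            drifted[p], pool_size, depth, rng,
            population=p, chrom=chrom, positions=positions, ref=ref, alt=alt,
        )
        for p in pops
    }
    sites, pool_names = combine_pools([samples[p] for p in pops])
    gene_regions = {
        g: (chrom, w * window_size + 1, (w + 1) * window_size)
        for g, w in gene_windows.items()
    }
    return ScanDataset(
        samples=samples,
        sites=sites,
        pools=pool_names,
        gene_regions=gene_regions,
        selected_genes=tuple(selected_genes),
        window_size=window_size,
        n_windows=n_windows,
        truth=truth,
    )
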