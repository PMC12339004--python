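"""Pooled-data diversity statistics over non-overlapping genomic windows.

Implements the subsample-then-compute estimators used for pool-seq
diversity scans: per-site reads are subsampled without replacement to a
uniform depth ``b`` (default 50), after which reads are treated as
sampled sequences.  Per 5-kb window the module reports nucleotide
diversity (pi, with the b/(b-1) depth correction), Watterson's theta,
Tajima's D (classical constants with n = b) and pairwise FST
(pi_total - pi_within) / pi_total.

Windows are 1-based inclusive and aligned to the (k*window + 1) grid.
Sites failing the depth requirement are masked, never silently dropped
into the denominators.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sync import SiteCounts, check_sorted

__all__ = [
    "SubsampleConfig",
    "subsample_site",
    "site_pi",
    "watterson_a1",
    "tajima_d",
    "fst_from_counts",
    "window_stats",
    "WindowStats",
]


@dataclass(frozen=True)
class SubsampleConfig:
    """Depth-uniformising and SNP-calling thresholds.

    ``b`` is the uniform target depth; sites with fewer than ``b``
    nucleotide reads are masked.  A site is a SNP when its non-major
    read count after subsampling is at least ``min_count``.  When the
    input stream only contains variable sites (as synthetic sync files
    do), ``assume_full_coverage=True`` makes the per-site denominators
    use the full window span, treating unlisted positions as covered and
    monomorphic.
    """

    b: int = 50
    min_count: int = 2
    max_depth: int | None = None
    min_cover_frac: float = 0.0
    assume_full_coverage: bool = False

    def __post_init__(self) -> None:
        if self.b < 2:
            raise ValueError("target depth b must be >= 2")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def subsample_site(counts, b: int, rng: np.random.Generator) -> np.ndarray | None:
    """Multivariate-hypergeometric draw of exactly ``b`` reads.

    ``counts`` is a length-6 (A:T:C:G:N:del) or length-4 vector for one
    pool; N and deletion reads are excluded.  Returns the length-4
    subsampled counts, or None (masked-site sentinel) when fewer than
    ``b`` nucleotide reads are available.  Monomorphic input stays
    monomorphic and no absent allele can be created.
    """
    counts = np.asarray(counts, dtype=np.int64)
    base = counts[:4]
    total = int(base.sum())
    if total < b:
        return None
    if total == b:
        return base.copy()
    return rng.multivariate_hypergeometric(base, b)


def site_pi(counts) -> float:
    """Per-site nucleotide diversity pi = (b/(b-1)) * (1 - sum p_a^2)."""
    counts = np.asarray(counts, dtype=float)[:4]
    b = counts.sum()
    if b < 2:
        raise ValueError("site_pi requires depth >= 2")
    p = counts / b
    return float(b / (b - 1.0) * (1.0 - np.sum(p**2)))


def watterson_a1(n: int) -> float:
    """Harmonic number a1 = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def tajima_d(pi_sum: float, n_snps: int, n: int) -> float:
    """Tajima's D from the window sums, classical constants, sample size n.

    Returns NaN (masked-D sentinel) for windows without SNPs.
    """
    S = n_snps
    if S == 0:
        return float("nan")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((pi_sum - S / a1) / np.sqrt(var))


def fst_from_counts(counts_a, counts_b) -> float:
    """Window FST from two pools' per-site count matrices at uniform depth.

    FST = (pi_total - pi_within) / pi_total with pi_within the average of
    the two per-pool diversities and pi_total computed on the pooled
    counts, both summed over sites.  NaN when pi_total is 0.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))[:, :4]
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))[:, :4]
    if counts_a.shape != counts_b.shape:
        raise ValueError("pools cover different site sets")
    pi_a = _pi_rows(counts_a)
    pi_b = _pi_rows(counts_b)
    pi_t = _pi_rows(counts_a + counts_b)
    pi_within = (pi_a.sum() + pi_b.sum()) / 2.0
    pi_total = pi_t.sum()
    if pi_total <= 0:
        return float("nan")
    return float((pi_total - pi_within) / pi_total)


def _pi_rows(counts: np.ndarray) -> np.ndarray:
    depth = counts.sum(axis=1)
    p = counts / depth[:, None]
    return depth / (depth - 1.0) * (1.0 - np.sum(p**2, axis=1))


def _in_mask(chrom: str, pos: int, mask) -> bool:
    if not mask:
        return False
    for mc, start0, end0 in mask:
        if mc == chrom and start0 <= pos - 1 < end0:
            return True
    return False


@dataclass
class WindowStats:
    """Windowed diversity per pool, plus the subsampled counts for FST."""

    diversity: pd.DataFrame
    pools: list[str]
    window_size: int
    cfg: SubsampleConfig
    _site_meta: pd.DataFrame
    _sub_counts: np.ndarray  # (n_sites, n_pools, 4); masked rows are -1

    def fst(self, pool_a: str, pool_b: str) -> pd.DataFrame:
        """Per-window FST between two pools (symmetric)."""
        ia, ib = self.pools.index(pool_a), self.pools.index(pool_b)
        rows = []
        meta = self._site_meta
        for (chrom, start), idx in meta.groupby(["chrom", "win_start"], sort=False).groups.items():
            idx = np.asarray(idx)
            ca = self._sub_counts[idx, ia]
            cb = self._sub_counts[idx, ib]
            ok = (ca[:, 0] >= 0) & (cb[:, 0] >= 0)
            value = fst_from_counts(ca[ok], cb[ok]) if ok.any() else float("nan")
            rows.append(dict(chrom=chrom, start=int(start),
                             end=int(start) + self.window_size - 1, fst=value))
        return pd.DataFrame(rows)

    def fst_all_pairs(self) -> pd.DataFrame:
        frames = []
        for a, b in itertools.combinations(self.pools, 2):
            df = self.fst(a, b)
            df.insert(3, "pool_a", a)
            df.insert(4, "pool_b", b)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def window_stats(
    sites: Iterable[SiteCounts],
    cfg: SubsampleConfig = SubsampleConfig(),
    *,
    pools: Sequence[str] | None = None,
    window_size: int = 5_000,
    seed: int = 0,
    mask: Sequence[tuple[str, int, int]] | None = None,
) -> WindowStats:
    """Subsample a sorted sync stream and compute per-window diversity.

    ``mask`` is an optional list of 0-based half-open intervals (BED
    convention) excluded from all computations, e.g. indel margins.
    Windows with no covered site, or covered fraction below
    ``cfg.min_cover_frac``, are reported with masked (NaN) statistics.
    """
    sites = list(sites)
    check_sorted(sites)
    rng = np.random.default_rng(seed)
    if not sites:
        raise ValueError("empty site stream")
    n_pools = sites[0].n_pools
    if pools is None:
        pools = [f"pool{i + 1}" for i in range(n_pools)]
    pools = list(pools)
    if len(pools) != n_pools:
        raise ValueError("pool name list does not match the sync column count")

    meta_rows = []
    sub = np.full((len(sites), n_pools, 4), -1, dtype=np.int64)
    kept = 0
    for site in sites:
        if site.n_pools != n_pools:
            raise ValueError(f"inconsistent pool count at {site.chrom}:{site.pos}")
        if _in_mask(site.chrom, site.pos, mask):
            continue
        for j in range(n_pools):
            total = int(site.counts[j, :4].sum())
            if cfg.max_depth is not None and total > cfg.max_depth:
                continue  # leave masked
            drawn = subsample_site(site.counts[j], cfg.b, rng)
            if drawn is not None:
                sub[kept, j] = drawn
        win_start = ((site.pos - 1) // window_size) * window_size + 1
        meta_rows.append(dict(chrom=site.chrom, pos=site.pos, win_start=win_start))
        kept += 1
    sub = sub[:kept]
    meta = pd.DataFrame(meta_rows)
    if meta.empty:
        raise ValueError("all sites masked")

    a1 = watterson_a1(cfg.b)
    rows = []
    for (chrom, start), idx in meta.groupby(["chrom", "win_start"], sort=False).groups.items():
        idx = np.asarray(idx)
        for j, pool in enumerate(pools):
            counts = sub[idx, j]
            covered = counts[:, 0] >= 0
            n_cov = int(covered.sum())
            denom = float(window_size if cfg.assume_full_coverage else n_cov)
            frac = (window_size if cfg.assume_full_coverage else n_cov) / window_size
            record = dict(chrom=chrom, start=int(start), end=int(start) + window_size - 1,
                          pool=pool, n_sites_covered=n_cov)
            if n_cov == 0 or frac < cfg.min_cover_frac:
                record.update(n_snps=0, pi=np.nan, theta_w=np.nan, tajimas_d=np.nan,
                              masked=True)
            else:
                cc = counts[covered]
                minor = cfg.b - cc.max(axis=1)
                snp = minor >= cfg.min_count
                n_snps = int(snp.sum())
                pi_sum = float(_pi_rows(cc[snp].astype(float)).sum()) if n_snps else 0.0
                record.update(
                    n_snps=n_snps,
                    pi=pi_sum / denom,
                    theta_w=(n_snps / a1) / denom,
                    tajimas_d=tajima_d(pi_sum, n_snps, cfg.b),
                    masked=False,
                )
            rows.append(record)
    diversity = pd.DataFrame(rows)
    return WindowStats(diversity=diversity, pools=pools, window_size=window_size,
                       cfg=cfg, _site_meta=meta, _sub_counts=sub)
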