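"""Reading and writing pooled allele-count tables ("sync" dialect).

A sync file is tab-separated with one row per genomic site: chromosome,
1-based position, reference base, then one ``A:T:C:G:N:del`` read-count
string per pool.  This is the PoPoolation2 convention and is the exchange
format between the synthetic-data generator and the pool-seq statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

#: column order of the per-pool count vectors
SYNC_COLUMNS = ("A", "T", "C", "G", "N", "del")

#: base -> column index for the four nucleotide columns
BASE_INDEX = {b: i for i, b in enumerate(SYNC_COLUMNS[:4])}


@dataclass
class SiteCounts:
    """Per-site, per-pool nucleotide read counts (one sync row).

    ``counts`` has shape ``(n_pools, 6)`` in ``A:T:C:G:N:del`` column
    order; a single pool may be passed as a flat length-6 vector.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim == 1:
            counts = counts[None, :]
        if counts.ndim != 2 or counts.shape[1] != 6:
            raise ValueError("counts must have shape (n_pools, 6) in A:T:C:G:N:del order")
        if (counts < 0).any():
            raise ValueError(f"negative read counts at {self.chrom}:{self.pos}")
        if self.ref not in BASE_INDEX:
            raise ValueError(f"reference base {self.ref!r} is not one of A/T/C/G")
        if int(self.pos) < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")
        self.counts = counts
        self.pos = int(self.pos)

    @property
    def n_pools(self) -> int:
        return self.counts.shape[0]


def write_sync(sites: Iterable[SiteCounts], path) -> None:
    """Write sync rows; sites must already be sorted by (chrom, pos)."""
    with open(path, "w") as fh:
        for site in sites:
            pools = [":".join(str(int(x)) for x in row) for row in site.counts]
            fh.write("\t".join([site.chrom, str(site.pos), site.ref, *pools]) + "\n")


def read_sync(path) -> list[SiteCounts]:
    """Read a sync file, enforcing strictly increasing positions per chromosome.

    A chromosome may not be interleaved with another (each chromosome's
    rows must form one contiguous block).
    """
    sites: list[SiteCounts] = []
    last_pos: dict[str, int] = {}
    closed: set[str] = set()
    current: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated fields")
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            pos = int(pos_s)
            if chrom != current:
                if chrom in closed:
                    raise ValueError(f"{path}:{lineno}: chromosome {chrom} is interleaved")
                if current is not None:
                    closed.add(current)
                current = chrom
            if chrom in last_pos and pos <= last_pos[chrom]:
                raise ValueError(
                    f"{path}:{lineno}: positions not strictly increasing on {chrom}"
                )
            last_pos[chrom] = pos
            counts = np.array(
                [[int(x) for x in pool.split(":")] for pool in fields[3:]],
                dtype=np.int64,
            )
            sites.append(SiteCounts(chrom=chrom, pos=pos, ref=ref, counts=counts))
    return sites


def check_sorted(sites: Iterable[SiteCounts]) -> None:
    """Raise ValueError if sites are unsorted or chromosomes interleave."""
    last_pos: dict[str, int] = {}
    closed: set[str] = set()
    current: str | None = None
    for site in sites:
        if site.chrom != current:
            if site.chrom in closed:
                raise ValueError(f"chromosome {site.chrom} is interleaved")
            if current is not None:
                closed.add(current)
            current = site.chrom
        if site.chrom in last_pos and site.pos <= last_pos[site.chrom]:
            raise ValueError(f"positions not strictly increasing on {site.chrom}")
        last_pos[site.chrom] = site.pos
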