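"""Haplotype resolution, networks, and recombination-vs-recurrence tests.

Sanger amplicon genotypes are unphased, so haplotypes are resolved under
the at-most-one-heterozygous-site rule: a fully homozygous individual
contributes two copies of one haplotype, an individual with exactly one
heterozygous site contributes the two implied haplotypes, and anything
more ambiguous is excluded (with the reason reported).  Resolved
haplotypes are connected into a minimum-spanning network on Hamming
distances (all co-minimal edges retained), common central haplotypes are
classified as ancestral, and candidate single-crossover recombinant
origins of any haplotype can be enumerated exhaustively -- the evidence
used to separate recurrent mutation from recombination as the source of
a resistance mutation on multiple backgrounds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Haplotype",
    "RecombinationModel",
    "resolve_haplotypes",
    "build_network",
    "classify_ancestral",
    "enumerate_recombinants",
    "co_occurrence_screen",
    "expected_recombinants",
    "hamming",
]

_MISSING = {"", "-", "N", "NA", "nan", None}


@dataclass
class Haplotype:
    """A resolved haplotype over an ordered SNP panel."""

    id: str
    sequence: str
    count: int
    populations: set = field(default_factory=set)
    years: set = field(default_factory=set)
    resistance_mutation: str | None = None


@dataclass(frozen=True)
class RecombinationModel:
    """Population recombination-rate model rho = 2 * c * Ne * r over d bp.

    ``r`` is the per-bp per-generation crossover rate (default 1e-7,
    i.e. 10 cM/Mb), ``c`` the ploidy factor of a mating pair (3 under
    haplodiploidy) and ``d`` the physical distance between the two sites.
    """

    r: float = 1e-7
    c: float = 3.0
    ne: float = 1e6
    d: float = 60.0

    def __post_init__(self) -> None:
        if min(self.r, self.c, self.ne) < 0:
            raise ValueError("model fields must be non-negative")
        if self.d <= 0:
            raise ValueError("inter-site distance d must be positive")


def _parse_genotype(value) -> tuple[str, str] | None:
    """Normalize one genotype cell to an allele pair, or None if missing."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().upper()
    if s in _MISSING:
        return None
    if "/" in s:
        a, b = s.split("/")
    elif len(s) == 2:
        a, b = s[0], s[1]
    elif len(s) == 1:
        a = b = s
    else:
        raise ValueError(f"genotype symbol {value!r} outside the allele alphabet")
    for x in (a, b):
        if x not in "ACGT":
            raise ValueError(f"genotype symbol {value!r} outside the allele alphabet")
    return a, b


def resolve_haplotypes(
    genotypes: pd.DataFrame,
    snp_columns: list[str] | None = None,
) -> tuple[list[Haplotype], pd.DataFrame]:
    """Resolve haplotypes under the <=1-heterozygous-site rule.

    ``genotypes`` has one row per individual with columns ``individual``,
    ``population``, ``year`` and one column per panel SNP.  Returns the
    haplotype list (ids H1, H2, ... in decreasing carrier count) and an
    exclusion report.  Copy counts are conserved: every retained
    individual contributes exactly two haplotype copies; individuals
    with missing panel genotypes are excluded (strict reading).
    """
    if snp_columns is None:
        snp_columns = [c for c in genotypes.columns
                       if c not in ("individual", "population", "year")]
    counts: dict[str, int] = {}
    meta: dict[str, dict] = {}
    excluded = []
    for _, row in genotypes.iterrows():
        pairs = [_parse_genotype(row[c]) for c in snp_columns]
        if any(p is None for p in pairs):
            excluded.append(dict(individual=row["individual"], reason="missing-genotype"))
            continue
        het_sites = [i for i, (a, b) in enumerate(pairs) if a != b]
        if len(het_sites) > 1:
            excluded.append(dict(individual=row["individual"], reason="phase-ambiguous"))
            continue
        if not het_sites:
            hap = "".join(a for a, _ in pairs)
            haps = [hap, hap]
        else:
            i = het_sites[0]
            a, b = pairs[i]
            base = [p[0] for p in pairs]
            h1, h2 = base.copy(), base.copy()
            h1[i], h2[i] = a, b
            haps = ["".join(h1), "".join(h2)]
        for hap in haps:
            counts[hap] = counts.get(hap, 0) + 1
            m = meta.setdefault(hap, dict(populations=set(), years=set()))
            m["populations"].add(row.get("population"))
            m["years"].add(row.get("year"))
    ordered = sorted(counts, key=lambda h: (-counts[h], h))
    haplotypes = [
        Haplotype(id=f"H{i + 1}", sequence=h, count=counts[h],
                  populations=meta[h]["populations"], years=meta[h]["years"])
        for i, h in enumerate(ordered)
    ]
    report = pd.DataFrame(excluded, columns=["individual", "reason"])
    return haplotypes, report


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def build_network(haplotypes: list[Haplotype]) -> nx.Graph:
    """Minimum-spanning network on Hamming distances.

    Kruskal by increasing distance, but within each distance class every
    edge joining two (pre-merge) components is retained, so co-minimal
    alternative connections are not broken arbitrarily.  Edge weights
    carry the Hamming distance; node attributes carry count and sequence.
    """
    if not haplotypes:
        raise ValueError("at least one haplotype is required")
    g = nx.Graph()
    for h in haplotypes:
        g.add_node(h.id, count=h.count, sequence=h.sequence)
    dists: dict[int, list[tuple[str, str]]] = {}
    for a, b in itertools.combinations(haplotypes, 2):
        dists.setdefault(hamming(a.sequence, b.sequence), []).append((a.id, b.id))
    comp = {h.id: h.id for h in haplotypes}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for d in sorted(dists):
        snapshot = {h.id: find(h.id) for h in haplotypes}
        added = [(a, b) for a, b in dists[d] if snapshot[a] != snapshot[b]]
        for a, b in added:
            g.add_edge(a, b, weight=d)
        for a, b in added:
            ra, rb = find(a), find(b)
            if ra != rb:
                comp[ra] = rb
    return g


def classify_ancestral(
    network: nx.Graph,
    *,
    frequency_quantile: float = 0.75,
    min_degree: int = 2,
) -> tuple[dict[str, bool], dict[str, str]]:
    """Label haplotypes ancestral (common and central) or derived.

    Ancestral nodes sit in the top frequency stratum (carrier count at or
    above the ``frequency_quantile`` of all counts) and have network
    degree >= ``min_degree``; both thresholds are explicit knobs.  Every
    derived node is assigned its nearest ancestral node by weighted
    shortest path.  If no node meets both rules the single most frequent
    node is ancestral by fallback.
    """
    counts = {n: network.nodes[n]["count"] for n in network.nodes}
    if len(counts) == 1:
        only = next(iter(counts))
        return {only: True}, {}
    cut = float(np.quantile(list(counts.values()), frequency_quantile))
    ancestral = {n for n in counts
                 if counts[n] >= cut and network.degree[n] >= min_degree}
    if not ancestral:
        ancestral = {max(counts, key=lambda n: (counts[n], network.degree[n]))}
    labels = {n: n in ancestral for n in counts}
    nearest: dict[str, str] = {}
    lengths = dict(nx.all_pairs_dijkstra_path_length(network, weight="weight"))
    for n in counts:
        if labels[n]:
            continue
        reachable = [(lengths[n][a], a) for a in ancestral if a in lengths[n]]
        if reachable:
            nearest[n] = min(reachable)[1]
    return labels, nearest


def enumerate_recombinants(
    target: Haplotype,
    pool: list[Haplotype],
    positions: list[int],
    *,
    double_crossover: bool = False,
) -> list[dict]:
    """All single-crossover parental explanations of ``target``.

    Returns every ordered parent pair (a, b) and breakpoint index k such
    that target = a[:k] + b[k:], with both parents required to differ
    from the target (trivial self-explanations excluded).  The breakpoint
    is reported as the physical interval between the flanking SNPs.
    Double-crossover (gene-conversion-like) explanations are off by
    default and enumerate an internal donor segment when enabled.
    """
    L = len(target.sequence)
    if len(positions) != L:
        raise ValueError("positions must match the SNP panel length")
    parents = [h for h in pool if h.sequence != target.sequence]
    out = []
    for a, b in itertools.permutations(parents, 2):
        for k in range(1, L):
            if target.sequence == a.sequence[:k] + b.sequence[k:]:
                out.append(dict(
                    parent_a=a.id, parent_b=b.id, breakpoint_index=k,
                    breakpoint_interval=(positions[k - 1], positions[k]),
                    kind="single",
                ))
    if double_crossover:
        for a, b in itertools.permutations(parents, 2):
            for i in range(1, L - 1):
                for j in range(i + 1, L):
                    cand = a.sequence[:i] + b.sequence[i:j] + a.sequence[j:]
                    if target.sequence == cand:
                        out.append(dict(
                            parent_a=a.id, parent_b=b.id,
                            breakpoint_index=(i, j),
                            breakpoint_interval=((positions[i - 1], positions[i]),
                                                 (positions[j - 1], positions[j])),
                            kind="double",
                        ))
    return out


def co_occurrence_screen(
    target: Haplotype,
    candidates: list[dict],
    haplotypes: list[Haplotype],
) -> pd.DataFrame:
    """Which populations contain both required parents and the recombinant.

    For each candidate parental pair, lists the populations where parent
    a, parent b and the target haplotype were all observed -- the
    geographic plausibility screen for a recombinant origin.
    """
    by_id = {h.id: h for h in haplotypes}
    rows = []
    for cand in candidates:
        pa, pb = by_id[cand["parent_a"]], by_id[cand["parent_b"]]
        shared = pa.populations & pb.populations & target.populations
        rows.append(dict(
            target=target.id, parent_a=pa.id, parent_b=pb.id,
            breakpoint_interval=cand["breakpoint_interval"],
            populations_with_all=sorted(p for p in shared if p is not None),
            n_populations_with_all=len(shared),
        ))
    return pd.DataFrame(
        rows,
        columns=["target", "parent_a", "parent_b", "breakpoint_interval",
                 "populations_with_all", "n_populations_with_all"],
    )


def expected_recombinants(model: RecombinationModel) -> dict:
    """Expected recombination events between two sites per generation.

    rho = 2 * c * Ne * r * d across distance d, with the reciprocal
    reported as the expected number of effective individuals per single
    event.  Both interpretations are returned so the scale of the
    recurrence-vs-recombination argument is explicit.
    """
    rho = 2.0 * model.c * model.ne * model.r * model.d
    return dict(
        rho_per_generation=rho,
        individuals_per_event=np.inf if rho == 0 else 1.0 / rho,
        model=model,
    )
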