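"""Target-site mutation catalog and codon-level annotation of sdhB/sdhD.

The succinate dehydrogenase subunits B and D carry the known target-site
substitutions conferring SDH-inhibitor acaricide resistance in the
two-spotted spider mite.  The curated catalog (15 amino-acid
substitutions: six on five sdhB residues, nine on three sdhD residues,
five of them at sdhD R119) ships as a versioned TSV asset.  D116E is
stored as two rows sharing one label because two alternative wild codons
(GAC and GAT) each reach GAA by a single nucleotide change; it counts
once toward the 15.

Residue numbering follows the mite protein coordinates.  The standard
nuclear genetic code applies throughout (the sdh subunits are
nuclear-encoded).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .sync import SiteCounts

__all__ = [
    "CodonMutation",
    "GeneModel",
    "CodingEffect",
    "load_catalog",
    "catalog_frame",
    "annotate_variant",
    "annotate_snp",
    "accessible_substitutions",
    "saturation_report",
    "population_mutation_summary",
    "genomic_change",
    "load_gene_models",
    "synthetic_gene_models",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"
_STOP = "*"


def _translate_codon(codon: str) -> str:
    table = CodonTable.unambiguous_dna_by_id[1]
    if codon in table.stop_codons:
        return _STOP
    return table.forward_table[codon]


@dataclass(frozen=True)
class CodonMutation:
    """One catalogued amino-acid substitution at a target codon."""

    gene: str
    residue_index: int  # 1-based protein position
    wild_codon: str
    mutant_codon: str
    wild_aa: str
    mutant_aa: str
    label: str
    first_detected_year: int

    def validate(self) -> None:
        if _translate_codon(self.wild_codon) != self.wild_aa:
            raise ValueError(f"{self.label}: wild codon {self.wild_codon} does not encode {self.wild_aa}")
        if _translate_codon(self.mutant_codon) != self.mutant_aa:
            raise ValueError(f"{self.label}: mutant codon {self.mutant_codon} does not encode {self.mutant_aa}")
        diffs = self.changed_positions
        if len(diffs) < 1:
            raise ValueError(f"{self.label}: wild and mutant codons are identical")
        if self.label != f"{self.wild_aa}{self.residue_index}{self.mutant_aa}":
            raise ValueError(f"{self.label}: label does not match amino acids")

    @property
    def changed_positions(self) -> tuple[int, ...]:
        """0-based intra-codon positions at which wild and mutant differ."""
        return tuple(i for i in range(3) if self.wild_codon[i] != self.mutant_codon[i])


def _catalog_path():
    return resources.files("resistscan.data").joinpath("sdh_mutations.tsv")


def catalog_frame() -> pd.DataFrame:
    """The raw catalog table (one row per wild-codon route; 16 rows)."""
    with resources.as_file(_catalog_path()) as p:
        return pd.read_csv(p, sep="\t")


def load_catalog() -> list[CodonMutation]:
    """Load and validate the in-package mutation catalog.

    Every row must translate consistently, differ from wild type in at
    least one nucleotide, and be a single-nucleotide codon change (the
    catalog is ground truth; validation failure is a hard error).  The
    15 distinct labels comprise 6 sdhB substitutions on 5 residues and 9
    sdhD substitutions on 3 residues.
    """
    df = catalog_frame().rename(columns={"residue": "residue_index"})
    entries = [
        CodonMutation(
            gene=str(row["gene"]),
            residue_index=int(row["residue_index"]),
            wild_codon=str(row["wild_codon"]),
            mutant_codon=str(row["mutant_codon"]),
            wild_aa=str(row["wild_aa"]),
            mutant_aa=str(row["mutant_aa"]),
            label=str(row["label"]),
            first_detected_year=int(row["first_detected_year"]),
        )
        for row in df.to_dict("records")
    ]
    for e in entries:
        e.validate()
        if len(e.changed_positions) != 1:
            raise ValueError(f"{e.label}: catalog entries must be single-nucleotide changes")
    labels = {(e.gene, e.label) for e in entries}
    if len(labels) != 15:
        raise ValueError(f"catalog must contain 15 distinct substitutions, found {len(labels)}")
    by_gene = {}
    for gene in ("sdhB", "sdhD"):
        gene_entries = [e for e in entries if e.gene == gene]
        by_gene[gene] = (len({e.label for e in gene_entries}),
                         len({e.residue_index for e in gene_entries}))
    if by_gene["sdhB"] != (6, 5) or by_gene["sdhD"] != (9, 3):
        raise ValueError(f"unexpected catalog composition: {by_gene}")
    return entries


# ---------------------------------------------------------------------------
# gene models and annotation


@dataclass
class GeneModel:
    """A coding gene: CDS intervals on a chromosome plus its coding sequence.

    ``cds_intervals`` are 1-based inclusive (start, end) pairs in genomic
    order; ``cds_seq`` is the spliced coding sequence 5'->3' on the mRNA
    (i.e. already reverse-complemented for minus-strand genes).
    """

    gene: str
    chrom: str
    cds_intervals: list[tuple[int, int]]
    strand: str
    cds_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        length = sum(e - s + 1 for s, e in self.cds_intervals)
        if length != len(self.cds_seq):
            raise ValueError(f"{self.gene}: CDS intervals span {length} bp but sequence has {len(self.cds_seq)}")
        if length % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length {length} not divisible by 3")
        protein = str(Seq(self.cds_seq).translate())
        if _STOP in protein[:-1]:
            raise ValueError(f"{self.gene}: internal stop codon in CDS")

    @property
    def n_residues(self) -> int:
        return len(self.cds_seq) // 3

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset into the coding sequence, or None outside the CDS."""
        running = 0
        intervals = self.cds_intervals if self.strand == "+" else list(reversed(self.cds_intervals))
        for s, e in intervals:
            if s <= pos <= e:
                return running + (pos - s if self.strand == "+" else e - pos)
            running += e - s + 1
        return None

    def genomic_pos(self, offset: int) -> int:
        """Genomic 1-based position of CDS offset (inverse of cds_offset)."""
        if not 0 <= offset < len(self.cds_seq):
            raise ValueError("CDS offset out of range")
        running = 0
        intervals = self.cds_intervals if self.strand == "+" else list(reversed(self.cds_intervals))
        for s, e in intervals:
            span = e - s + 1
            if offset < running + span:
                within = offset - running
                return s + within if self.strand == "+" else e - within
            running += span
        raise AssertionError("unreachable")

    def codon(self, residue_index: int) -> str:
        """Codon (mRNA orientation) of the 1-based residue index."""
        return self.cds_seq[3 * (residue_index - 1): 3 * residue_index]


@dataclass(frozen=True)
class CodingEffect:
    """Effect of substituting one base within (or outside) a gene model."""

    gene: str
    kind: str  # missense | synonymous | nonsense | non_coding
    residue_index: int | None = None
    codon_position: int | None = None  # 0-based within the codon
    wild_codon: str | None = None
    mutant_codon: str | None = None
    wild_aa: str | None = None
    mutant_aa: str | None = None
    label: str | None = None


def annotate_variant(model: GeneModel, pos: int, ref_base: str, alt_base: str) -> CodingEffect:
    """Map a genomic substitution to its codon-level effect (strand-aware)."""
    offset = model.cds_offset(pos)
    if offset is None:
        return CodingEffect(gene=model.gene, kind="non_coding")
    ref_cds = ref_base if model.strand == "+" else ref_base.translate(_COMPLEMENT)
    alt_cds = alt_base if model.strand == "+" else alt_base.translate(_COMPLEMENT)
    if model.cds_seq[offset] != ref_cds:
        raise ValueError(
            f"{model.gene}: reference base mismatch at CDS offset {offset} "
            f"(model has {model.cds_seq[offset]}, observed {ref_cds})"
        )
    codon_index = offset // 3
    codon_pos = offset % 3
    wild = model.cds_seq[3 * codon_index: 3 * codon_index + 3]
    mutant = wild[:codon_pos] + alt_cds + wild[codon_pos + 1:]
    wild_aa = _translate_codon(wild)
    mutant_aa = _translate_codon(mutant)
    residue = codon_index + 1
    if mutant_aa == wild_aa:
        kind = "synonymous"
    elif mutant_aa == _STOP:
        kind = "nonsense"
    else:
        kind = "missense"
    return CodingEffect(
        gene=model.gene, kind=kind, residue_index=residue, codon_position=codon_pos,
        wild_codon=wild, mutant_codon=mutant, wild_aa=wild_aa, mutant_aa=mutant_aa,
        label=f"{wild_aa}{residue}{mutant_aa}",
    )


def annotate_snp(site: SiteCounts, model: GeneModel, alt_base: str | None = None) -> CodingEffect:
    """Annotate a sync row against a gene model.

    When ``alt_base`` is not given, the most abundant non-reference base
    summed over pools is used.
    """
    if alt_base is None:
        totals = site.counts[:, :4].sum(axis=0).astype(float)
        order = ["A", "T", "C", "G"]
        totals[order.index(site.ref)] = -1
        alt_base = order[int(np.argmax(totals))]
    return annotate_variant(model, site.pos, site.ref, alt_base)


def genomic_change(model: GeneModel, mutation: CodonMutation) -> tuple[str, int, str, str]:
    """Genomic (chrom, pos, ref, alt) of a catalogued single-base change.

    The gene model's codon at the mutation's residue must equal the
    entry's wild codon.
    """
    wild = model.codon(mutation.residue_index)
    if wild != mutation.wild_codon:
        raise ValueError(
            f"{model.gene} residue {mutation.residue_index}: model codon {wild} "
            f"differs from catalog wild codon {mutation.wild_codon}"
        )
    (cp,) = mutation.changed_positions
    offset = 3 * (mutation.residue_index - 1) + cp
    pos = model.genomic_pos(offset)
    ref_cds, alt_cds = mutation.wild_codon[cp], mutation.mutant_codon[cp]
    if model.strand == "-":
        ref_cds = ref_cds.translate(_COMPLEMENT)
        alt_cds = alt_cds.translate(_COMPLEMENT)
    return model.chrom, pos, ref_cds, alt_cds


# ---------------------------------------------------------------------------
# single-nucleotide accessibility


def accessible_substitutions(codon: str) -> list[dict]:
    """All 9 single-nucleotide neighbours of a codon with their translations.

    Stop-codon neighbours are flagged and excluded from missense
    accessibility counts by :func:`saturation_report`.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    wild_aa = _translate_codon(codon)
    out = []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            aa = _translate_codon(mutant)
            out.append(dict(
                codon_position=pos, mutant_codon=mutant, amino_acid=aa,
                is_stop=aa == _STOP, is_synonymous=aa == wild_aa,
            ))
    assert len(out) == 9
    return out


def saturation_report(gene: str, residue_index: int, codon: str,
                      catalog: list[CodonMutation] | None = None) -> pd.DataFrame:
    """Observed vs accessible amino-acid changes per codon position.

    For each intra-codon position: the accessible missense amino acids
    (stop and synonymous neighbours excluded), which of them appear in
    the catalog for this residue, and the resulting saturation fraction.
    """
    if catalog is None:
        catalog = load_catalog()
    observed = {e.mutant_aa for e in catalog
                if e.gene == gene and e.residue_index == residue_index}
    rows = []
    for pos in range(3):
        neighbours = [n for n in accessible_substitutions(codon) if n["codon_position"] == pos]
        missense = {n["amino_acid"] for n in neighbours if not (n["is_stop"] or n["is_synonymous"])}
        seen = missense & observed
        rows.append(dict(
            gene=gene, residue_index=residue_index, codon_position=pos,
            accessible_missense=sorted(missense), observed=sorted(seen),
            n_accessible=len(missense), n_observed=len(seen),
            saturation=len(seen) / len(missense) if missense else np.nan,
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-population presence summaries


def population_mutation_summary(
    freqs: pd.DataFrame,
    threshold: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mutation presence counts per population and their year-group means.

    ``freqs`` is long format with columns ``population``, ``year``,
    ``label``, ``frequency``.  A mutation is present when its frequency
    exceeds ``threshold`` (default: any non-zero evidence; the detection
    rule is configurable because no universal cut-off exists across data
    types).
    """
    required = {"population", "year", "label", "frequency"}
    if not required.issubset(freqs.columns):
        raise ValueError(f"freqs must have columns {sorted(required)}")
    if freqs["year"].isna().any():
        raise ValueError("unknown (missing) year label in frequency table")
    present = freqs[freqs["frequency"] > threshold]
    counts = (
        present.groupby(["population", "year"])["label"].nunique().rename("n_mutations")
    )
    all_pops = freqs[["population", "year"]].drop_duplicates().set_index(["population", "year"])
    counts = counts.reindex(all_pops.index, fill_value=0).reset_index()
    year_means = counts.groupby("year")["n_mutations"].mean()
    return counts, year_means


# ---------------------------------------------------------------------------
# gene model IO and synthetic fixtures


def load_gene_models(gff3_path, fasta_path) -> dict[str, GeneModel]:
    """Build gene models from a GFF3 (CDS features) and a genome FASTA."""
    from Bio import SeqIO

    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    feats: dict[str, dict] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            name = attrs.get("Parent") or attrs.get("ID") or attrs.get("gene_id")
            if name is None:
                raise ValueError("CDS feature without Parent/ID attribute")
            rec = feats.setdefault(name, dict(chrom=cols[0], strand=cols[6], intervals=[]))
            rec["intervals"].append((int(cols[3]), int(cols[4])))
    models = {}
    for name, rec in feats.items():
        intervals = sorted(rec["intervals"])
        seq = "".join(genome[rec["chrom"]][s - 1: e] for s, e in intervals)
        if rec["strand"] == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
        models[name] = GeneModel(gene=name, chrom=rec["chrom"], cds_intervals=intervals,
                                 strand=rec["strand"], cds_seq=seq)
    return models


_SAFE_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                if _translate_codon(a + b + c) != _STOP]


def synthetic_gene_models(seed: int = 0, chrom: str = "chr1",
                          sdhb_start: int = 10_001, sdhd_start: int = 40_001,
                          sdhd_strand: str = "-",
                          wild_codon_overrides: dict[tuple[str, int], str] | None = None,
                          ) -> dict[str, GeneModel]:
    """Synthetic sdhB/sdhD gene models for testing and simulation.

    Randomly generated stop-free coding sequences with the catalog's wild
    codons planted at the catalogued residues (sdhB: 288 codons covering
    residues up to 285; sdhD: 173 codons covering up to 120).  These are
    synthetic stand-ins -- the coordinates and background sequence carry
    no relation to the real mite genome; only the planted target codons
    are meaningful.
    """
    rng = np.random.default_rng(seed)
    catalog = load_catalog()
    sizes = {"sdhB": 288, "sdhD": 173}
    starts = {"sdhB": sdhb_start, "sdhD": sdhd_start}
    strands = {"sdhB": "+", "sdhD": sdhd_strand}
    models = {}
    for gene, n_codons in sizes.items():
        codons = [_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), n_codons)]
        planted: dict[int, str] = {}
        for e in catalog:
            if e.gene == gene:
                planted.setdefault(e.residue_index, e.wild_codon)
        for (g, residue), codon in (wild_codon_overrides or {}).items():
            if g == gene:
                planted[residue] = codon
        for residue, codon in planted.items():
            codons[residue - 1] = codon
        codons[-1] = "TAA"
        cds = "".join(codons)
        start = starts[gene]
        models[gene] = GeneModel(
            gene=gene, chrom=chrom,
            cds_intervals=[(start, start + 3 * n_codons - 1)],
            strand=strands[gene], cds_seq=cds,
        )
    return models
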