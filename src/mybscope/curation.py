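"""Curation of the R2R3-MYB gene family: representative isoforms, family
naming, protein properties, and domain-to-genome coordinate mapping.

The representative of each gene is its longest CDS isoform, falling back to
the next-longest whose MYB domain passes the integrity filter.  Family
names follow chromosomal placement: genome A before B, chromosomes 1-7,
unplaced (U) genes last, with a zero-padded global ordinal
(TdMYB1A001 ... TdMYBU233 for a 233-member family).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .simulate import GeneModel, Isoform

# ExPASy average residue masses (Da); free water added once per chain.
RESIDUE_MASS_AVG = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS_AVG = 18.0153

# Bjellqvist pK values (as used by the ExPASy pI tool).
PK_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PK_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PK_NTERM_BY_RESIDUE = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
                       "V": 7.44, "E": 7.7}
PK_CTERM_BY_RESIDUE = {"D": 4.55, "E": 4.75}


@dataclass
class CuratedGene:
    gene_id: str
    representative: str
    myb_class: str
    assigned_name: str | None = None
    intron_count: int | None = None
    pI: float | None = None
    molecular_weight: float | None = None
    domain_genomic_intervals: list[tuple[int, int]] | None = None


def select_representative(gene: GeneModel,
                          per_isoform_pass: dict[str, bool],
                          ) -> tuple[str, str | None]:
    """Longest-CDS isoform, else next-longest with an intact domain.

    Ties on CDS length break to the lexicographically smaller mRNA id.
    Returns ``(mrna_id, reason)`` where *reason* is ``None`` when an intact
    isoform was found and ``"no_intact_domain"`` when the gene keeps its
    longest isoform despite failing integrity.
    """
    if not gene.isoforms:
        raise ValueError(f"gene {gene.gene_id} has no isoforms")
    ranked = sorted(gene.isoforms, key=lambda i: (-i.cds_length, i.mrna_id))
    for iso in ranked:
        if per_isoform_pass.get(iso.mrna_id, False):
            return iso.mrna_id, None
    return ranked[0].mrna_id, "no_intact_domain"


def ambiguity_expression_filter(cds_sequence: str,
                                max_tpm_across_samples: float,
                                tpm_floor: float = 1.0) -> bool:
    """Keep/drop rule for ambiguous, unexpressed genes.

    A gene is dropped only when *both* hold: its CDS contains ambiguous
    bases (N) *and* its maximum TPM over all samples is below *tpm_floor*.
    Returns True to keep.
    """
    has_n = "N" in cds_sequence.upper()
    low = max_tpm_across_samples < tpm_floor
    return not (has_n and low)


def assign_names(genes: list[tuple[str, str, int]] | pd.DataFrame,
                 prefix: str = "TdMYB") -> dict[str, str]:
    """Assign family names by chromosomal placement.

    *genes* gives (gene_id, chromosome, start) triples (or a frame with
    those columns).  Sort order: genome letter A < B < U; chromosome number
    1-7; start coordinate ascending; U-genome genes come after all placed
    genes ordered by gene_id (their coordinates are not trusted).  Names are
    ``prefix + chromosome digit + genome letter + NNN`` with a global
    3-digit ordinal (the digit is omitted for U).  The assignment is a
    bijection and invariant to input order.
    """
    if isinstance(genes, pd.DataFrame):
        triples = list(genes[["gene_id", "chromosome", "start"]]
                       .itertuples(index=False, name=None))
    else:
        triples = list(genes)

    def key(t):
        gene_id, chrom, start = t
        if chrom == "U":
            return (1, "", 0, 0, gene_id)
        return (0, chrom[-1], int(chrom[:-1]), start, gene_id)

    names = {}
    for i, (gene_id, chrom, _start) in enumerate(sorted(triples, key=key), 1):
        tag = "U" if chrom == "U" else chrom
        names[gene_id] = f"{prefix}{tag}{i:03d}"
    if len(names) != len(triples):
        raise ValueError("duplicate gene_id in input")
    return names


def _charge_at(ph: float, counts: dict[str, int], nterm_pk: float,
               cterm_pk: float) -> float:
    pos = 10 ** -ph / (10 ** -nterm_pk + 10 ** -ph)
    for res in ("K", "R", "H"):
        pk = PK_POSITIVE[res]
        pos += counts.get(res, 0) * 10 ** -ph / (10 ** -pk + 10 ** -ph)
    neg = 10 ** -cterm_pk / (10 ** -cterm_pk + 10 ** -ph)
    for res in ("D", "E", "C", "Y"):
        pk = PK_NEGATIVE[res]
        neg += counts.get(res, 0) * 10 ** -pk / (10 ** -pk + 10 ** -ph)
    return pos - neg


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge with the Bjellqvist pK set."""
    seq = sequence.upper()
    bad = sorted(set(seq) - set(RESIDUE_MASS_AVG))
    if bad:
        raise ValueError(f"nonstandard residues: {bad}")
    counts = {a: seq.count(a) for a in set(seq)}
    nterm_pk = PK_NTERM_BY_RESIDUE.get(seq[0], PK_POSITIVE["Nterm"])
    cterm_pk = PK_CTERM_BY_RESIDUE.get(seq[-1], PK_NEGATIVE["Cterm"])
    return _charge_at(ph, counts, nterm_pk, cterm_pk)


def compute_pi_mw(sequence: str, tol: float = 1e-4,
                  max_iter: int = 60) -> tuple[float, float]:
    """Isoelectric point and average molecular weight of a protein chain.

    Mw sums average residue masses plus one water; pI is solved by
    bisection on the net charge (monotone decreasing in pH) until
    ``|charge| < tol``.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = sorted(set(seq) - set(RESIDUE_MASS_AVG))
    if bad:
        raise ValueError(f"nonstandard residues: {bad}")
    mw = sum(RESIDUE_MASS_AVG[a] for a in seq) + WATER_MASS_AVG
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(max_iter):
        ph = 0.5 * (lo + hi)
        c = net_charge(seq, ph)
        # stop on the charge criterion only once the bracket is tight in pH,
        # so shallow titration curves still give a converged pI
        if abs(c) < tol and hi - lo < 1e-5:
            break
        if c > 0:
            lo = ph
        else:
            hi = ph
    return ph, mw


def map_domain_to_genome(protein_span: tuple[int, int],
                         exons: list[tuple[int, int]],
                         strand: str) -> list[tuple[int, int]]:
    """Map a protein span onto genomic intervals through the CDS.

    Protein positions [a, b] correspond to CDS nucleotides [3a-2, 3b];
    those are projected through the exon structure (minus-strand CDSs walk
    the exons from the rightmost end leftward).  Output intervals are
    1-based inclusive, sorted by genomic coordinate, and their lengths sum
    to 3x the span length.
    """
    a, b = protein_span
    if a < 1 or b < a:
        raise ValueError("invalid protein span")
    cds_len = sum(e - s + 1 for s, e in exons)
    c1, c2 = 3 * a - 2, 3 * b
    if c2 > cds_len:
        raise ValueError(f"span end {b} beyond CDS ({cds_len} nt)")
    exons = sorted(exons)
    out: list[tuple[int, int]] = []
    offset = 0  # CDS nucleotides consumed so far
    walk = exons if strand == "+" else list(reversed(exons))
    for s, e in walk:
        ln = e - s + 1
        lo = max(c1, offset + 1)
        hi = min(c2, offset + ln)
        if lo <= hi:
            if strand == "+":
                out.append((s + (lo - offset - 1), s + (hi - offset - 1)))
            else:
                g_hi = e - (lo - offset - 1)
                g_lo = e - (hi - offset - 1)
                out.append((g_lo, g_hi))
        offset += ln
    return sorted(out)


def extract_cds(chrom_seq: str, exons: list[tuple[int, int]],
                strand: str) -> str:
    """Spliced CDS nucleotide sequence from a chromosome string."""
    from Bio.Seq import Seq
    parts = [chrom_seq[s - 1:e] for s, e in sorted(exons)]
    cds = "".join(parts)
    if strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def intron_count(isoform: Isoform) -> int:
    return len(isoform.exons) - 1


def curate_family(genes: list[GeneModel],
                  per_isoform_pass: dict[str, bool],
                  per_isoform_class: dict[str, str] | None = None,
                  proteins: dict[str, str] | None = None,
                  prefix: str = "TdMYB") -> pd.DataFrame:
    """Assemble the curated family table from gene models and annotations.

    *per_isoform_pass* maps mRNA id -> integrity verdict;
    *per_isoform_class* maps mRNA id -> MYB class (defaults to R2R3 for
    passing isoforms); *proteins* optionally maps mRNA id -> protein
    sequence for pI/Mw computation.
    """
    rows = []
    for g in genes:
        rep_id, reason = select_representative(g, per_isoform_pass)
        rep = next(i for i in g.isoforms if i.mrna_id == rep_id)
        if per_isoform_class is not None:
            klass = per_isoform_class.get(rep_id, "none")
        else:
            klass = "R2R3" if per_isoform_pass.get(rep_id) else "none"
        pi = mw = None
        if proteins and rep_id in proteins:
            pi, mw = compute_pi_mw(proteins[rep_id])
        rows.append(dict(gene_id=g.gene_id, representative=rep_id,
                         chromosome=g.chromosome, strand=g.strand,
                         start=g.start, myb_class=klass,
                         exclusion_reason=reason,
                         intron_count=intron_count(rep),
                         pI=pi, mw_da=mw))
    table = pd.DataFrame(rows)
    r2r3 = table[table.myb_class == "R2R3"]
    names = assign_names(r2r3[["gene_id", "chromosome", "start"]], prefix)
    table["name"] = table["gene_id"].map(names)
    return table
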