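"""Readers and writers for the standard formats, and pipeline configuration.

FASTA goes through Biopython, GFF3 through gffutils, Newick through
Bio.Phylo, and tabular data through pandas.  Coordinates are 1-based
inclusive throughout, matching GFF3.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .simulate import GeneModel, Isoform


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map (CRLF tolerated)."""
    from Bio import SeqIO
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS; exons double as CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            end = max(e for iso in g.isoforms for (_, e) in iso.exons)
            start = min(s for iso in g.isoforms for (s, _) in iso.exons)
            fh.write(f"{g.chromosome}\tmybscope\tgene\t{start}\t{end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for iso in g.isoforms:
                istart = min(s for s, _ in iso.exons)
                iend = max(e for _, e in iso.exons)
                fh.write(f"{g.chromosome}\tmybscope\tmRNA\t{istart}\t{iend}"
                         f"\t.\t{g.strand}\t.\tID={iso.mrna_id};"
                         f"Parent={g.gene_id}\n")
                for j, (s, e) in enumerate(sorted(iso.exons), 1):
                    fh.write(f"{g.chromosome}\tmybscope\texon\t{s}\t{e}\t.\t"
                             f"{g.strand}\t.\tID={iso.mrna_id}.exon{j};"
                             f"Parent={iso.mrna_id}\n")
                    fh.write(f"{g.chromosome}\tmybscope\tCDS\t{s}\t{e}\t.\t"
                             f"{g.strand}\t0\tID={iso.mrna_id}.cds{j};"
                             f"Parent={iso.mrna_id}\n")


def read_gff3(path) -> list[GeneModel]:
    """Read gene models (gene/mRNA/exon hierarchy) from a GFF3 file."""
    import gffutils
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for gf in db.features_of_type("gene"):
        isoforms = []
        for mf in db.children(gf, featuretype="mRNA"):
            exons = sorted((e.start, e.end)
                           for e in db.children(mf, featuretype="exon"))
            if not exons:
                raise ValueError(f"{path}: mRNA {mf.id} has no exons")
            cds = sorted((c.start, c.end)
                         for c in db.children(mf, featuretype="CDS")) or exons
            cds_len = sum(e - s + 1 for s, e in cds)
            isoforms.append(Isoform(mrna_id=mf.id, cds_length=cds_len,
                                    exons=exons))
        genes.append(GeneModel(gene_id=gf.id, chromosome=gf.seqid,
                               strand=gf.strand, start=gf.start,
                               isoforms=isoforms))
    return genes


def read_newick(path):
    from Bio import Phylo
    return Phylo.read(str(path), "newick")


def read_matrix_tsv(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All pipeline thresholds, defaulting to the published values."""

    seed: int = 0
    # synthetic family
    n_true_r2r3: int = 50
    n_decoys_per_kind: int = 5
    mutation_rate: float = 0.05
    # domain scan
    scan_threshold_bits: float = 5.0
    # expression
    tpm_threshold: float = 5.0
    min_replicates: int = 3
    fc_threshold: float = 2.0
    fdr_alpha: float = 0.05
    reference_gene: str = "RLIa"
    # motifs
    motif_threshold_fraction: float = 0.8
    # GRN
    n_trees: int = 100
    top_k: int = 16000
    # enrichment
    go_min_size: int = 10
    go_max_size: int = 1000
    go_permutations: int = 1000

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from JSON or TOML; unknown keys are rejected."""
        path = Path(path)
        if path.suffix == ".json":
            data = json.loads(path.read_text())
        else:
            import tomllib
            data = tomllib.loads(path.read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
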