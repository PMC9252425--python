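"""Synthetic-data generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here: protein
families with embedded R2R3 MYB domains plus decoy classes, multi-isoform
gene models on named chromosomes, motif-bearing sequence sets, replicated
qPCR Ct tables with known fold changes, expression matrices produced from a
known regulator->target network, and GO annotations with one planted
enriched category.

All randomness flows from a single integer seed through one
``numpy.random.Generator`` per call; identical spec + seed reproduces
identical output.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.array(list(AA20))


# ---------------------------------------------------------------------------
# canonical R2R3 domain template
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CanonicalDomainTemplate:
    """Coordinate system of the canonical 105-residue R2R3 MYB domain.

    Positions are 1-based.  The five tryptophan landmarks sit at 6, 26 and 46
    (R2 repeat) and 78 and 97 (R3 repeat).  The first tryptophan slot of R3,
    typical of animal c-MYB, is in plants generally occupied by a hydrophobic
    F or I; its coordinate is configurable (default 58).  The linker between
    the repeats carries the conserved LRPD motif (default positions 50-53).
    """

    length: int = 105
    tryptophan_landmarks: tuple[int, ...] = (6, 26, 46, 78, 97)
    r3_first_slot: int = 58
    r3_first_residue: str = "F"
    r3_first_allowed: frozenset[str] = frozenset({"F", "I", "W"})
    conserved_residues: dict[int, str] = field(
        default_factory=lambda: {
            10: "E", 11: "D", 14: "L", 22: "G", 42: "C", 43: "R", 45: "R",
            63: "E", 75: "G", 82: "A", 88: "R", 94: "K", 95: "N",
        }
    )
    l35_site: int = 35
    linker_motif: str = "LRPD"
    linker_offset: int = 50
    r2_span: tuple[int, int] = (1, 52)
    r3_span: tuple[int, int] = (53, 105)

    def __post_init__(self) -> None:
        if list(self.tryptophan_landmarks) != sorted(set(self.tryptophan_landmarks)):
            raise ValueError("tryptophan landmarks must be strictly increasing")
        if self.r2_span[0] != 1 or self.r3_span[1] != self.length \
                or self.r2_span[1] + 1 != self.r3_span[0]:
            raise ValueError("r2_span and r3_span must partition [1, length]")
        self.constraints()  # raises on conflict / out-of-range

    def constraints(self) -> dict[int, str]:
        """Map of constrained position -> mandated residue.

        Raises ``ValueError`` if two constraints disagree at one position or
        any constrained position falls outside [1, length].
        """
        out: dict[int, str] = {}

        def put(pos: int, res: str) -> None:
            if not 1 <= pos <= self.length:
                raise ValueError(f"constrained position {pos} outside [1,{self.length}]")
            if pos in out and out[pos] != res:
                raise ValueError(
                    f"conflicting constraints at position {pos}: "
                    f"{out[pos]!r} vs {res!r}"
                )
            out[pos] = res

        for p in self.tryptophan_landmarks:
            put(p, "W")
        if self.r3_first_residue not in self.r3_first_allowed:
            raise ValueError(
                f"r3_first_residue {self.r3_first_residue!r} not in allowed set")
        put(self.r3_first_slot, self.r3_first_residue)
        for p, r in self.conserved_residues.items():
            put(p, r)
        put(self.l35_site, "L")
        for i, r in enumerate(self.linker_motif):
            put(self.linker_offset + i, r)
        return out

    def landmarks_in_r2(self) -> tuple[int, ...]:
        lo, hi = self.r2_span
        return tuple(p for p in self.tryptophan_landmarks if lo <= p <= hi)

    def landmarks_in_r3(self) -> tuple[int, ...]:
        lo, hi = self.r3_span
        return tuple(p for p in self.tryptophan_landmarks if lo <= p <= hi)


def make_template(spec: CanonicalDomainTemplate | None = None,
                  seed: int = 0) -> str:
    """Draw one concrete 105-residue domain sequence from the template.

    Constrained positions carry their mandated residue; unconstrained
    positions are drawn uniformly from the 20 amino acids.
    """
    spec = spec or CanonicalDomainTemplate()
    rng = np.random.default_rng(seed)
    cons = spec.constraints()
    residues = _AA_ARR[rng.integers(0, 20, size=spec.length)]
    for pos, res in cons.items():
        residues[pos - 1] = res
    return "".join(residues)


# ---------------------------------------------------------------------------
# protein family with decoys
# ---------------------------------------------------------------------------

DECOY_KINDS = ("single_repeat", "truncated_repeat", "w_deficient", "triple_repeat")


@dataclass(frozen=True)
class FamilySimSpec:
    n_true_r2r3: int = 50
    n_decoys_per_kind: int = 5
    mutation_rate: float = 0.05
    seed: int = 0
    decoy_kinds: tuple[str, ...] = DECOY_KINDS
    flank_range: tuple[int, int] = (10, 80)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0,1]")
        if self.n_true_r2r3 < 0 or self.n_decoys_per_kind < 0:
            raise ValueError("counts must be >= 0")
        unknown = set(self.decoy_kinds) - set(DECOY_KINDS)
        if unknown:
            raise ValueError(f"unknown decoy kinds: {sorted(unknown)}")


def _random_flanks(rng: np.random.Generator,
                   flank_range: tuple[int, int]) -> tuple[str, str]:
    lo, hi = flank_range
    nl, nr = rng.integers(lo, hi + 1, size=2)
    left = "".join(_AA_ARR[rng.integers(0, 20, size=nl)])
    right = "".join(_AA_ARR[rng.integers(0, 20, size=nr)])
    return left, right


def _mutate_domain(domain: str, rng: np.random.Generator, rate: float,
                   constrained: set[int]) -> str:
    """Seeded point mutations that never touch constrained positions."""
    if rate == 0.0:
        return domain
    chars = np.array(list(domain))
    for i in range(len(chars)):
        if (i + 1) in constrained:
            continue
        if rng.random() < rate:
            chars[i] = _AA_ARR[rng.integers(0, 20)]
    return "".join(chars)


def simulate_family(spec: FamilySimSpec,
                    template: CanonicalDomainTemplate | None = None,
                    domain_sequence: str | None = None,
                    ) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate a labelled protein set: true R2R3 members plus decoys.

    Returns ``(sequences, truth)`` where *sequences* maps id -> protein and
    *truth* is a table with one row per record: true class, the planted
    repeat spans in protein coordinates, and the number of intact tryptophan
    landmarks.

    By default each member's unconstrained domain positions are drawn
    independently (only the template's constraint scaffold is shared), so
    column statistics outside the constrained sites stay at background.
    Passing *domain_sequence* instead embeds that one concrete domain in
    every member (mutated per member at unconstrained positions), so at
    ``mutation_rate=0`` every member's domain equals it exactly.

    Decoy construction: ``single_repeat`` keeps only the R2 repeat;
    ``truncated_repeat`` deletes 15 positions from inside R3;
    ``w_deficient`` mutates 3 landmark tryptophans to alanine;
    ``triple_repeat`` prepends an extra R2-like copy.
    """
    tpl = template or CanonicalDomainTemplate()
    rng = np.random.default_rng(spec.seed)
    cons = tpl.constraints()
    constrained = set(cons)
    if domain_sequence is not None and len(domain_sequence) != tpl.length:
        raise ValueError("domain_sequence length does not match template")
    r2_lo, r2_hi = tpl.r2_span
    r3_lo, r3_hi = tpl.r3_span

    seqs: dict[str, str] = {}
    rows: list[dict] = []

    def fresh_domain() -> str:
        if domain_sequence is not None:
            base = domain_sequence
        else:
            residues = _AA_ARR[rng.integers(0, 20, size=tpl.length)]
            for pos, res in cons.items():
                residues[pos - 1] = res
            base = "".join(residues)
        return _mutate_domain(base, rng, spec.mutation_rate, constrained)

    for i in range(spec.n_true_r2r3):
        sid = f"true_{i + 1:03d}"
        dom = fresh_domain()
        left, right = _random_flanks(rng, spec.flank_range)
        seqs[sid] = left + dom + right
        off = len(left)
        rows.append(dict(
            seq_id=sid, true_class="R2R3",
            domain_start=off + 1, domain_end=off + tpl.length,
            r2_start=off + r2_lo, r2_end=off + r2_hi,
            r3_start=off + r3_lo, r3_end=off + r3_hi,
            intact_landmarks=len(tpl.tryptophan_landmarks),
        ))

    for kind in spec.decoy_kinds:
        for i in range(spec.n_decoys_per_kind):
            sid = f"{kind}_{i + 1:03d}"
            dom = fresh_domain()
            left, right = _random_flanks(rng, spec.flank_range)
            off = len(left)
            intact = len(tpl.tryptophan_landmarks)
            r2s, r2e = off + r2_lo, off + r2_hi
            r3s: int | None = off + r3_lo
            r3e: int | None = off + r3_hi
            if kind == "single_repeat":
                dom = dom[:r2_hi]
                r3s = r3e = None
                intact = len(tpl.landmarks_in_r2())
            elif kind == "truncated_repeat":
                # delete 15 residues from inside R3 (template positions 60-74)
                dom = dom[:59] + dom[74:]
                r3s = r3e = None
            elif kind == "w_deficient":
                # destroy 3 of the 5 landmark tryptophans
                hit = rng.choice(len(tpl.tryptophan_landmarks), size=3, replace=False)
                chars = list(dom)
                for j in hit:
                    chars[tpl.tryptophan_landmarks[j] - 1] = "A"
                dom = "".join(chars)
                intact -= 3
            elif kind == "triple_repeat":
                extra = fresh_domain()[:r2_hi]
                dom = extra + dom
                r2s, r2e = off + r2_hi + r2_lo, off + 2 * r2_hi
                r3s, r3e = off + r2_hi + r3_lo, off + r2_hi + r3_hi
            seqs[sid] = left + dom + right
            rows.append(dict(
                seq_id=sid, true_class=kind,
                domain_start=off + 1, domain_end=off + len(dom),
                r2_start=r2s, r2_end=r2e, r3_start=r3s, r3_end=r3e,
                intact_landmarks=intact,
            ))

    truth = pd.DataFrame(rows)
    return seqs, truth


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

CHROMOSOMES = tuple(f"{n}{g}" for g in "AB" for n in range(1, 8)) + ("U",)


@dataclass
class Isoform:
    mrna_id: str
    cds_length: int
    exons: list[tuple[int, int]]  # 1-based inclusive genomic intervals, ascending
    domain_ok: bool = True


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    start: int
    isoforms: list[Isoform]


def simulate_gene_models(n_genes: int,
                         chromosomes: tuple[str, ...] = CHROMOSOMES,
                         isoforms_per_gene: int = 2,
                         frac_longest_broken: float = 0.2,
                         frac_unplaced: float = 0.03,
                         seed: int = 0,
                         with_sequences: bool = False,
                         ) -> tuple[list[GeneModel], pd.DataFrame] | tuple[
                             list[GeneModel], pd.DataFrame, dict[str, str]]:
    """Generate multi-isoform gene models with planted representatives.

    Exactly one isoform per gene is flagged in the truth table as the
    expected representative under the longest / second-longest rule: with
    probability *frac_longest_broken* the longest isoform's domain is marked
    incomplete and the second-longest becomes the planted representative.

    Truth also carries the expected family name for each gene, following
    chromosome order 1-7 within genome A then B, unplaced (U) genes last.

    With ``with_sequences=True`` a third element maps chromosome -> nucleotide
    sequence covering all generated loci, so CDS extraction round trips can
    be checked.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    placed_chroms = [c for c in chromosomes if c != "U"]

    genes: list[GeneModel] = []
    next_start: dict[str, int] = {}
    for gi in range(n_genes):
        gene_id = f"TRITDsim{gi + 1:04d}"
        if "U" in chromosomes and rng.random() < frac_unplaced:
            chrom = "U"
        else:
            chrom = placed_chroms[rng.integers(0, len(placed_chroms))]
        strand = "+" if rng.random() < 0.5 else "-"
        start = next_start.get(chrom, 1001) + int(rng.integers(0, 5000))
        n_iso = max(1, int(isoforms_per_gene))
        # distinct CDS lengths, multiples of 3
        lengths = sorted(set(int(x) * 3 for x in rng.integers(100, 400, size=n_iso * 2)))
        rng.shuffle(lengths)
        lengths = sorted(lengths[:n_iso], reverse=True)
        isoforms = []
        broken_longest = n_iso > 1 and rng.random() < frac_longest_broken
        for ii, cds_len in enumerate(lengths):
            n_exons = int(rng.integers(1, 5))
            exons = _split_into_exons(start, cds_len, n_exons, rng)
            isoforms.append(Isoform(
                mrna_id=f"{gene_id}.{ii + 1}",
                cds_length=cds_len,
                exons=exons,
                domain_ok=not (broken_longest and ii == 0),
            ))
        genes.append(GeneModel(gene_id, chrom, strand, start, isoforms))
        gene_end = max(e for iso in isoforms for (_, e) in iso.exons)
        next_start[chrom] = gene_end + 1

    truth = _gene_truth(genes)
    if not with_sequences:
        return genes, truth
    chrom_seqs: dict[str, str] = {}
    for chrom in {g.chromosome for g in genes}:
        end = max(e for g in genes if g.chromosome == chrom
                  for iso in g.isoforms for (_, e) in iso.exons)
        chrom_seqs[chrom] = "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, size=end + 100)])
    return genes, truth, chrom_seqs


def _split_into_exons(start: int, cds_len: int, n_exons: int,
                      rng: np.random.Generator) -> list[tuple[int, int]]:
    cuts = sorted(rng.choice(np.arange(1, cds_len), size=n_exons - 1,
                             replace=False)) if n_exons > 1 else []
    pieces = np.diff([0, *cuts, cds_len])
    exons = []
    pos = start
    for ln in pieces:
        exons.append((pos, pos + int(ln) - 1))
        pos += int(ln) + int(rng.integers(50, 500))  # intron
    return exons


def _gene_truth(genes: list[GeneModel]) -> pd.DataFrame:
    rows = []
    for g in genes:
        by_rule = sorted(g.isoforms, key=lambda i: (-i.cds_length, i.mrna_id))
        rep = next((i for i in by_rule if i.domain_ok), by_rule[0])
        rows.append(dict(gene_id=g.gene_id, chromosome=g.chromosome,
                         strand=g.strand, start=g.start,
                         representative=rep.mrna_id,
                         n_isoforms=len(g.isoforms)))
    truth = pd.DataFrame(rows)

    def sort_key(r):
        if r.chromosome == "U":
            return (1, "", 0, 0, r.gene_id)
        return (0, r.chromosome[-1], int(r.chromosome[:-1]), r.start, r.gene_id)

    order = sorted(truth.itertuples(), key=sort_key)
    names = {}
    for i, r in enumerate(order, start=1):
        tag = "U" if r.chromosome == "U" else f"{int(r.chromosome[:-1])}{r.chromosome[-1]}"
        names[r.gene_id] = f"TdMYB{tag}{i:03d}"
    truth["expected_name"] = truth["gene_id"].map(names)
    return truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_qpcr(true_fold_changes: dict[tuple[str, str, float], float],
                  ct_noise_sd: float = 0.1,
                  n_bio: int = 3,
                  n_tech: int = 3,
                  reference_gene: str = "RLIa",
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a replicated Ct table with known stressed/control folds.

    *true_fold_changes* maps (gene, tissue, time_h) -> fold change of the
    stressed condition relative to control.  The reference gene's Ct is
    constant in expectation across conditions; the target's stressed Ct is
    shifted by -log2(fold).  Each well receives independent Gaussian noise
    of sd *ct_noise_sd* cycles.

    A planted fold of 0 means the gene is undetected (NaN Ct) in both
    conditions; ``float('inf')`` means detected only under stress.
    """
    for fold in true_fold_changes.values():
        if not (fold > 0 or fold == 0 or np.isinf(fold)):
            raise ValueError("fold changes must be > 0 (or 0/inf for undetected)")
    rng = np.random.default_rng(seed)
    rows = []
    ref_base, target_base = 20.0, 25.0
    keys = sorted(true_fold_changes)
    blocks = sorted({(t, h) for (_, t, h) in keys})
    for tissue, time_h in blocks:
        for cond in ("control", "stressed"):
            for b in range(1, n_bio + 1):
                for r in range(1, n_tech + 1):
                    rows.append(dict(
                        gene=reference_gene, tissue=tissue, condition=cond,
                        time_h=time_h, bio_rep=b, tech_rep=r,
                        ct=ref_base + rng.normal(0.0, ct_noise_sd)))
    for (gene, tissue, time_h) in keys:
        fold = true_fold_changes[(gene, tissue, time_h)]
        for cond in ("control", "stressed"):
            shift = 0.0
            undetected = False
            if fold == 0:
                undetected = True
            elif np.isinf(fold):
                undetected = cond == "control"
            elif cond == "stressed":
                shift = -np.log2(fold)
            for b in range(1, n_bio + 1):
                for r in range(1, n_tech + 1):
                    ct = np.nan if undetected else \
                        target_base + shift + rng.normal(0.0, ct_noise_sd)
                    rows.append(dict(gene=gene, tissue=tissue, condition=cond,
                                     time_h=time_h, bio_rep=b, tech_rep=r, ct=ct))
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [dict(gene=g, tissue=t, time_h=h, true_fold=f)
         for (g, t, h), f in sorted(true_fold_changes.items())])
    return table, truth


# ---------------------------------------------------------------------------
# GRN expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrnSimSpec:
    n_genes: int = 200
    n_tfs: int = 20
    edges_per_target: int = 2
    n_samples: int = 100
    noise_sd: float = 0.3
    link_function: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs >= self.n_genes:
            raise ValueError("n_tfs must be < n_genes")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.link_function not in ("linear", "hinge"):
            raise ValueError("link_function must be 'linear' or 'hinge'")


def simulate_grn_expression(spec: GrnSimSpec) -> tuple[
        pd.DataFrame, pd.DataFrame, list[str], set[tuple[str, str]]]:
    """Expression matrices generated from a known regulator->target network.

    Regulator (TF) latent expression is iid standard normal across samples;
    each non-TF target is the link function of its true regulators plus
    Gaussian noise.  Latent values are exponentiated to positive abundances;
    counts are rounded scaled abundances and TPM columns are normalised to
    sum to 10^6.

    Returns ``(counts, tpm, regulators, true_edges)``.
    """
    rng = np.random.default_rng(spec.seed)
    tf_ids = [f"TF{i + 1:03d}" for i in range(spec.n_tfs)]
    tgt_ids = [f"G{i + 1:04d}" for i in range(spec.n_genes - spec.n_tfs)]
    genes = tf_ids + tgt_ids

    tf_latent = rng.normal(size=(spec.n_tfs, spec.n_samples))
    latent = np.empty((spec.n_genes, spec.n_samples))
    latent[:spec.n_tfs] = tf_latent
    true_edges: set[tuple[str, str]] = set()
    for ti, tgt in enumerate(tgt_ids):
        k = min(spec.edges_per_target, spec.n_tfs)
        regs = rng.choice(spec.n_tfs, size=k, replace=False)
        coefs = rng.uniform(0.8, 1.5, size=k) * rng.choice([-1.0, 1.0], size=k)
        x = tf_latent[regs]
        if spec.link_function == "hinge":
            x = np.maximum(x, 0.0)
        y = coefs @ x + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
        latent[spec.n_tfs + ti] = y
        for r in regs:
            true_edges.add((tf_ids[r], tgt))

    abundance = np.exp(latent)
    counts = pd.DataFrame(np.round(abundance * 50).astype(int), index=genes,
                          columns=[f"S{j + 1:03d}" for j in range(spec.n_samples)])
    tpm_vals = abundance / abundance.sum(axis=0, keepdims=True) * 1e6
    tpm = pd.DataFrame(tpm_vals, index=genes, columns=counts.columns)
    return counts, tpm, tf_ids, true_edges


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

def simulate_go_annotation(n_genes: int,
                           n_categories: int,
                           planted_category_size: int,
                           target_set_overlap: float,
                           target_set_size: int = 20,
                           size_range: tuple[int, int] = (10, 60),
                           seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """GO annotation map with exactly one category enriched by construction.

    The designated target (query) set of *target_set_size* genes overlaps
    the planted category in ``round(overlap * target_set_size)`` genes; the
    planted category is filled up to *planted_category_size* with random
    non-target genes.  All other categories annotate genes at random.

    Returns ``(annotation, truth)`` where *annotation* has columns
    (gene, category) and *truth* records the planted category id and the
    target set.
    """
    if not 10 <= planted_category_size <= 1000:
        raise ValueError("planted_category_size must lie in [10, 1000]")
    if not 0.0 <= target_set_overlap <= 1.0:
        raise ValueError("target_set_overlap must lie in [0,1]")
    if target_set_size > n_genes:
        raise ValueError("target set larger than universe")
    rng = np.random.default_rng(seed)
    universe = [f"G{i + 1:05d}" for i in range(n_genes)]
    target_set = list(rng.choice(universe, size=target_set_size, replace=False))

    planted_id = "GO:PLANTED"
    n_overlap = int(round(target_set_overlap * target_set_size))
    n_overlap = min(n_overlap, planted_category_size)
    members = set(rng.choice(target_set, size=n_overlap, replace=False))
    non_target = [g for g in universe if g not in target_set]
    fill = planted_category_size - len(members)
    if fill > len(non_target):
        raise ValueError("universe too small for planted category")
    members |= set(rng.choice(non_target, size=fill, replace=False))

    rows = [dict(gene=g, category=planted_id) for g in sorted(members)]
    lo, hi = size_range
    for c in range(n_categories - 1):
        cid = f"GO:{c + 1:07d}"
        size = int(rng.integers(lo, hi + 1))
        for g in sorted(rng.choice(universe, size=size, replace=False)):
            rows.append(dict(gene=g, category=cid))
    annotation = pd.DataFrame(rows)
    truth = dict(planted_category=planted_id, target_set=sorted(target_set),
                 universe=universe)
    return annotation, truth


# ---------------------------------------------------------------------------
# motif stand-ins
# ---------------------------------------------------------------------------

def make_motif_matrix(consensus: str, motif_id: str = "user",
                      sharpness: float = 0.9):
    """Build a synthetic position probability matrix around a consensus.

    Each column puts *sharpness* on the consensus residue and spreads the
    rest uniformly.  Returns a :class:`mybscope.motifs.MotifMatrix`.
    """
    from .motifs import MotifMatrix
    w = len(consensus)
    probs = np.full((w, 20), (1.0 - sharpness) / 19.0)
    for i, r in enumerate(consensus):
        probs[i, AA20.index(r)] = sharpness
    return MotifMatrix(motif_id=motif_id, probs=probs)


def make_related_motif_pair(target_correlation: float = 0.6,
                            width: int = 15,
                            seed: int = 0):
    """Synthetic stand-in pair of related motif matrices (PS1/PS2-like).

    The genuine reference motif matrices are external supplementary data;
    this constructs a clearly synthetic surrogate pair whose planted mean
    column-wise Pearson correlation (at zero offset) equals
    *target_correlation*.  The second matrix is a convex blend of the first
    with an independent random matrix; the blend weight is solved by
    bisection against the realised correlation, so the planted value is the
    generator's own construction, recoverable by
    :func:`mybscope.motifs.compare_motifs`.
    """
    from .motifs import MotifMatrix, compare_motifs
    rng = np.random.default_rng(seed)

    def random_probs() -> np.ndarray:
        p = rng.dirichlet(np.full(20, 0.3), size=width)
        return p

    a = random_probs()
    b_indep = random_probs()
    m1 = MotifMatrix(motif_id="PS1_synth", probs=a)

    def corr_at(alpha: float) -> float:
        blend = (1 - alpha) * a + alpha * b_indep
        blend = blend / blend.sum(axis=1, keepdims=True)
        return compare_motifs(m1, MotifMatrix(motif_id="PS2_synth", probs=blend))

    lo, hi = 0.0, 1.0
    if corr_at(1.0) > target_correlation:
        warnings.warn("independent matrix already above target correlation")
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if corr_at(mid) > target_correlation:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    blend = (1 - alpha) * a + alpha * b_indep
    blend = blend / blend.sum(axis=1, keepdims=True)
    m2 = MotifMatrix(motif_id="PS2_synth", probs=blend)
    return m1, m2


def plant_motifs_in_sequences(assignments: dict[str, list[str]],
                              motifs: dict[str, "object"],
                              length: int = 120,
                              seed: int = 0) -> dict[str, str]:
    """Random sequences with the consensus of named motifs planted.

    *assignments* maps sequence id -> list of motif ids (from *motifs*) to
    embed, left to right, separated by random spacers.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for sid, motif_ids in sorted(assignments.items()):
        pieces = ["".join(_AA_ARR[rng.integers(0, 20, size=10)])]
        for mid in motif_ids:
            pieces.append(motifs[mid].consensus())
            pieces.append("".join(_AA_ARR[rng.integers(0, 20, size=8)]))
        seq = "".join(pieces)
        if len(seq) < length:
            seq += "".join(_AA_ARR[rng.integers(0, 20, size=length - len(seq))])
        out[sid] = seq
    return out
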