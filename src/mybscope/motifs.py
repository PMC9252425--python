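"""Auxiliary-motif scanning, Poaceae clade rules, motif comparison, and
tree-anchored subfamily assignment.

Poaceae-restricted R2R3-MYB lineages are recognised from the presence or
absence of auxiliary amino-acid motifs (PS1-PS5 and motif 12): the
Poaceae-specific clade splits into group A (motif 12 without PS2) and
group B (PS2 without motif 12), the Poaceae-unique clade carries PS3, and
the Poaceae-basal clade carries PS4 and PS5.  Motif discovery itself is
consumed, not performed: motifs enter as position probability matrices.
"""

from __future__ import annotations

import io as _io
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import AA20

_AA_INDEX = {a: i for i, a in enumerate(AA20)}

POACEAE_MOTIFS = ("PS1", "PS2", "PS3", "PS4", "PS5", "motif12")
CLADES = ("poaceae_specific_A", "poaceae_specific_B", "poaceae_unique",
          "poaceae_basal", "unclassified")


@dataclass
class MotifMatrix:
    """Position probability matrix over the 20 amino acids, width 6-53."""

    motif_id: str
    probs: np.ndarray  # (width, 20)
    background: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not 6 <= self.width <= 53:
            raise ValueError("motif width must lie in [6, 53]")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("motif columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self, floor: float = 1e-9) -> np.ndarray:
        return np.log2(np.maximum(self.probs, floor) / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(AA20[i] for i in self.probs.argmax(axis=1))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.probs, columns=list(AA20))
        df.index = np.arange(1, self.width + 1)
        df.index.name = "position"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, motif_id: str | None = None) -> "MotifMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(motif_id=motif_id or str(path), probs=df[list(AA20)].to_numpy())


@dataclass
class MotifHit:
    motif_id: str
    score: float
    offset: int  # 0-based best offset; -1 when sequence shorter than motif
    present: bool


def scan_motif(sequence: str, motif: MotifMatrix,
               threshold_fraction: float = 0.8) -> MotifHit:
    """Best ungapped occurrence of a motif in a protein sequence.

    The score at an offset is the summed log-odds of the window; the call is
    *present* when the best score reaches ``threshold_fraction`` of the
    maximum attainable score.  A sequence shorter than the motif is absent
    with a warning.
    """
    w = motif.width
    if len(sequence) < w:
        warnings.warn(f"sequence shorter than motif {motif.motif_id}")
        return MotifHit(motif.motif_id, float("-inf"), -1, False)
    idx = np.array([_AA_INDEX.get(c, -1) for c in sequence.upper()])
    lo = np.concatenate([motif.log_odds(), np.full((w, 1), np.log2(1e-9 / 0.05))],
                        axis=1)
    win = np.lib.stride_tricks.sliding_window_view(idx, w)
    scores = lo[np.arange(w)[None, :], win].sum(axis=1)
    best = int(scores.argmax())
    score = float(scores[best])
    # threshold 0 is the degenerate "everything present" call: window
    # log-odds can be negative, so 0 * max_score would not be vacuous
    cutoff = threshold_fraction * motif.max_score() \
        if threshold_fraction > 0 else float("-inf")
    return MotifHit(motif.motif_id, score, best, score >= cutoff)


@dataclass
class PresenceTable:
    present: pd.DataFrame  # sequences x motifs, bool
    score: pd.DataFrame
    offset: pd.DataFrame


def build_presence_table(sequences: dict[str, str],
                         motifs: list[MotifMatrix],
                         threshold_fraction: float = 0.8) -> PresenceTable:
    ids = [m.motif_id for m in motifs]
    pres, score, off = ({} for _ in range(3))
    for sid, seq in sequences.items():
        hits = [scan_motif(seq, m, threshold_fraction) for m in motifs]
        pres[sid] = [h.present for h in hits]
        score[sid] = [h.score for h in hits]
        off[sid] = [h.offset for h in hits]
    mk = lambda d: pd.DataFrame.from_dict(d, orient="index", columns=ids)
    return PresenceTable(mk(pres).astype(bool), mk(score), mk(off))


def classify_poaceae_clade(presence: dict[str, bool] | pd.Series) -> str:
    """Clade call from the six motif presence flags, in priority order.

    Group A: motif 12 (with PS1) but not PS2; group B: PS2 (with PS1) but
    not motif 12; unique: PS3; basal: PS4 and PS5; otherwise unclassified.
    """
    p = dict(presence)
    missing = set(POACEAE_MOTIFS) - set(p)
    if missing:
        raise ValueError(f"presence row lacks motifs: {sorted(missing)}")
    if p["PS1"] and p["motif12"] and not p["PS2"]:
        return "poaceae_specific_A"
    if p["PS1"] and p["PS2"] and not p["motif12"]:
        return "poaceae_specific_B"
    if p["PS3"]:
        return "poaceae_unique"
    if p["PS4"] and p["PS5"]:
        return "poaceae_basal"
    return "unclassified"


def classify_clades(table: PresenceTable,
                    overrides: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-sequence clade assignments, with optional identifier pinning.

    *overrides* maps sequence id -> clade for documented exceptions that
    the motif rules alone would misplace.
    """
    overrides = overrides or {}
    rows = []
    for sid, row in table.present.iterrows():
        clade = overrides.get(sid) or classify_poaceae_clade(row)
        rows.append(dict(sequence_id=sid, clade=clade))
    return pd.DataFrame(rows)


def _column_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def compare_motifs(m1: MotifMatrix, m2: MotifMatrix,
                   min_overlap: int | None = None) -> float:
    """Similarity of two motif matrices in [-1, 1].

    The shorter motif is slid along the longer without gaps; at each offset
    with at least *min_overlap* aligned columns (default: half the shorter
    width) the mean column-wise Pearson correlation of the probability
    vectors is taken, and the maximum over offsets is returned.
    """
    short, long_ = (m1, m2) if m1.width <= m2.width else (m2, m1)
    if min_overlap is None:
        min_overlap = max(1, short.width // 2)
    if min_overlap > short.width:
        raise ValueError("min_overlap exceeds the shorter motif's width")
    best = -np.inf
    ws, wl = short.width, long_.width
    for shift in range(-(ws - min_overlap), wl - min_overlap + 1):
        lo = max(0, shift)
        hi = min(wl, shift + ws)
        if hi - lo < min_overlap:
            continue
        cors = [_column_corr(short.probs[j - shift], long_.probs[j])
                for j in range(lo, hi)]
        best = max(best, float(np.mean(cors)))
    return best


def presence_correlation(table: PresenceTable) -> pd.DataFrame:
    """Motif x motif phi coefficient on the 0/1 presence columns.

    Constant columns have undefined correlation and are reported as NaN
    (diagonal forced to 1).
    """
    x = table.present.to_numpy(float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 sequences")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.atleast_2d(c)
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=table.present.columns,
                        columns=table.present.columns)


# ---------------------------------------------------------------------------
# tree-anchored subfamily assignment
# ---------------------------------------------------------------------------

def assign_subfamily(tree, reference_labels: dict[str, str]) -> dict[str, str]:
    """Label query leaves from reference-annotated leaves in a rooted tree.

    *tree* is a ``Bio.Phylo`` tree, a path, or a Newick string.  Each
    unannotated leaf walks toward the root to the smallest enclosing clade
    that contains at least one reference leaf; its label is the majority
    subgroup among that clade's references, ``"ambiguous"`` on a tie.
    """
    from Bio import Phylo

    if isinstance(tree, str):
        tree = Phylo.read(_io.StringIO(tree), "newick")
    elif hasattr(tree, "read") or not hasattr(tree, "get_terminals"):
        tree = Phylo.read(tree, "newick")
    terminals = tree.get_terminals()
    names = [t.name for t in terminals]
    if len(names) != len(set(names)):
        raise ValueError("tree leaves must be unique")
    if not any(n in reference_labels for n in names):
        raise ValueError("no reference leaf present in tree")

    parent = {}
    for clade in tree.find_clades(order="level"):
        for child in clade.clades:
            parent[child] = clade

    out = {}
    for leaf in terminals:
        if leaf.name in reference_labels:
            continue
        node = parent.get(leaf)
        while node is not None:
            refs = [reference_labels[t.name] for t in node.get_terminals()
                    if t.name in reference_labels]
            if refs:
                counts = Counter(refs).most_common()
                if len(counts) > 1 and counts[0][1] == counts[1][1]:
                    out[leaf.name] = "ambiguous"
                else:
                    out[leaf.name] = counts[0][0]
                break
            node = parent.get(node)
    return out


# ---------------------------------------------------------------------------
# MEME minimal motif text format
# ---------------------------------------------------------------------------

def write_meme(motifs: list[MotifMatrix], path) -> None:
    """Write motifs in MEME minimal text format (protein alphabet)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AA20 + "\n\n")
        bg = motifs[0].background if motifs else np.full(20, 0.05)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{a} {b:.6f}" for a, b in zip(AA20, bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 20 w= {m.width}\n")
            for row in m.probs:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[MotifMatrix]:
    """Read motifs from MEME minimal text format.

    Only the letter-probability matrices and the background line are
    consumed; alphabet order is taken from the ALPHABET line when present.
    """
    alphabet = AA20
    background = np.full(20, 0.05)
    motifs: list[MotifMatrix] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("ALPHABET="):
            alphabet = ln.split("=", 1)[1].strip()
        elif ln.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            background = np.array([float(toks[j + 1]) for j in range(0, len(toks) // 2 * 2, 2)
                                   ][:len(alphabet)])
            i += 1
        elif ln.startswith("MOTIF"):
            motif_id = ln.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                    "letter-probability matrix"):
                i += 1
            header = lines[i].strip()
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(1, w + 1):
                rows.append([float(x) for x in lines[i + j].split()])
            i += w
            probs = np.array(rows)
            if alphabet != AA20:  # reorder columns to the canonical alphabet
                order = [alphabet.index(a) for a in AA20]
                probs = probs[:, order]
            bg = background
            if alphabet != AA20:
                bg = background[[alphabet.index(a) for a in AA20]]
            motifs.append(MotifMatrix(motif_id=motif_id, probs=probs,
                                      background=bg))
        i += 1
    return motifs
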