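"""Tree-ensemble gene-regulatory-network inference and GO enrichment.

Edges are scored GENIE3-style: each target gene (standardised to unit
variance across samples) is regressed on the expression of all candidate
regulators with a random-forest ensemble (bootstrap resampling, a random
candidate subset at each split, splits maximising variance reduction); a
regulator's edge weight is its total variance reduction, averaged over
trees.  Because tree splits depend only on the ordering of each feature,
weights are invariant under strictly monotone transforms of any single
regulator's expression.

Downstream, the global edge list is pruned to the top-k by weight,
per-regulator sub-networks are extracted, and target sets are tested for
GO biological-process enrichment with a hypergeometric test and
permutation-based family-wise error control.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor


def infer_network(expr: pd.DataFrame, regulators: list[str],
                  n_trees: int = 100,
                  candidate_fraction: float | str = "sqrt",
                  seed: int = 0) -> pd.DataFrame:
    """Infer a weighted directed regulator->target edge list.

    *expr* is genes x samples; *regulators* names the candidate
    transcription factors (must be rows of *expr*).  Every gene is a
    potential target; self-edges are excluded.  ``candidate_fraction``
    sets the number of candidate regulators tried at each split, either
    the string ``"sqrt"`` (GENIE3's K = sqrt default) or a fraction of the
    candidate count.

    Returns a frame with columns (regulator, target, weight, rank), ranked
    by descending weight with ties broken lexicographically.  A
    constant-expression target contributes zero-weight edges with a
    warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    missing = [r for r in regulators if r not in expr.index]
    if missing:
        raise ValueError(f"regulators absent from matrix: {missing[:5]}")
    if len(regulators) < 2:
        raise ValueError("need >= 2 regulators")

    # canonical sample order: bootstrap draws depend on row order, so fix it
    # to make results invariant to the input's column permutation
    expr = expr[sorted(expr.columns)]
    x_all = expr.loc[regulators].to_numpy(dtype=float).T  # samples x TFs
    reg_pos = {r: i for i, r in enumerate(regulators)}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(expr.index))

    rows = []
    for gi, target in enumerate(expr.index):
        y = expr.loc[target].to_numpy(dtype=float)
        cand_idx = [i for r, i in reg_pos.items() if r != target]
        sd = y.std()
        if sd == 0.0:
            warnings.warn(f"constant-expression target {target}; "
                          "zero-weight edges")
            imp = np.zeros(len(cand_idx))
        else:
            y_std = (y - y.mean()) / sd
            x = x_all[:, cand_idx]
            if candidate_fraction == "sqrt":
                mf = "sqrt"
            else:
                mf = max(1, int(np.ceil(float(candidate_fraction) * x.shape[1])))
            rf = RandomForestRegressor(
                n_estimators=n_trees, max_features=mf, bootstrap=True,
                random_state=int(child_seeds[gi] % (2**31 - 1)), n_jobs=1)
            rf.fit(x, y_std)
            # total variance reduction per feature, averaged over trees
            imp = np.mean(
                [t.tree_.compute_feature_importances(normalize=False)
                 for t in rf.estimators_], axis=0)
        for ci, w in zip(cand_idx, imp):
            rows.append((regulators[ci], target, float(w)))

    edges = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
    return _rank_edges(edges)


def _rank_edges(edges: pd.DataFrame) -> pd.DataFrame:
    edges = edges.sort_values(["weight", "regulator", "target"],
                              ascending=[False, True, True],
                              kind="mergesort").reset_index(drop=True)
    edges["rank"] = np.arange(1, len(edges) + 1)
    return edges


def prune_top_edges(edges: pd.DataFrame, k: int = 16000) -> pd.DataFrame:
    """Keep the top-k edges by weight.

    Boundary ties break lexicographically on (regulator, target), so the
    result is deterministic; ``prune_top_edges(k)`` is always a subset of
    ``prune_top_edges(k + 1)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return _rank_edges(edges).head(k).reset_index(drop=True)


def extract_subnetwork(edges: pd.DataFrame, query: list[str],
                       ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Edges whose regulator is in the query set, plus per-TF out-degrees.

    Query TFs absent from the edge list get an out-degree of 0 (their
    target list is empty).
    """
    sub = edges[edges.regulator.isin(query)].reset_index(drop=True)
    degrees = {q: 0 for q in query}
    degrees.update(sub.groupby("regulator").size().to_dict())
    return sub, degrees


def to_graphml(edges: pd.DataFrame, path) -> None:
    """Export an edge list as GraphML (regulator -> target, weight attr)."""
    import networkx as nx
    g = nx.DiGraph()
    for r in edges.itertuples():
        g.add_edge(r.regulator, r.target, weight=float(r.weight))
    nx.write_graphml(g, path)


def edge_recovery_aupr(edges: pd.DataFrame,
                       true_edges: set[tuple[str, str]]) -> float:
    """Area under precision-recall for ranked edges against planted truth."""
    from sklearn.metrics import average_precision_score
    labels = [(r, t) in true_edges
              for r, t in zip(edges.regulator, edges.target)]
    if not any(labels):
        raise ValueError("no true edge appears in the edge list")
    return float(average_precision_score(labels, edges.weight.to_numpy()))


# ---------------------------------------------------------------------------
# GO biological-process enrichment
# ---------------------------------------------------------------------------

def go_enrichment(query: list[str],
                  annotation: pd.DataFrame,
                  universe: list[str],
                  min_size: int = 10, max_size: int = 1000,
                  n_permutations: int = 1000,
                  seed: int = 0,
                  alpha: float = 0.05,
                  method: str = "permutation") -> pd.DataFrame:
    """Hypergeometric category enrichment with FWER control.

    *annotation* has columns (gene, category); categories are restricted to
    the universe and those with fewer than *min_size* or more than
    *max_size* annotated genes are excluded.  The per-category p-value is
    the hypergeometric upper tail of the query/category overlap.

    FWER control: with ``method="permutation"`` (min-p method),
    *n_permutations* random query sets of the same size define the null of
    the minimum p-value, and a category's adjusted p is the (add-one
    smoothed) fraction of permutations whose minimum p is at most its
    observed p.  ``method="bonferroni"`` is a fast fallback.
    """
    if len(query) == 0:
        raise ValueError("empty query set")
    uni = pd.Index(universe)
    stray = set(query) - set(uni)
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:5]}")
    ann = annotation[annotation.gene.isin(uni)]
    sizes = ann.groupby("category")["gene"].nunique()
    cats = sizes[(sizes >= min_size) & (sizes <= max_size)].index.to_numpy()
    if len(cats) == 0:
        return pd.DataFrame(columns=["category", "category_size", "overlap",
                                     "p_value", "p_fwer", "significant"])

    n_univ = len(uni)
    n_query = len(set(query))
    pos = {g: i for i, g in enumerate(uni)}
    member = np.zeros((len(cats), n_univ), dtype=bool)
    for ci, c in enumerate(cats):
        for g in ann.loc[ann.category == c, "gene"].unique():
            member[ci, pos[g]] = True
    k_sizes = member.sum(axis=1)

    member_int = member.astype(np.int64)
    q_vec = np.zeros(n_univ, dtype=np.int64)
    for g in set(query):
        q_vec[pos[g]] = 1
    overlap = member_int @ q_vec
    p_obs = stats.hypergeom.sf(overlap - 1, n_univ, k_sizes, n_query)

    if method == "bonferroni":
        p_fwer = np.minimum(1.0, p_obs * len(cats))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        min_ps = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = np.zeros(n_univ, dtype=np.int64)
            perm[rng.choice(n_univ, size=n_query, replace=False)] = 1
            ov = member_int @ perm
            min_ps[b] = stats.hypergeom.sf(ov - 1, n_univ, k_sizes,
                                           n_query).min()
        p_fwer = np.array([(1 + np.sum(min_ps <= p)) / (n_permutations + 1)
                           for p in p_obs])
    else:
        raise ValueError("method must be 'permutation' or 'bonferroni'")

    out = pd.DataFrame(dict(category=cats, category_size=k_sizes,
                            overlap=overlap, p_value=p_obs, p_fwer=p_fwer))
    out["significant"] = out.p_fwer < alpha
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
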