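"""Differential expression and gene-set statistics.

Covers the perturbation-statistics layer: per-gene Wilcoxon rank-sum
differential expression with Benjamini-Hochberg FDR, GO include/exclude
filtering of DEG lists, upper-tail hypergeometric significance of DEG
overlaps between cell types (reported as -log10 FDR p), one-vs-rest
top-N gene modules per cell class, over-representation "disease scores"
trimmed to [0, 10], and a preranked GSEA with a gene-permutation null.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_gmt",
    "write_gmt",
    "wilcoxon_deg",
    "filter_degs_go",
    "overlap_significance_matrix",
    "top_modules",
    "disease_enrichment",
    "prerank_gsea",
]


# ---------------------------------------------------------------- gene sets


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file: one set per line, name <tab> description <tab> genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, genes = parts[0], {g for g in parts[2:] if g}
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        sets[name] = genes
    return sets


def write_gmt(path, sets: dict[str, set[str]], description: str = "na") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(sorted(genes)) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------- differential expression


def wilcoxon_deg(
    expr: pd.DataFrame | np.ndarray,
    group_labels,
    test_group: str = "deletion",
    ref_group: str = "control",
    cell_classes=None,
    restrict_class: str | None = None,
    fdr_threshold: float = 0.05,
    method: str = "auto",
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE between two cell groups.

    ``expr`` is genes x cells of log2(CPM+1) values; ``group_labels`` one
    label per cell.  Optionally restrict to cells of one class.  P-values
    use the tie-corrected rank-sum test (exact for small untied samples),
    BH-adjusted over all genes of the family; ``significant`` marks
    FDR p < ``fdr_threshold``.  Log2 fold change is computed on the
    exponentiated group means of the log-normalised values with a 1e-9
    pseudocount.
    """
    if isinstance(expr, pd.DataFrame):
        genes = expr.index
        X = expr.to_numpy(dtype=float)
    else:
        X = np.asarray(expr, dtype=float)
        genes = pd.Index([f"g{i}" for i in range(X.shape[0])])
    labels = np.asarray(group_labels)
    mask = np.ones(X.shape[1], dtype=bool)
    if restrict_class is not None:
        if cell_classes is None:
            raise ValueError("restrict_class requires cell_classes")
        mask = np.asarray(cell_classes) == restrict_class
    sel_a = mask & (labels == test_group)
    sel_b = mask & (labels == ref_group)
    if sel_a.sum() < 3 or sel_b.sum() < 3:
        raise ValueError(
            f"both groups need >= 3 cells (got {int(sel_a.sum())} {test_group!r}, "
            f"{int(sel_b.sum())} {ref_group!r})"
        )
    A, B = X[:, sel_a], X[:, sel_b]
    res = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided", method=method)
    p = np.asarray(res.pvalue, dtype=float)
    stat = np.asarray(res.statistic, dtype=float)
    # constant genes have zero rank variance; the test is uninformative
    constant = (A.std(axis=1) == 0) & (B.std(axis=1) == 0) & (A.mean(axis=1) == B.mean(axis=1))
    p = np.where(constant, 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    eps = 1e-9
    log2fc = np.log2(
        (np.maximum(np.exp2(mean_a) - 1, 0.0) + eps)
        / (np.maximum(np.exp2(mean_b) - 1, 0.0) + eps)
    )
    return pd.DataFrame(
        {
            "mean_test": mean_a,
            "mean_ref": mean_b,
            "log2fc": log2fc,
            "statistic": stat,
            "p_value": p,
            "fdr": fdr,
            "significant": fdr < fdr_threshold,
        },
        index=genes,
    )


def filter_degs_go(genes, include: dict[str, set] | None, exclude: dict[str, set] | None) -> list:
    """Keep genes in the union of include sets minus the union of excludes.

    An empty/None ``include`` keeps everything not excluded.  Input order
    is preserved.
    """
    inc = set().union(*include.values()) if include else None
    exc = set().union(*exclude.values()) if exclude else set()
    out = []
    for g in genes:
        if inc is not None and g not in inc:
            continue
        if g in exc:
            continue
        out.append(g)
    return out


# --------------------------------------------------------------- overlaps


def hypergeom_overlap_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k > min(K, n):
        raise ValueError("overlap k cannot exceed min(K, n)")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overlap_significance_matrix(deg_lists: dict[str, set], universe) -> pd.DataFrame:
    """Pairwise hypergeometric overlap significance between DEG lists.

    ``universe`` is either the background gene collection (sets are
    validated against it) or its size N.  For every ordered off-diagonal
    pair the upper-tail hypergeometric p of the observed overlap is
    computed, BH-corrected across all off-diagonal pairs of the family,
    and reported as score = -log10(FDR p).
    """
    names = list(deg_lists)
    sets = {k: set(v) for k, v in deg_lists.items()}
    if isinstance(universe, (int, np.integer)):
        N = int(universe)
    else:
        uni = set(universe)
        for name, s in sets.items():
            extra = s - uni
            if extra:
                raise ValueError(f"DEG list {name!r} has genes outside the universe: {sorted(extra)[:5]}")
        N = len(uni)
    if any(len(s) > N for s in sets.values()):
        raise ValueError("universe smaller than a DEG list")
    rows = []
    for a in names:
        for b in names:
            if a == b:
                continue
            k = len(sets[a] & sets[b])
            p = hypergeom_overlap_p(k, N, len(sets[a]), len(sets[b])) if k > 0 else 1.0
            rows.append({"list_a": a, "list_b": b, "k": k, "K": len(sets[a]), "n": len(sets[b]), "N": N, "p": p})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    df["score"] = -np.log10(df["fdr"].clip(lower=np.finfo(float).tiny)) + 0.0
    return df


def top_modules(
    expr: pd.DataFrame,
    class_labels,
    n: int = 200,
) -> dict[str, list[str]]:
    """Per-class gene modules: top ``n`` one-vs-rest upregulated genes.

    Each class is tested against all other cells with the rank-sum test;
    genes are ranked by significance (raw p ascending) and then by effect
    size (log2 fold change descending), with upregulated genes ahead of
    downregulated ones — a module is the class's positive signature.
    """
    labels = pd.Series(np.asarray(class_labels))
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    onevsrest = np.where(labels.to_numpy()[None, :] == np.array(classes)[:, None], "self", "rest")
    modules: dict[str, list[str]] = {}
    for i, cls in enumerate(classes):
        table = wilcoxon_deg(expr, onevsrest[i], test_group="self", ref_group="rest", method="asymptotic")
        table = table.assign(_down=table["log2fc"] <= 0)
        ranked = table.sort_values(
            ["_down", "p_value", "log2fc"], ascending=[True, True, False], kind="stable"
        )
        modules[cls] = list(ranked.index[: min(n, len(ranked))])
    return modules


def disease_enrichment(
    deg_genes,
    disease_sets: dict[str, set],
    universe,
    trim: float = 10.0,
) -> pd.DataFrame:
    """Over-representation of a DEG list in curated disease gene sets.

    Per set: upper-tail hypergeometric p of the overlap, BH across sets,
    score = -log10(FDR p) clipped to [0, ``trim``].  An empty DEG list
    yields all-zero scores with a flag column.
    """
    deg = set(deg_genes)
    if isinstance(universe, (int, np.integer)):
        N = int(universe)
        restrict = None
    else:
        restrict = set(universe)
        N = len(restrict)
    rows = []
    for name, s in disease_sets.items():
        s = set(s) if restrict is None else set(s) & restrict
        k = len(deg & s)
        if not deg:
            rows.append({"disease_set": name, "k": 0, "K": len(deg), "n": len(s), "N": N, "p": 1.0, "empty_deg": True})
            continue
        p = hypergeom_overlap_p(k, N, len(deg), len(s)) if k > 0 else 1.0
        rows.append({"disease_set": name, "k": k, "K": len(deg), "n": len(s), "N": N, "p": p, "empty_deg": False})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    df["score"] = np.clip(-np.log10(df["fdr"].clip(lower=np.finfo(float).tiny)), 0.0, trim) + 0.0
    return df


# ----------------------------------------------------------------- GSEA


def _enrichment_score(order: np.ndarray, weights: np.ndarray, in_set: np.ndarray) -> float:
    """Weighted Kolmogorov-Smirnov running-sum ES for one ranked list.

    ``order`` indexes genes from best to worst rank; ``weights`` are
    |score|^w per gene; ``in_set`` flags set membership.  Hits step up by
    their weight share, misses step down by 1/(N - n_set); the ES is the
    running-sum extremum of largest magnitude.
    """
    hits = in_set[order]
    n_miss = len(order) - hits.sum()
    if hits.sum() == 0:
        raise ValueError("gene set is empty after intersecting the ranking")
    if n_miss == 0:
        return 0.0  # the complement is empty: the set carries no ranking signal
    w = weights[order] * hits
    w_total = w.sum()
    if w_total == 0:
        # all member scores are zero: fall back to unweighted steps
        w = hits.astype(float)
        w_total = w.sum()
    running = np.cumsum(w / w_total - (~hits) / n_miss)
    i = np.argmax(np.abs(running))
    return float(running[i])


def prerank_gsea(
    ranked_scores: pd.Series,
    gene_set,
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
) -> dict:
    """Preranked GSEA: weighted KS enrichment score with a permutation null.

    ``ranked_scores`` maps gene -> ranking metric (any order; sorted
    descending internally).  The null redraws the member labels uniformly
    among the ranked genes ``n_perm`` times.  NES divides the observed ES
    by the mean |null ES| of matching sign; the permutation p is the
    fraction of null scores at least as extreme in absolute value.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100 gives a coarse permutation p", stacklevel=2)
    scores = ranked_scores.sort_values(ascending=False, kind="stable")
    if not np.all(np.isfinite(scores.to_numpy(dtype=float))):
        raise ValueError("ranking scores must be finite")
    genes = scores.index.to_numpy()
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set is empty after intersecting the ranking")
    in_set = np.isin(genes, list(members))
    weights = np.abs(scores.to_numpy(dtype=float)) ** weight
    order = np.arange(len(genes))
    es = _enrichment_score(order, weights, in_set)

    rng = np.random.default_rng(seed)
    n_hit = int(in_set.sum())
    null_es = np.empty(n_perm)
    for i in range(n_perm):
        perm = np.zeros(len(genes), dtype=bool)
        perm[rng.choice(len(genes), size=n_hit, replace=False)] = True
        null_es[i] = _enrichment_score(order, weights, perm)
    same_sign = null_es * np.sign(es) > 0
    denom = np.abs(null_es[same_sign]).mean() if same_sign.any() else np.nan
    nes = es / denom if denom and np.isfinite(denom) else np.nan
    p = float(np.mean(np.abs(null_es) >= abs(es)))
    return {"es": es, "nes": float(nes), "p_value": p, "n_perm": n_perm, "n_hits": n_hit}
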