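"""Synthetic UMI count matrices with class structure and known DEG truth.

Cells belong to one of a few neural classes (default NEC, oRG, IPC, CN,
IN); each class has a disjoint set of boosted marker genes over a shared
log-normal baseline expression profile.  Counts are negative-binomial
with mean mu and dispersion theta (var = mu + mu^2/theta).  Deletion
samples carry injected per-class log2 fold changes on known gene sets
(half up, half down).  Mitochondrial genes ("MT-" prefix) are scaled per
cell to hit a Beta-distributed mitochondrial fraction in expectation, and
each cell draws a log-normal library size.  Pseudotime ground truth is a
per-class Beta distribution on [0, 1]; the genotype effect is a location
shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ..scqc import CountMatrix

__all__ = ["ScSimConfig", "ScTruth", "ReferenceQuery", "simulate_counts", "simulate_reference_query"]

DEFAULT_PSEUDOTIME = {
    "NEC": (1.5, 6.0),
    "oRG": (3.0, 5.0),
    "IPC": (4.0, 4.0),
    "CN": (6.0, 3.0),
    "IN": (6.0, 2.5),
}


@dataclass
class ScSimConfig:
    """Generative settings for a synthetic perturbation experiment."""

    n_genes: int = 2000
    classes: tuple[str, ...] = ("NEC", "oRG", "IPC", "CN", "IN")
    n_markers_per_class: int = 20
    marker_boost: float = 8.0  # fold boost of marker means in their class
    samples: tuple[tuple[str, str], ...] = (
        ("ctrl1", "control"),
        ("ctrl2", "control"),
        ("del1", "deletion"),
        ("del2", "deletion"),
    )
    time_point: str = "3.5mo"
    n_cells_per_class_per_sample: int = 200
    nb_dispersion: float = 2.0
    library_size_mean: float = 6000.0
    library_size_sigma: float = 0.35  # log-normal sigma of library sizes
    n_mito_genes: int = 13
    mito_frac_mean: float = 0.05
    mito_frac_concentration: float = 50.0  # Beta concentration of per-cell fraction
    n_deg_per_class: int = 50
    deg_log2fc: float = 1.0  # magnitude of injected effects (half up, half down)
    pseudotime_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PSEUDOTIME)
    )
    pseudotime_shift: float = 0.08  # deletion location shift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_class_per_sample < 1:
            raise ValueError("every class needs at least one cell per sample")
        if self.n_markers_per_class * len(self.classes) + self.n_mito_genes > self.n_genes:
            raise ValueError("gene universe too small for markers + mito genes")
        if not np.isfinite(self.deg_log2fc):
            raise ValueError("deg_log2fc must be finite")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("nb_dispersion and library_size_mean must be positive")
        if not (0 < self.mito_frac_mean < 1):
            raise ValueError("mito_frac_mean must lie in (0, 1)")


@dataclass
class ScTruth:
    """Ground truth: true class, injected DEG effects, true pseudotime."""

    cell_class: pd.Series
    deg_effects: dict[str, dict[str, float]]  # class -> gene -> signed log2fc
    pseudotime: pd.Series
    markers: dict[str, list[str]]

    def deg_sets(self) -> dict[str, set[str]]:
        return {c: set(d) for c, d in self.deg_effects.items()}


def _gene_names(config: ScSimConfig) -> list[str]:
    n_reg = config.n_genes - config.n_mito_genes
    names = [f"G{i:05d}" for i in range(n_reg)]
    names += [f"MT-{i + 1}" for i in range(config.n_mito_genes)]
    return names


def _build_profiles(config: ScSimConfig, rng: np.random.Generator):
    """Per-class relative expression over non-mito genes, plus assignments."""
    genes = _gene_names(config)
    n_reg = config.n_genes - config.n_mito_genes
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_reg)
    markers: dict[str, list[str]] = {}
    profiles: dict[str, np.ndarray] = {}
    marker_pool = rng.permutation(n_reg)
    used = 0
    for cls in config.classes:
        idx = marker_pool[used : used + config.n_markers_per_class]
        used += config.n_markers_per_class
        prof = base.copy()
        prof[idx] *= config.marker_boost
        profiles[cls] = prof
        markers[cls] = [genes[i] for i in idx]
    # injected DEG sets: non-marker, non-mito genes that are actually
    # expressed (expected >= ~1 UMI/cell) — a fold change on a gene with
    # near-zero counts is unidentifiable at any sample size
    candidates = marker_pool[used:]
    rel = base / base.sum()
    candidates = candidates[rel[candidates] * config.library_size_mean >= 1.0]
    deg_idx: dict[str, np.ndarray] = {}
    effects: dict[str, dict[str, float]] = {}
    for cls in config.classes:
        chosen = rng.choice(candidates, size=min(config.n_deg_per_class, len(candidates)), replace=False)
        deg_idx[cls] = chosen
        half = len(chosen) // 2
        eff = {}
        for j, gi in enumerate(chosen):
            eff[genes[gi]] = config.deg_log2fc if j < half or half == 0 else -config.deg_log2fc
        effects[cls] = eff
    mito_base = rng.lognormal(mean=0.0, sigma=0.5, size=config.n_mito_genes)
    return genes, profiles, markers, deg_idx, effects, mito_base


def simulate_counts(
    config: ScSimConfig, cell_seed: int | None = None
) -> tuple[CountMatrix, pd.DataFrame, ScTruth]:
    """Simulate a genes x cells UMI matrix with metadata and ground truth.

    Returns (counts, metadata, truth); metadata has one row per cell with
    sample, genotype, time_point, cell_class and true pseudotime.
    Identical config + seed gives identical output.  The class-generative
    profiles depend only on ``config.seed``; ``cell_seed`` draws an
    independent set of cells from the *same* generative models (used to
    produce matched reference/query datasets).
    """
    rng_profile = np.random.default_rng(config.seed)
    genes, profiles, markers, deg_idx, effects, mito_base = _build_profiles(config, rng_profile)
    rng = rng_profile if cell_seed is None else np.random.default_rng([config.seed, cell_seed])
    n_reg = config.n_genes - config.n_mito_genes
    mito_rel = mito_base / mito_base.sum()
    theta = config.nb_dispersion
    a_m = config.mito_frac_mean * config.mito_frac_concentration
    b_m = (1 - config.mito_frac_mean) * config.mito_frac_concentration

    blocks = []
    meta_rows = []
    pt_values = []
    cell_id = 0
    for sample, genotype in config.samples:
        for cls in config.classes:
            n = config.n_cells_per_class_per_sample
            prof = profiles[cls].copy()
            if genotype == "deletion":
                for j, gi in enumerate(deg_idx[cls]):
                    prof[gi] *= 2.0 ** effects[cls][genes[gi]]
            rel = prof / prof.sum()
            lib = config.library_size_mean * np.exp(
                config.library_size_sigma * rng.standard_normal(n)
                - config.library_size_sigma**2 / 2.0
            )
            mito_f = rng.beta(a_m, b_m, size=n)
            mu_reg = rel[:, None] * (lib * (1 - mito_f))[None, :]
            mu_mito = mito_rel[:, None] * (lib * mito_f)[None, :]
            mu = np.vstack([mu_reg, mu_mito])
            p = theta / (theta + mu)
            block = rng.negative_binomial(theta, p)
            blocks.append(sp.csr_matrix(block))
            a, b = config.pseudotime_params.get(cls, (2.0, 2.0))
            pt = rng.beta(a, b, size=n)
            if genotype == "deletion":
                pt = np.clip(pt + config.pseudotime_shift, 0.0, 1.0)
            pt_values.append(pt)
            for _ in range(n):
                meta_rows.append(
                    {
                        "barcode": f"cell{cell_id:06d}",
                        "sample": sample,
                        "genotype": genotype,
                        "time_point": config.time_point,
                        "cell_class": cls,
                    }
                )
                cell_id += 1
    X = sp.hstack(blocks, format="csr")
    meta = pd.DataFrame(meta_rows).set_index("barcode")
    meta["pseudotime"] = np.concatenate(pt_values)
    counts = CountMatrix(X, pd.Index(genes), meta.index)
    truth = ScTruth(
        cell_class=meta["cell_class"].copy(),
        deg_effects=effects,
        pseudotime=meta["pseudotime"].copy(),
        markers=markers,
    )
    return counts, meta, truth


@dataclass
class ReferenceQuery:
    """A matched reference/query pair sharing one gene universe."""

    reference: CountMatrix
    reference_labels: pd.Series
    query: CountMatrix
    query_clusters: pd.Series
    query_truth: ScTruth


def simulate_reference_query(
    config: ScSimConfig | None = None,
    label_noise: float = 0.0,
    reference_classes: tuple[str, ...] | None = None,
) -> ReferenceQuery:
    """Reference and query datasets from the same class-generative models.

    The query's cluster labels follow its true classes; ``label_noise``
    reassigns that fraction of cells to a random other cluster.
    ``reference_classes`` restricts the reference to a subset (to test
    behaviour for query classes absent from the reference).
    """
    config = config or ScSimConfig()
    if len(config.classes) < 2:
        raise ValueError("need >= 2 classes")
    ref_cfg = replace(config, samples=(("reference", "control"),))
    qry_cfg = replace(config, samples=(("query", "control"),))
    ref_counts, ref_meta, _ = simulate_counts(ref_cfg, cell_seed=1)
    qry_counts, qry_meta, qry_truth = simulate_counts(qry_cfg, cell_seed=2)
    if reference_classes is not None:
        keep = ref_meta["cell_class"].isin(reference_classes).to_numpy()
        ref_counts = ref_counts.subset_cells(keep)
        ref_meta = ref_meta.loc[keep]
    clusters = qry_meta["cell_class"].copy()
    if label_noise > 0:
        rng = np.random.default_rng(config.seed + 2)
        flip = rng.random(len(clusters)) < label_noise
        others = np.array(config.classes)
        for i in np.flatnonzero(flip):
            choices = others[others != clusters.iloc[i]]
            clusters.iloc[i] = rng.choice(choices)
    return ReferenceQuery(ref_counts, ref_meta["cell_class"].copy(), qry_counts, clusters, qry_truth)
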