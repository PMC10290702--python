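"""Configuration-driven orchestration of the analysis stages.

A YAML (or dict) config selects stages and parameters; ``run_config``
executes the requested stages in dependency order, writes standard-format
outputs into the output directory, and records every output with a
SHA-256 checksum in a manifest JSON alongside the full config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calcium, degstats, groupstats, io, labeltransfer, scqc, trajectory
from .synthdata import CalciumSimConfig, ScSimConfig, simulate_counts, simulate_reference_query, simulate_roi_traces
from .synthdata.calcium_sim import simulate_fov_summaries

log = logging.getLogger("orgscope")

STAGES = [
    "simulate_calcium",
    "analyze_calcium",
    "simulate_sc",
    "qc",
    "deg",
    "overlap",
    "modules",
    "enrich",
    "gsea",
    "label_transfer",
    "trajectory",
    "report",
]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "orgscope_out",
    "stages": STAGES,
    "calcium": {
        "n_fovs_per_genotype": 10,
        "genotypes": {
            "control": {"roi_event_rate": 3.0, "sync_event_rate": 2.0},
            "deletion": {"roi_event_rate": 1.5, "sync_event_rate": 1.0},
        },
        "sim": {},
        "peak_params": {},
        "per_roi_mean": False,
    },
    "sc": {"sim": {}},
    "qc": {"thresholds": {}},
    "deg": {"fdr_threshold": 0.05, "include_gmt": None, "exclude_gmt": None},
    "overlap": {},
    "modules": {"n": 200},
    "enrich": {"disease_gmt": None, "trim": 10.0},
    "gsea": {"gene_set_gmt": None, "n_perm": 1000},
    "label_transfer": {"label_noise": 0.0},
    "trajectory": {"n_perm": 500},
}


class ConfigError(ValueError):
    """A pipeline config failed validation; the message names the field."""


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict)
    cfg = _merge(DEFAULT_CONFIG, raw)
    unknown = [s for s in cfg["stages"] if s not in STAGES]
    if unknown:
        raise ConfigError(f"stages: unknown stage names {unknown}; valid: {STAGES}")
    for key in ("seed",):
        if not isinstance(cfg[key], int):
            raise ConfigError(f"{key}: expected an integer, got {cfg[key]!r}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dataclass_from(cls, overrides: dict, **extra):
    fields = {f.name for f in dataclasses.fields(cls)}
    bad = set(overrides) - fields
    if bad:
        raise ConfigError(f"{cls.__name__}: unknown fields {sorted(bad)}")
    return cls(**{**overrides, **extra})


class _Run:
    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.outdir = Path(cfg["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.outputs: list[dict] = []
        self.state: dict = {}
        seeds = np.random.default_rng(cfg["seed"]).integers(0, 2**31 - 1, size=len(STAGES))
        self.stage_seed = dict(zip(STAGES, (int(s) for s in seeds)))

    def record(self, stage: str, path: Path) -> None:
        self.outputs.append({"stage": stage, "path": str(path), "sha256": _sha256(path)})

    # ------------------------------------------------------------ calcium

    def simulate_calcium(self):
        c = self.cfg["calcium"]
        seed = self.stage_seed["simulate_calcium"]
        all_traces = []
        for gi, (genotype, over) in enumerate(sorted(c["genotypes"].items())):
            sim = _dataclass_from(CalciumSimConfig, {**c["sim"], **over}, seed=seed + gi)
            rng = np.random.default_rng([seed, gi])
            for i in range(c["n_fovs_per_genotype"]):
                fov_cfg = replace(sim, seed=int(rng.integers(0, 2**31 - 1)))
                traces, _ = simulate_roi_traces(fov_cfg)
                traces.fov_id = f"{genotype}_{i}"
                traces.genotype = genotype
                all_traces.append(traces)
        path = self.outdir / "traces.csv"
        io.write_traces_csv(path, all_traces)
        self.state["traces"] = all_traces
        self.record("simulate_calcium", path)
        log.info("simulated %d FOVs -> %s", len(all_traces), path)

    def analyze_calcium(self):
        c = self.cfg["calcium"]
        traces = self.state.get("traces")
        if traces is None:
            path = self.outdir / "traces.csv"
            if not path.exists():
                raise ConfigError("analyze_calcium: no traces in memory and missing traces.csv; run simulate_calcium first")
            traces = io.read_traces_csv(path)
        params = _dataclass_from(calcium.PeakParams, c["peak_params"])
        summaries = [calcium.analyze_fov(t, params, per_roi_mean=c["per_roi_mean"]) for t in traces]
        df = calcium.summaries_to_frame(summaries)
        path = self.outdir / "fov_summary.csv"
        df.to_csv(path, index=False)
        self.record("analyze_calcium", path)
        genotypes = sorted(df["genotype"].unique())
        comparisons = {}
        if len(genotypes) == 2:
            a, b = genotypes
            for metric in ("frequency_per_min", "amplitude_mean_dff", "sync_rate_per_min"):
                res = groupstats.t_test_two_sided(
                    df.loc[df["genotype"] == a, metric], df.loc[df["genotype"] == b, metric]
                )
                comparisons[metric] = {
                    "test": res.test,
                    "groups": [a, b],
                    "t": res.statistic,
                    "df": res.df,
                    "p": res.p_value,
                }
        cpath = self.outdir / "calcium_comparisons.json"
        cpath.write_text(json.dumps(comparisons, indent=1))
        self.record("analyze_calcium", cpath)
        self.state["fov_summary"] = df

    # ------------------------------------------------------------ single cell

    def simulate_sc(self):
        c = self.cfg["sc"]
        sim = _dataclass_from(ScSimConfig, c["sim"], seed=self.stage_seed["simulate_sc"])
        counts, meta, truth = simulate_counts(sim)
        d = self.outdir / "sc_counts"
        scqc.write_counts_dir(d, counts, meta)
        truth_path = self.outdir / "sc_truth.json"
        truth_path.write_text(
            json.dumps({"deg_effects": truth.deg_effects, "markers": truth.markers})
        )
        for p in ("matrix.mtx", "features.tsv", "barcodes.tsv", "metadata.csv"):
            self.record("simulate_sc", d / p)
        self.record("simulate_sc", truth_path)
        self.state.update(counts=counts, meta=meta, truth=truth)

    def _require_counts(self):
        if "counts" not in self.state:
            d = self.outdir / "sc_counts"
            if not (d / "matrix.mtx").exists():
                raise ConfigError("qc: no counts in memory and missing sc_counts/; run simulate_sc first")
            counts, meta = scqc.read_counts_dir(d)
            self.state.update(counts=counts, meta=meta)

    def qc(self):
        self._require_counts()
        counts, meta = self.state["counts"], self.state["meta"]
        thr = _dataclass_from(scqc.QcThresholds, self.cfg["qc"]["thresholds"])
        metrics = scqc.compute_cell_metrics(counts, "MT-")
        keep, report = scqc.apply_qc(metrics, thr)
        kept = counts.subset_cells(keep.to_numpy())
        norm = scqc.cpm_log_normalize(kept)
        mpath = self.outdir / "qc_keep_mask.csv"
        keep.to_csv(mpath)
        rpath = self.outdir / "qc_report.json"
        rpath.write_text(json.dumps(report, indent=1))
        self.record("qc", mpath)
        self.record("qc", rpath)
        self.state.update(
            counts_kept=kept,
            meta_kept=meta.loc[keep.to_numpy()],
            norm=pd.DataFrame(norm, index=kept.genes, columns=kept.barcodes),
        )
        log.info("QC kept %d / %d cells", report["n_kept"], report["n_input"])

    def _require_norm(self):
        if "norm" not in self.state:
            self.qc()

    def _load_gmt(self, field: str, path_value):
        if path_value is None:
            return None
        p = Path(path_value)
        if not p.exists():
            raise ConfigError(f"{field}: gene-set file not found: {p}")
        return degstats.read_gmt(p)

    def deg(self):
        self._require_norm()
        c = self.cfg["deg"]
        norm, meta = self.state["norm"], self.state["meta_kept"]
        include = self._load_gmt("deg.include_gmt", c["include_gmt"])
        exclude = self._load_gmt("deg.exclude_gmt", c["exclude_gmt"])
        deg_lists = {}
        tables = {}
        for cls in sorted(meta["cell_class"].unique()):
            try:
                table = degstats.wilcoxon_deg(
                    norm,
                    meta["genotype"].to_numpy(),
                    cell_classes=meta["cell_class"].to_numpy(),
                    restrict_class=cls,
                    fdr_threshold=c["fdr_threshold"],
                )
            except ValueError as e:
                log.warning("skipping class %s: %s", cls, e)
                continue
            tables[cls] = table
            sig = list(table.index[table["significant"]])
            if include or exclude:
                sig = degstats.filter_degs_go(sig, include, exclude)
            deg_lists[cls] = set(sig)
            path = self.outdir / f"deg_{cls}.csv"
            table.to_csv(path)
            self.record("deg", path)
        self.state.update(deg_lists=deg_lists, deg_tables=tables)

    def _require_degs(self):
        if "deg_lists" not in self.state:
            self.deg()

    def overlap(self):
        self._require_degs()
        norm = self.state["norm"]
        df = degstats.overlap_significance_matrix(self.state["deg_lists"], len(norm.index))
        path = self.outdir / "overlap_matrix.csv"
        df.to_csv(path, index=False)
        self.record("overlap", path)

    def modules(self):
        self._require_norm()
        mods = degstats.top_modules(
            self.state["norm"], self.state["meta_kept"]["cell_class"], n=self.cfg["modules"]["n"]
        )
        path = self.outdir / "modules.json"
        path.write_text(json.dumps(mods, indent=1))
        self.record("modules", path)

    def enrich(self):
        self._require_degs()
        sets = self._load_gmt("enrich.disease_gmt", self.cfg["enrich"]["disease_gmt"])
        if sets is None:
            raise ConfigError("enrich.disease_gmt: a disease gene-set GMT path is required")
        frames = []
        for cls, deg in self.state["deg_lists"].items():
            df = degstats.disease_enrichment(
                deg, sets, len(self.state["norm"].index), trim=self.cfg["enrich"]["trim"]
            )
            df.insert(0, "deg_list", cls)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        path = self.outdir / "disease_enrichment.csv"
        out.to_csv(path, index=False)
        self.record("enrich", path)

    def gsea(self):
        self._require_degs()
        sets = self._load_gmt("gsea.gene_set_gmt", self.cfg["gsea"]["gene_set_gmt"])
        if sets is None:
            raise ConfigError("gsea.gene_set_gmt: a gene-set GMT path is required")
        results = {}
        seed = self.stage_seed["gsea"]
        for cls, table in self.state["deg_tables"].items():
            # default ranking metric: signed -log10(p) x sign(log2fc)
            rank = pd.Series(
                -np.log10(np.clip(table["p_value"], 1e-300, None)) * np.sign(table["log2fc"]),
                index=table.index,
            )
            results[cls] = {
                name: degstats.prerank_gsea(rank, s, n_perm=self.cfg["gsea"]["n_perm"], seed=seed)
                for name, s in sets.items()
            }
        path = self.outdir / "gsea.json"
        path.write_text(json.dumps(results, indent=1))
        self.record("gsea", path)

    def label_transfer(self):
        c = self.cfg["label_transfer"]
        sim = _dataclass_from(ScSimConfig, self.cfg["sc"]["sim"], seed=self.stage_seed["label_transfer"])
        pair = simulate_reference_query(sim, label_noise=c["label_noise"])
        ref_norm = pd.DataFrame(
            scqc.cpm_log_normalize(pair.reference), index=pair.reference.genes, columns=pair.reference.barcodes
        )
        qry_norm = pd.DataFrame(
            scqc.cpm_log_normalize(pair.query), index=pair.query.genes, columns=pair.query.barcodes
        )
        model = labeltransfer.train_reference(ref_norm, pair.reference_labels)
        scores = labeltransfer.predict_scores(qry_norm, model)
        cluster_scores = labeltransfer.aggregate_cluster_scores(scores, pair.query_clusters)
        path = self.outdir / "cluster_scores.csv"
        cluster_scores.to_csv(path)
        self.record("label_transfer", path)
        argmax = cluster_scores.idxmax(axis=1)
        acc = float(np.mean([c == t for c, t in zip(argmax.index, argmax)]))
        apath = self.outdir / "label_transfer_summary.json"
        apath.write_text(json.dumps({"cluster_argmax_accuracy": acc, "assignments": dict(argmax)}))
        self.record("label_transfer", apath)

    def trajectory(self):
        if "meta" not in self.state:
            self._require_counts()
        meta = self.state["meta"]
        groups = {g: meta.loc[meta["genotype"] == g, "pseudotime"].to_numpy() for g in sorted(meta["genotype"].unique())}
        curves = trajectory.density_curves(groups)
        frames = [
            pd.DataFrame({"group": k, "grid": c.grid, "density": c.density, "bandwidth": c.bandwidth})
            for k, c in curves.items()
        ]
        path = self.outdir / "pseudotime_density.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        self.record("trajectory", path)
        if len(groups) == 2:
            (a, va), (b, vb) = groups.items()
            div = trajectory.genotype_divergence(
                va, vb, n_perm=self.cfg["trajectory"]["n_perm"], seed=self.stage_seed["trajectory"]
            )
            dpath = self.outdir / "pseudotime_divergence.json"
            dpath.write_text(json.dumps({"groups": [a, b], **div}))
            self.record("trajectory", dpath)

    def report(self):
        path = self.outdir / "manifest.json"
        manifest = {"config": self.cfg, "seed": self.cfg["seed"], "outputs": self.outputs}
        path.write_text(json.dumps(manifest, indent=1, default=str))
        return manifest


def run_config(config) -> dict:
    """Execute the configured stages in order and return the manifest."""
    cfg = load_config(config)
    run = _Run(cfg)
    for stage in STAGES:
        if stage in cfg["stages"] and stage != "report":
            log.info("stage: %s", stage)
            getattr(run, stage)()
    return run.report()
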