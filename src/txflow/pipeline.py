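"""End-to-end pipeline driver.

Stage order follows the analysis design: spatial track
``qc -> cluster -> annotate -> deg-spatial``; single-nucleus track
``qc -> cluster -> subtype -> deg-sn -> tf -> enrich``. Every stage
writes plain-text outputs under the configured output directory and is
recorded (with checksums and seeds) in a JSON run manifest. With
``resume=True`` a stage whose outputs already exist is reloaded instead
of recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from txflow import __version__, clustering, scstats
from txflow.annotation import (annotate_clusters, binarize_abundance,
                               estimate_abundance)
from txflow.consensus import PseudobulkDesign, run_consensus
from txflow.data import (ConfigError, ExpressionDataset, read_dataset,
                         read_gmt, write_dataset)
from txflow.qc import (QC_PROFILES, compute_cdr, filter_dataset,
                       normalize_log1p, qc_report, select_hvg)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``)."""

    out_dir: Path
    spatial: dict | None = None
    snrna: dict | None = None
    resume: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "out_dir" not in raw:
            raise ConfigError("config must declare out_dir")
        cfg = cls(out_dir=Path(raw["out_dir"]),
                  spatial=raw.get("spatial"),
                  snrna=raw.get("snrna"),
                  resume=bool(raw.get("resume", False)))
        for track in (cfg.spatial, cfg.snrna):
            if track is None:
                continue
            ds_path = Path(track["dataset"])
            if not ds_path.exists():
                raise ConfigError(f"dataset path does not exist: {ds_path}")
            for key in ("signatures", "region_map", "regulons", "gene_sets"):
                p = track.get(key)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"{key} path does not exist: {p}")
        return cfg

    def raw(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "spatial": self.spatial,
            "snrna": self.snrna,
            "resume": self.resume,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    stages: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.stages[stage] = {
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {str(p): _sha256(p) for p in outputs},
        }

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "version": self.version,
                "config_hash": self.config_hash,
                "seeds": self.seeds,
                "stages": self.stages,
            }, fh, indent=2, sort_keys=True)


def _cluster_dataset(ds: ExpressionDataset, params: dict,
                     use_spatial: bool) -> np.ndarray:
    norm = normalize_log1p(ds)
    n_hvg = min(int(params.get("n_hvg", 2000)), ds.n_genes)
    hvgs = select_hvg(ds, n_hvg).index
    emb = clustering.latent_embed(norm, hvgs,
                                  d=min(int(params.get("n_pcs", 30)),
                                        len(hvgs), ds.n_obs - 1))
    g_expr = clustering.expression_connectivities(
        emb, k=int(params.get("k_expr", 15)))
    if use_spatial:
        coords = ds.obs[["x", "y"]].to_numpy()
        g_spa = clustering.spatial_adjacency(
            coords, k=int(params.get("k_spatial", 6)))
        g = clustering.fuse_graphs(
            g_expr, g_spa,
            clustering.FusionWeights(float(params.get("alpha_expr", 0.8))))
    else:
        g = g_expr
    return clustering.leiden_cluster(
        g, resolution=float(params.get("resolution", 0.8)),
        seed=int(params.get("seed", 0)))


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the configured tracks; returns the run manifest (also
    written to ``out_dir/manifest.json``)."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(cfg.raw(), sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(version=__version__, config_hash=cfg_hash)
    if cfg.spatial is not None:
        _run_spatial_track(cfg, manifest)
    if cfg.snrna is not None:
        _run_snrna_track(cfg, manifest)
    manifest.write(cfg.out_dir / "manifest.json")
    return manifest


def _stage_done(cfg: PipelineConfig, paths: list[Path]) -> bool:
    return cfg.resume and all(p.exists() for p in paths)


def _run_spatial_track(cfg: PipelineConfig, manifest: RunManifest) -> None:
    track = cfg.spatial
    out = cfg.out_dir / "spatial"
    out.mkdir(parents=True, exist_ok=True)
    profile = QC_PROFILES[track.get("qc_profile", "spatial")]
    cl = track.get("cluster", {})
    manifest.seeds["spatial_cluster"] = int(cl.get("seed", 0))

    # --- qc
    qc_dir = out / "qc"
    if _stage_done(cfg, [qc_dir / "matrix.mtx", out / "qc_report.tsv"]):
        ds = read_dataset(qc_dir)
    else:
        raw = read_dataset(track["dataset"])
        qc_report(raw, profile).to_csv(out / "qc_report.tsv", sep="\t")
        ds = filter_dataset(raw, profile)
        write_dataset(ds, qc_dir)
        manifest.record("spatial/qc", [qc_dir / "matrix.mtx",
                                       out / "qc_report.tsv"])

    # --- cluster
    labels_path = out / "clusters.tsv"
    if _stage_done(cfg, [labels_path]):
        labels = pd.read_csv(labels_path, sep="\t",
                             index_col=0)["cluster"].to_numpy()
    else:
        labels = _cluster_dataset(ds, cl, use_spatial=True)
        pd.DataFrame({"cluster": labels}, index=ds.obs_ids).to_csv(
            labels_path, sep="\t", index_label="obs_id")
        manifest.record("spatial/cluster", [labels_path])

    # --- annotate
    ann = track.get("annotate")
    region_col = track.get("deg", {}).get("group_col", "region_assigned")
    regions_path = out / "regions.tsv"
    if ann is not None:
        if _stage_done(cfg, [regions_path]):
            assigned = pd.read_csv(regions_path, sep="\t",
                                   index_col=0)["region"]
        else:
            sig = pd.read_csv(ann["signatures"], sep="\t", index_col=0)
            with open(ann["region_map"]) as fh:
                region_map = yaml.safe_load(fh)
            ab = estimate_abundance(ds, sig)
            binary = binarize_abundance(ab, float(ann.get("quantile", 0.99)))
            enr = annotate_clusters(binary, labels, region_map,
                                    float(ann.get("fdr", 0.05)))
            ab.values.to_csv(out / "abundance.tsv", sep="\t")
            enr.table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            assigned = pd.Series(
                [enr.assignments[int(c)] for c in labels],
                index=ds.obs_ids, name="region")
            assigned.to_frame().to_csv(regions_path, sep="\t",
                                       index_label="obs_id")
            manifest.record("spatial/annotate", [
                out / "abundance.tsv", out / "enrichment.tsv", regions_path,
            ])
        ds.obs[region_col] = assigned.to_numpy()
    elif region_col not in ds.obs.columns:
        raise ConfigError("no annotate stage configured and obs lacks "
                          f"column {region_col!r}")

    # --- deg-spatial
    deg = track.get("deg", {})
    design = PseudobulkDesign(
        group_col=region_col,
        n_splits=int(deg.get("n_splits", 2)),
        min_spots=int(deg.get("min_spots", 10)),
        seed=int(deg.get("seed", 0)),
    )
    manifest.seeds["spatial_deg"] = design.seed
    results = run_consensus(
        ds, design,
        R=int(deg.get("repeats", 100)),
        consensus=float(deg.get("consensus", 0.8)),
        padj_max=float(deg.get("padj", 0.05)),
        lfc_min=float(deg.get("lfc", 0.1)),
        min_reps=int(deg.get("min_reps", 3)),
    )
    outputs = []
    for grp, res in results.items():
        path = out / f"deg_{grp}.tsv"
        res.table.to_csv(path, sep="\t", index_label="gene")
        outputs.append(path)
    manifest.record("spatial/deg", outputs)


def _run_snrna_track(cfg: PipelineConfig, manifest: RunManifest) -> None:
    track = cfg.snrna
    out = cfg.out_dir / "snrna"
    out.mkdir(parents=True, exist_ok=True)
    profile = QC_PROFILES[track.get("qc_profile", "snrna")]
    cl = track.get("cluster", {})
    manifest.seeds["snrna_cluster"] = int(cl.get("seed", 0))

    qc_dir = out / "qc"
    if _stage_done(cfg, [qc_dir / "matrix.mtx"]):
        ds = read_dataset(qc_dir)
    else:
        raw = read_dataset(track["dataset"])
        qc_report(raw, profile).to_csv(out / "qc_report.tsv", sep="\t")
        ds = filter_dataset(raw, profile)
        write_dataset(ds, qc_dir)
        manifest.record("snrna/qc", [qc_dir / "matrix.mtx",
                                     out / "qc_report.tsv"])

    norm = normalize_log1p(ds)

    labels_path = out / "clusters.tsv"
    if _stage_done(cfg, [labels_path]):
        labels = pd.read_csv(labels_path, sep="\t",
                             index_col=0)["cluster"].to_numpy()
    else:
        labels = _cluster_dataset(ds, {**cl,
                                       "resolution": cl.get("resolution", 1.0)},
                                  use_spatial=False)
        pd.DataFrame({"cluster": labels}, index=ds.obs_ids).to_csv(
            labels_path, sep="\t", index_label="obs_id")
        manifest.record("snrna/cluster", [labels_path])

    # --- subtype assignment (optional; needs marker map)
    markers = track.get("subtype_markers")
    groupby = track.get("deg", {}).get("groupby", "cell_type")
    if markers is not None:
        subtypes, _cmap = clustering.assign_inhibitory_subtypes(
            norm, labels, markers)
        ds.obs["subtype_assigned"] = subtypes.to_numpy()
        path = out / "subtypes.tsv"
        subtypes.to_frame().to_csv(path, sep="\t", index_label="obs_id")
        manifest.record("snrna/subtype", [path])
        if groupby == "subtype_assigned" or groupby not in ds.obs.columns:
            groupby = "subtype_assigned"
    if groupby not in ds.obs.columns:
        raise ConfigError(f"obs lacks grouping column {groupby!r}")

    # --- hurdle DEG
    deg = track.get("deg", {})
    results = scstats.hurdle_deg(
        ds, norm, ds.obs[groupby],
        min_frac=float(deg.get("min_frac", 0.05)),
        padj_max=float(deg.get("padj", 0.05)),
        lfc_min=float(deg.get("lfc", 0.1)),
    )
    outputs = []
    for ct, res in results.items():
        safe = str(ct).replace("/", "_")
        path = out / f"deg_{safe}_lrt.tsv"
        res.lrt.to_csv(path, sep="\t", index_label="gene")
        outputs.append(path)
        for cname, tbl in res.contrasts.items():
            path = out / f"deg_{safe}_{cname}.tsv"
            tbl.to_csv(path, sep="\t", index_label="gene")
            outputs.append(path)
    manifest.record("snrna/deg", outputs)

    # --- TF activity
    tf = track.get("tf")
    if tf is not None:
        regulons = read_gmt(tf["regulons"])
        ras = scstats.aucell_matrix(
            norm, regulons, float(tf.get("top_fraction", 0.05)))
        ras.to_csv(out / "ras.tsv", sep="\t", index_label="obs_id")
        outputs = [out / "ras.tsv"]
        cell_type = tf.get("cell_type")
        targets = ([cell_type] if cell_type
                   else list(pd.unique(ds.obs[groupby])))
        for ct in targets:
            for a, b in (("HC", "CD"), ("HC", "TN"), ("CD", "TN")):
                try:
                    tbl = scstats.differential_tf(
                        ras, ds.obs[groupby], ds.obs["condition"],
                        ct, a, b, alpha=float(tf.get("alpha", 0.01)))
                except Exception as exc:  # degenerate groups are skipped
                    logger.warning("tf %s %s_vs_%s skipped: %s", ct, b, a, exc)
                    continue
                safe = str(ct).replace("/", "_")
                path = out / f"tf_{safe}_{b}_vs_{a}.tsv"
                tbl.to_csv(path, sep="\t")
                outputs.append(path)
        manifest.record("snrna/tf", outputs)

    # --- ORA
    enr = track.get("enrich")
    if enr is not None:
        gene_sets = read_gmt(enr["gene_sets"])
        outputs = []
        universe = list(ds.gene_ids)
        for ct, res in results.items():
            for cname, tbl in res.contrasts.items():
                query = list(tbl.index[tbl["sig"]])
                if not query:
                    continue
                res_ora = scstats.ora(query, universe, gene_sets)
                safe = str(ct).replace("/", "_")
                path = out / f"ora_{safe}_{cname}.tsv"
                res_ora.to_csv(path, sep="\t")
                outputs.append(path)
        manifest.record("snrna/enrich", outputs)
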