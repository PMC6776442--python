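"""Stage orchestration behind one YAML configuration and one entry point.

Stages run in the canonical order ``simulate -> select -> barcodes ->
count -> enrich -> power``; each stage is enabled by the presence of its
config section (or an explicit ``stages`` list). A run writes a
reproducibility manifest (package/library versions, master seed, per-stage
derived seeds, input file hashes, row counts, timings) that makes reruns
byte-identical. Stage outputs are written to temporary ``.partial`` files
and renamed only on stage success, so a failed stage leaves its partial
outputs inspectable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .barcodes import (
    BarcodeSet,
    assign_barcodes,
    design_barcodes,
    read_barcodes_tsv,
    read_gre_map_tsv,
    validate_barcode_set,
    write_barcodes_tsv,
    write_gre_map_tsv,
)
from .errors import ConfigError, ValidationError
from .quant import (
    AssignmentPolicy,
    CellByFeatureMatrix,
    aggregate_gre,
    count_umis,
    library_complexity,
    read_labels_tsv,
    read_reads_tsv,
    write_labels_tsv,
    write_reads_tsv,
)
from .selection import (
    SelectionConfig,
    read_bed,
    read_conservation_tsv,
    read_signal_tsv,
    select_gre_panel,
    PeakTable,
)
from .simulate import ScreenTruth, simulate_screen
from .stats import (
    EnrichmentConfig,
    barcode_consistency,
    detection_rates,
    nb_lrt_test,
    screen_folds,
    shuffle_null,
    subsample_power,
)

STAGE_ORDER = ("simulate", "select", "barcodes", "count", "enrich", "power")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write(path: Path, writer) -> None:
    """Write via a .partial temp file, renaming on success."""
    tmp = path.with_name(path.name + ".partial")
    writer(tmp)
    tmp.replace(path)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return cfg


def run_pipeline(config: dict, outdir, seed: int | None = None) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0) if seed is None else seed)
    requested = config.get("stages")
    stages = [
        s
        for s in STAGE_ORDER
        if (requested is not None and s in requested)
        or (requested is None and s in config)
    ]
    if not stages:
        raise ConfigError("no stages configured")

    ss = np.random.SeedSequence(master_seed)
    stage_seeds = {
        s: int(child.generate_state(1)[0] % 2**31)
        for s, child in zip(STAGE_ORDER, ss.spawn(len(STAGE_ORDER)))
    }
    manifest: dict = {
        "pesca_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": master_seed,
        "stage_seeds": {s: stage_seeds[s] for s in stages},
        "stages": {},
        "inputs": {},
    }
    state: dict = {}

    for stage in stages:
        t0 = time.time()
        try:
            counts = _run_stage(stage, config.get(stage, {}) or {}, outdir,
                                stage_seeds[stage], state, manifest)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, outdir)
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "status": "ok",
            "seconds": round(time.time() - t0, 3),
            **counts,
        }

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _record_input(manifest: dict, path) -> Path:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    manifest["inputs"][str(path)] = _sha256(path)
    return path


def _run_stage(stage, cfg, outdir, seed, state, manifest) -> dict:
    if stage == "simulate":
        truth = ScreenTruth(**cfg.get("truth", {}))
        n_cells = int(cfg.get("n_cells", 1000))
        scr = simulate_screen(truth, n_cells, seed=seed)
        _atomic_write(outdir / "reads.tsv", lambda p: write_reads_tsv(scr.reads, p))
        _atomic_write(outdir / "labels.tsv", lambda p: write_labels_tsv(scr.labels, p))
        _atomic_write(outdir / "gremap.tsv", lambda p: write_gre_map_tsv(scr.gre_map, p))
        _atomic_write(outdir / "barcodes.tsv", lambda p: write_barcodes_tsv(scr.barcode_set, p))
        _atomic_write(
            outdir / "truth.yaml",
            lambda p: Path(p).write_text(yaml.safe_dump(asdict(truth))),
        )
        state.update(
            reads=scr.reads, labels=scr.labels, barcode_set=scr.barcode_set,
            gre_map=scr.gre_map,
        )
        return {"n_reads": len(scr.reads), "n_cells": n_cells}

    if stage == "select":
        for key in ("peaks", "signal", "conservation", "control_scores"):
            if key not in cfg:
                raise ConfigError(f"select stage requires {key!r}")
        intervals = read_bed(_record_input(manifest, cfg["peaks"]))
        signal = read_signal_tsv(_record_input(manifest, cfg["signal"]))
        conservation = read_conservation_tsv(_record_input(manifest, cfg["conservation"]))
        controls = read_conservation_tsv(_record_input(manifest, cfg["control_scores"]))
        peaks = PeakTable(
            intervals=intervals, signal=signal, conservation=conservation
        )
        sel_cfg = SelectionConfig(**cfg.get("config", {}))
        panel = select_gre_panel(peaks, controls.to_numpy(), sel_cfg)
        _atomic_write(
            outdir / "panel.tsv", lambda p: panel.to_csv(p, sep="\t")
        )
        by_id = {iv.id: iv for iv in intervals}
        _atomic_write(
            outdir / "panel.bed",
            lambda p: Path(p).write_text(
                "".join(
                    f"{by_id[i].chrom}\t{by_id[i].start}\t{by_id[i].end}\t{i}"
                    f"\t{panel.loc[i,'score']:.6g}\t.\n"
                    for i in panel.index
                )
            ),
        )
        state["panel"] = panel
        return {"n_selected": len(panel)}

    if stage == "barcodes":
        bset = design_barcodes(
            length=int(cfg.get("length", 10)),
            min_dist=int(cfg.get("min_dist", 3)),
            n_required=int(cfg.get("n", 861)),
            metric=cfg.get("metric", "levenshtein"),
            seed=seed if cfg.get("seed") is None else int(cfg["seed"]),
        )
        report = validate_barcode_set(bset)
        if not report.valid:
            raise ValidationError("designed barcode set failed validation")
        _atomic_write(outdir / "barcodes.tsv", lambda p: write_barcodes_tsv(bset, p))
        state["barcode_set"] = bset
        if "gre_ids" in cfg or "panel" in state:
            gre_ids = cfg.get("gre_ids") or list(state["panel"].index)
            gmap = assign_barcodes(
                gre_ids, bset, per_gre=int(cfg.get("per_gre", 3)), seed=seed
            )
            _atomic_write(outdir / "gremap.tsv", lambda p: write_gre_map_tsv(gmap, p))
            state["gre_map"] = gmap
        return {"n_barcodes": len(bset)}

    if stage == "count":
        reads = state.get("reads")
        if reads is None:
            if "reads" not in cfg:
                raise ConfigError("count stage requires 'reads' (no simulate stage ran)")
            reads = read_reads_tsv(_record_input(manifest, cfg["reads"]))
        bset = state.get("barcode_set")
        if bset is None:
            if "barcodes" not in cfg:
                raise ConfigError("count stage requires 'barcodes'")
            bset = read_barcodes_tsv(_record_input(manifest, cfg["barcodes"]))
        gmap = state.get("gre_map")
        if gmap is None and "map" in cfg:
            gmap = read_gre_map_tsv(_record_input(manifest, cfg["map"]))
            state["gre_map"] = gmap
        policy = AssignmentPolicy(
            max_mismatch=int(cfg.get("max_mismatch", 1)),
            uniqueness_radius=int(cfg.get("uniqueness_radius", 2)),
        )
        labels = state.get("labels")
        whitelist = labels["cell_barcode"].tolist() if labels is not None else None
        mat, qc = count_umis(reads, bset, policy, cell_whitelist=whitelist)
        mat.save(outdir, prefix="counts_barcode")
        _atomic_write(outdir / "qc.json", lambda p: qc.write_json(p))
        state["barcode_matrix"] = mat
        if gmap is not None:
            gre_mat = aggregate_gre(mat, gmap)
            gre_mat.save(outdir, prefix="counts_gre")
            state["gre_matrix"] = gre_mat
            complexity = library_complexity(mat, bset, gmap)
            _atomic_write(
                outdir / "complexity.json",
                lambda p: Path(p).write_text(
                    json.dumps(complexity.to_dict(), indent=2) + "\n"
                ),
            )
        return {"n_cells": len(mat.cells), "n_umis": qc.n_umis}

    if stage == "enrich":
        mat, gre_mat, labels, gmap = _need_counts(cfg, state, manifest, outdir)
        target = cfg.get("target", "Sst")
        e_cfg = EnrichmentConfig(**cfg.get("config", {}), seed=seed)
        bc_folds, gre_folds = screen_folds(mat, labels, gmap, target, e_cfg)
        consistency = barcode_consistency(np.log2(bc_folds), gmap)
        null = shuffle_null(np.log2(bc_folds), gmap, e_cfg.n_shuffles, seed=seed)
        table = nb_lrt_test(gre_mat, labels, target, e_cfg)
        table["fold"] = gre_folds.loc[table.index]
        table["log2_fold"] = np.log2(table["fold"])
        table["enriched"] = (table["q"] < e_cfg.fdr_threshold) & (table["fold"] > 1)
        _atomic_write(outdir / "enrichment.tsv", lambda p: table.to_csv(p, sep="\t"))
        _atomic_write(
            outdir / "consistency.tsv", lambda p: consistency.to_csv(p, sep="\t", index=False)
        )
        _atomic_write(
            outdir / "shuffle_null.json",
            lambda p: Path(p).write_text(json.dumps(null.to_dict(), indent=2) + "\n"),
        )
        state["enrichment"] = table
        return {"n_features": len(table), "n_enriched": int(table["enriched"].sum())}

    if stage == "power":
        mat, gre_mat, labels, gmap = _need_counts(cfg, state, manifest, outdir)
        target = cfg.get("target", "Sst")
        e_cfg = EnrichmentConfig(**cfg.get("config", {}), seed=seed)
        features = cfg.get("features")
        gm = gre_mat
        sf_values = None
        if features:
            # size factors from the full library, not the tested subset
            from .stats import compute_size_factors

            sf_values = compute_size_factors(gre_mat.to_dense(), e_cfg.size_factors)
            idx = [gm.features.index(f) for f in features]
            gm = CellByFeatureMatrix(
                cells=gm.cells, features=list(features),
                counts=gm.counts[:, idx],
            )
        report = subsample_power(
            gm, labels, target,
            probabilities=cfg.get("probabilities", [0.5, 0.25, 0.125, 0.0625]),
            replicates=int(cfg.get("replicates", 10)),
            seed=seed, config=e_cfg, size_factors_values=sf_values,
        )
        _atomic_write(outdir / "power.tsv", lambda p: report.to_csv(p, sep="\t", index=False))
        rates = detection_rates(report)
        _atomic_write(outdir / "power_rates.tsv", lambda p: rates.to_csv(p, sep="\t", index=False))
        return {"n_rows": len(report)}

    raise ConfigError(f"unknown stage {stage!r}")


def _need_counts(cfg, state, manifest, outdir):
    """Resolve count matrices, labels and GRE map for enrich/power stages."""
    mat = state.get("barcode_matrix")
    gre_mat = state.get("gre_matrix")
    labels = state.get("labels")
    gmap = state.get("gre_map")
    if mat is None:
        if "counts" not in cfg:
            raise ConfigError("stage requires 'counts' directory (no count stage ran)")
        mat = CellByFeatureMatrix.load(cfg["counts"], prefix="counts_barcode")
        gre_mat = CellByFeatureMatrix.load(cfg["counts"], prefix="counts_gre")
    if labels is None:
        if "labels" not in cfg:
            raise ConfigError("stage requires 'labels'")
        labels = read_labels_tsv(_record_input(manifest, cfg["labels"]))
    if gmap is None:
        if "map" not in cfg:
            raise ConfigError("stage requires 'map'")
        gmap = read_gre_map_tsv(_record_input(manifest, cfg["map"]))
    if gre_mat is None:
        gre_mat = aggregate_gre(mat, gmap)
    return mat, gre_mat, labels, gmap
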