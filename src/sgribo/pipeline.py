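"""End-to-end orchestration from a single YAML config.

A run selects stages (simulate → segment/quantify and/or de/te/classify →
gsea/go, plus tm), executes them in dependency order, and writes a JSON
manifest recording the seed, the parameter values actually applied, every
output file, and per-stage row counts. One global seed is fanned out to
per-stage child seeds by hashing the stage name (CRC-32) into a
SeedSequence, so any stage can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrich, io, melt, riboclass, sgquant, simdata

logger = logging.getLogger(__name__)

__all__ = ["default_config", "load_config", "stage_seed", "run_pipeline"]

STAGES = ("simulate_images", "simulate_counts", "simulate_melt",
          "segment_quantify", "de_te_classify", "gsea", "go", "tm")


def default_config() -> dict:
    """Config with every threshold at its standard default."""
    return {
        "stages": [],
        "outdir": "sgribo_run",
        "seed": 0,
        "images": {"n_fields": 2, "n_cells": 20, "noise_sd": 50.0},
        "counts": {"n_genes": 500, "n_replicates": 3, "dispersion": 0.05,
                   "effect_lfc": 2.0},
        "melt": {"true_tm": 55.0, "steepness": 0.5, "noise_sd": 2.0},
        "segmentation": {
            "rescale_factor": 1.0,
            "nucleus_min_area": 50.0,
            "nucleus_max_area": 5000.0,
            "regularization": 0.05,
            "speckle_radius": 5.0,
            "threshold_mode": "otsu",
            "manual_threshold": None,
            "foci_min_area": 4.0,
            "max_eccentricity": 0.875,
        },
        "classification": {
            "basemean_min": 20.0,
            "padj_rna": 0.01,
            "padj_ribo": 0.05,
            "padj_both": 0.05,
            "padj_te": 0.05,
        },
        "gsea": {"n_perm": 10000, "weight_p": 1.0, "gmt": None},
        "go": {"tpm_threshold": 1.0, "annotation": None, "lengths": None},
        "tm": {"smooth_window": 5},
    }


def load_config(path) -> dict:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Child seed for a stage: SeedSequence over (seed, crc32(stage))."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _hash_outputs(paths) -> str:
    h = hashlib.sha256()
    for p in sorted(map(str, paths)):
        h.update(Path(p).name.encode())
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, seed: int | None = None) -> dict:
    """Execute the selected stages; returns (and writes) the run manifest."""
    cfg = {**default_config(), **config}
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(default_config().get(k), dict):
            cfg[k] = {**default_config()[k], **v}
    seed = int(cfg["seed"] if seed is None else seed)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    manifest = {"seed": seed, "stages": {}, "outputs": [],
                "parameters": {k: cfg[k] for k in
                               ("segmentation", "classification", "gsea",
                                "go", "tm")}}
    outputs: list[Path] = []

    def record(stage, path, n_rows=None):
        outputs.append(Path(path))
        manifest["outputs"].append(str(path))
        manifest["stages"].setdefault(stage, {"files": [], "rows": {}})
        manifest["stages"][stage]["files"].append(str(path))
        if n_rows is not None:
            manifest["stages"][stage]["rows"][Path(path).name] = int(n_rows)

    try:
        if "simulate_images" in stages:
            s = stage_seed(seed, "simulate_images")
            icfg = cfg["images"]
            spec = simdata.FieldSpec(n_cells=int(icfg.get("n_cells", 20)),
                                     noise_sd=float(icfg.get("noise_sd", 50.0)))
            for i in range(int(icfg.get("n_fields", 2))):
                fld = simdata.generate_field(spec, s + i)
                tif = outdir / f"field_{i}.tiff"
                io.write_field_tiff(tif, fld)
                record("simulate_images", tif)
                for name, df in (("cells", fld.truth_cells),
                                 ("foci", fld.truth_foci)):
                    p = outdir / f"field_{i}_truth_{name}.tsv"
                    io.write_table(p, df, index=False)
                    record("simulate_images", p, len(df))

        if "simulate_counts" in stages:
            s = stage_seed(seed, "simulate_counts")
            ccfg = cfg["counts"]
            design = simdata.CountDesign(
                n_genes=int(ccfg.get("n_genes", 500)),
                n_replicates=int(ccfg.get("n_replicates", 3)),
                dispersion=float(ccfg.get("dispersion", 0.05)),
                effect_lfc=float(ccfg.get("effect_lfc", 2.0)),
                seed=s)
            counts, meta, truth = simdata.generate_counts(design)
            for name, df, idx in (("counts", counts, True),
                                  ("metadata", meta.reset_index(), False),
                                  ("truth", truth, True)):
                p = outdir / f"{name}.tsv"
                io.write_table(p, df, index=idx)
                record("simulate_counts", p, len(df))

        if "simulate_melt" in stages:
            s = stage_seed(seed, "simulate_melt")
            mcfg = cfg["melt"]
            curve = simdata.generate_melt_curve(
                float(mcfg.get("true_tm", 55.0)),
                steepness=float(mcfg.get("steepness", 0.5)),
                noise_sd=float(mcfg.get("noise_sd", 2.0)), seed=s)
            p = outdir / "melt_curve.tsv"
            io.write_melt_curve(p, curve)
            record("simulate_melt", p, len(curve.temperature))

        if "segment_quantify" in stages:
            scfg = cfg["segmentation"]
            logger.info("segmentation thresholds: max_eccentricity=%s, "
                        "threshold_mode=%s, foci_min_area=%s",
                        scfg["max_eccentricity"], scfg["threshold_mode"],
                        scfg["foci_min_area"])
            tiffs = sorted(outdir.glob("field_*.tiff"))
            if not tiffs:
                raise FileNotFoundError("segment_quantify: no field_*.tiff in outdir")
            all_cells = []
            for tif in tiffs:
                nuc, rep = io.read_field_tiff(tif)
                cell_table, foci_table, masks = sgquant.quantify_field(
                    nuc, rep,
                    rescale_factor=scfg["rescale_factor"],
                    nucleus_min_area=scfg["nucleus_min_area"],
                    nucleus_max_area=scfg["nucleus_max_area"],
                    regularization=scfg["regularization"],
                    speckle_radius=scfg["speckle_radius"],
                    threshold_mode=scfg["threshold_mode"],
                    manual_threshold=scfg["manual_threshold"],
                    foci_min_area=scfg["foci_min_area"],
                    max_eccentricity=scfg["max_eccentricity"])
                stem = tif.stem
                for kind, mask in masks.items():
                    p = outdir / f"{stem}_mask_{kind}.tiff"
                    io.write_label_mask(p, mask)
                    record("segment_quantify", p)
                for name, df in (("cells", cell_table), ("foci", foci_table)):
                    p = outdir / f"{stem}_{name}.tsv"
                    io.write_table(p, df, index=False)
                    record("segment_quantify", p, len(df))
                cell_table = cell_table.assign(field=stem)
                all_cells.append(cell_table)
            pooled = pd.concat(all_cells, ignore_index=True)
            summary = sgquant.summarize_condition(
                {stem: grp for stem, grp in pooled.groupby("field")},
                condition="synthetic")
            p = outdir / "condition_summary.tsv"
            io.write_table(p, pd.DataFrame([vars(summary)]), index=False)
            record("segment_quantify", p, 1)

        if "de_te_classify" in stages:
            kcfg = cfg["classification"]
            logger.info("classification thresholds: baseMean>%s, padj RNA<%s, "
                        "Ribo<%s, both<%s, TE<%s", kcfg["basemean_min"],
                        kcfg["padj_rna"], kcfg["padj_ribo"], kcfg["padj_both"],
                        kcfg["padj_te"])
            counts = io.read_counts(outdir / "counts.tsv")
            meta = io.read_metadata(outdir / "metadata.tsv")
            cond = sorted(meta["condition"].unique())
            contrast = ("condition", cond[-1], cond[0])
            rna_cols = meta.index[meta["assay"] == "RNA"]
            ribo_cols = meta.index[meta["assay"] == "RIBO"]
            rna = riboclass.nb_wald_test(counts[rna_cols], meta.loc[rna_cols],
                                         contrast)
            ribo = riboclass.nb_wald_test(counts[ribo_cols], meta.loc[ribo_cols],
                                          contrast)
            te = riboclass.te_interaction_test(counts[rna_cols], counts[ribo_cols],
                                               meta.loc[rna_cols],
                                               meta.loc[ribo_cols], contrast)
            th = riboclass.ClassificationThresholds(
                basemean_min=kcfg["basemean_min"], padj_rna=kcfg["padj_rna"],
                padj_ribo=kcfg["padj_ribo"], padj_both=kcfg["padj_both"],
                padj_te=kcfg["padj_te"])
            cls = riboclass.classify_genes(rna, ribo, te, th)
            for name, df in (("de_rna", rna.table), ("de_ribo", ribo.table),
                             ("te", te.table), ("classification", cls)):
                p = outdir / f"{name}.tsv"
                io.write_table(p, df)
                record("de_te_classify", p, len(df))

        if "gsea" in stages:
            s = stage_seed(seed, "gsea")
            gcfg = cfg["gsea"]
            logger.info("GSEA: n_perm=%s, weight_p=%s", gcfg["n_perm"],
                        gcfg["weight_p"])
            ribo_table = io.read_table(outdir / "de_ribo.tsv")
            ranked = enrich.RankedList(ribo_table["log2FC"].dropna())
            if gcfg.get("gmt"):
                sets = io.read_gmt(gcfg["gmt"])
            else:
                # demo set: most translationally repressed decile
                bottom = list(ranked.genes[-max(len(ranked) // 10, 5):])
                sets = [enrich.GeneSet("repressed_decile", frozenset(bottom))]
            res = enrich.preranked_gsea(ranked, sets,
                                        weight_p=float(gcfg["weight_p"]),
                                        n_perm=int(gcfg["n_perm"]), seed=s)
            p = outdir / "gsea.tsv"
            io.write_table(p, res.table)
            record("gsea", p, len(res.table))

        if "go" in stages:
            ocfg = cfg["go"]
            logger.info("GO background: TPM > %s", ocfg["tpm_threshold"])
            counts = io.read_counts(outdir / "counts.tsv")
            meta = io.read_metadata(outdir / "metadata.tsv")
            rna_cols = meta.index[meta["assay"] == "RNA"]
            if ocfg.get("lengths"):
                lengths = io.read_table(ocfg["lengths"]).iloc[:, 0]
            else:
                lengths = pd.Series(1000.0, index=counts.index)
            tpm = enrich.compute_tpm(counts[rna_cols], lengths)
            background = enrich.build_background(tpm, float(ocfg["tpm_threshold"]))
            cls_path = outdir / "classification.tsv"
            if cls_path.exists():
                cls = io.read_table(cls_path)
                study = set(cls.index[cls["label"] == "Buffering up"]) & background
            else:
                study = set()
            if ocfg.get("annotation"):
                annotation = {g.set_id: g.genes for g in io.read_gmt(ocfg["annotation"])}
            else:
                # demo annotation: deciles of the background by gene id
                bg = sorted(background)
                annotation = {f"decile_{i}": bg[i::10] for i in range(10)}
            if study:
                ora = enrich.go_overrepresentation(study, background, annotation)
            else:
                ora = pd.DataFrame(columns=["k", "K", "n", "N", "pval", "padj",
                                            "significant"])
            p = outdir / "go.tsv"
            io.write_table(p, ora)
            record("go", p, len(ora))

        if "tm" in stages:
            tcfg = cfg["tm"]
            curve = io.read_melt_curve(outdir / "melt_curve.tsv")
            est = melt.melt_curve_tm(curve, smooth_window=int(tcfg["smooth_window"]))
            p = outdir / "tm.tsv"
            io.write_table(p, pd.DataFrame([{"tm": est.tm,
                                             "smooth_window": est.smooth_window}]),
                           index=False)
            record("tm", p, 1)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest["content_hash"] = _hash_outputs(outputs) if outputs else ""
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest
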