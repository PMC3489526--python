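"""Staged pipeline orchestration with deterministic, resumable artifacts.

Each stage reads its upstream artifact from the run directory, writes its
own outputs plus a manifest (config hash, seed, package version), and is
skipped on re-run when the manifest matches — unless forced.  All
randomness flows from the single config seed, so two runs with equal
config produce identical CSV outputs.  Between stages the cube travels in
the HDF5 container, not imzML, keeping stage re-entry fast and memory
O(n_pixels x retained channels).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Callable

import numpy as np

from . import __version__
from . import classify as clf
from . import interpretation as interp
from . import io as msio
from . import peaks as pk
from . import preprocess as pp
from . import synthgen
from . import unsupervised as us
from . import viz
from .config import PipelineConfig

__all__ = ["run_stage", "run_all", "run_batch", "STAGES", "StageError"]

log = logging.getLogger("msipipe")

STAGES = ("ingest", "preprocess", "peaks", "segment", "interpret",
          "classify", "report")


class StageError(RuntimeError):
    """A stage cannot run; the message names what is missing."""


def _manifest_path(outdir: Path, stage: str) -> Path:
    return outdir / f"{stage}.manifest.json"


def _write_manifest(outdir: Path, stage: str, digest: str,
                    artifacts: list[str], elapsed: float) -> None:
    _manifest_path(outdir, stage).write_text(json.dumps({
        "stage": stage,
        "config_digest": digest,
        "version": __version__,
        "elapsed_s": round(elapsed, 3),
        "artifacts": artifacts,
    }, indent=2))


def _up_to_date(outdir: Path, stage: str, digest: str) -> bool:
    path = _manifest_path(outdir, stage)
    if not path.exists():
        return False
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise StageError(
            f"manifest for stage '{stage}' is corrupt ({exc}); "
            "re-run with force=True to regenerate"
        ) from exc
    if manifest.get("config_digest") != digest:
        return False
    return all((outdir / a).exists() for a in manifest.get("artifacts", []))


def _require(outdir: Path, artifact: str, produced_by: str) -> Path:
    path = outdir / artifact
    if not path.exists():
        raise StageError(
            f"missing upstream artifact '{artifact}'; run the "
            f"'{produced_by}' stage first"
        )
    return path


# ---- stage bodies -------------------------------------------------------

def _stage_simulate(config: PipelineConfig, outdir: Path) -> list[str]:
    s = config.section("synth")
    spec = synthgen.two_region_spec(
        width=int(s["width"]), height=int(s["height"]),
        noise_cv=float(s["noise_cv"]), baseline=float(s["baseline"]),
        hotspot_fraction=float(s["hotspot_fraction"]), seed=config.seed,
    )
    cube, truth = synthgen.generate_datacube(spec)
    msio.save_container(cube, outdir / "cube.h5")
    truth_doc = {
        "label_names": truth.label_names,
        "region_labels": truth.region_labels.tolist(),
        "peaks": {region: [p.mz for p in plist]
                  for region, plist in truth.peaks.items()},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth_doc))
    return ["cube.h5", "ground_truth.json"]


def _stage_ingest(config: PipelineConfig, outdir: Path) -> list[str]:
    source = config["input"]
    if source is None:
        if (outdir / "cube.h5").exists():   # simulate already provided it
            return ["cube.h5"]
        raise StageError("no input configured; set 'input' or run 'simulate'")
    source = Path(source)
    if source.suffix.lower() == ".h5":
        cube = msio.load_container(source)
    else:
        cube = msio.read_imzml(source)
    msio.save_container(cube, outdir / "cube.h5")
    return ["cube.h5"]


def _stage_preprocess(config: PipelineConfig, outdir: Path) -> list[str]:
    cube = msio.load_container(_require(outdir, "cube.h5", "ingest"))
    bl = config.section("baseline")
    sm = config.section("smoothing")
    nm = config.section("normalization")
    if bl["enabled"]:
        cube = pp.correct_baseline_cube(cube, int(bl["window"]))
    if sm["enabled"]:
        cube = pp.smooth_cube(cube, int(sm["window"]))
    artifacts = ["preprocessed.h5"]
    # exemplary images under both normalizations support the visual choice
    # between TIC and median normalization
    mid = float(cube.axis.values[cube.n_channels // 2])
    for method, fn in (("tic", pp.tic_normalize), ("median", pp.median_normalize)):
        normalized, _ = fn(cube.copy_with())
        img = msio.get_mz_image(normalized, mid, tol=(cube.axis.mz_max - cube.axis.mz_min) / 4)
        name = f"normalization_example_{method}.png"
        viz.render(img, outdir / name)
        artifacts.append(name)
    method = nm["method"]
    if method == "tic":
        cube, _ = pp.tic_normalize(cube, nm["target_scale"])
    elif method == "median":
        cube, _ = pp.median_normalize(cube, nm["target_scale"])
    elif method != "none":
        raise ValueError(f"unknown normalization method '{method}'")
    msio.save_container(cube, outdir / "preprocessed.h5")
    return artifacts


def _stage_peaks(config: PipelineConfig, outdir: Path) -> list[str]:
    cube = msio.load_container(_require(outdir, "preprocessed.h5", "preprocess"))
    p = config.section("peaks")
    consensus = pk.dataset_peaks(
        cube, snr=float(p["snr"]), min_fraction=float(p["min_fraction"]),
        tol=float(p["tol"]), max_peaks_per_spectrum=p["max_per_spectrum"],
        target_range=(50, int(p["target_max"])),
    )
    msio.export_table(
        [{"mz": mz, "presence_fraction": frac, "mean_intensity": mi}
         for mz, frac, mi in zip(consensus.mzs, consensus.presence_fractions,
                                 consensus.mean_intensities)],
        outdir / "consensus_peaks.csv",
        columns=["mz", "presence_fraction", "mean_intensity"],
    )
    return ["consensus_peaks.csv"]


def _load_consensus(outdir: Path) -> pk.ConsensusPeakList:
    import pandas as pd
    table = pd.read_csv(_require(outdir, "consensus_peaks.csv", "peaks"))
    return pk.ConsensusPeakList(table["mz"].to_numpy(),
                                table["presence_fraction"].to_numpy(),
                                table["mean_intensity"].to_numpy())


def _stage_segment(config: PipelineConfig, outdir: Path) -> list[str]:
    cube = msio.load_container(_require(outdir, "preprocessed.h5", "preprocess"))
    consensus = _load_consensus(outdir)
    s = config.section("segment")
    tol = float(config.section("peaks")["tol"])
    features = us.peak_features(cube, consensus, tol=tol)
    k, seed = int(s["k"]), config.seed
    method = s["method"]
    if method == "kmeans":
        segmap = us.kmeans_segment(features, cube, k, seed=seed)
    elif method == "hierarchical":
        segmap = us.hierarchical_segment(features, cube, k,
                                         linkage=s["linkage"],
                                         pca_variance=float(s["pca_variance"]))
    elif method == "denoise":
        segmap = us.denoise_then_cluster(features, cube, k,
                                         denoise_strength=float(s["denoise_strength"]),
                                         seed=seed)
    elif method == "spatial":
        segmap = us.spatially_aware_segment(features, cube, k,
                                            radius=float(s["radius"]),
                                            adaptive=bool(s["adaptive"]), seed=seed)
    else:
        raise ValueError(f"unknown segmentation method '{method}'")
    msio.export_table(
        [{"x": int(x), "y": int(y), "label": int(lab)}
         for (x, y), lab in zip(segmap.coords, segmap.labels)],
        outdir / "segmentation.csv", columns=["x", "y", "label"],
    )
    _render_segmentation(segmap, outdir / "segmentation.png")
    return ["segmentation.csv", "segmentation.png"]


def _render_segmentation(segmap: us.SegmentationMap, path: Path) -> None:
    import matplotlib.pyplot as plt
    grid = segmap.label_grid()
    rgb = np.ones(grid.shape + (3,)) * viz.BACKGROUND_RGB
    for c in range(1, segmap.k + 1):
        rgb[grid == c] = segmap.palette[(c - 1) % len(segmap.palette)]
    plt.imsave(path, np.repeat(np.repeat(rgb, 4, axis=0), 4, axis=1),
               metadata={"Software": None})


def _load_segmap(outdir: Path) -> us.SegmentationMap:
    import pandas as pd
    table = pd.read_csv(_require(outdir, "segmentation.csv", "segment"))
    coords = table[["x", "y"]].to_numpy()
    labels = table["label"].to_numpy()
    shape = (int(coords[:, 1].max() - coords[:, 1].min() + 1),
             int(coords[:, 0].max() - coords[:, 0].min() + 1))
    return us.SegmentationMap(labels=labels, k=int(labels.max()),
                              coords=coords, grid_shape=shape)


def _stage_interpret(config: PipelineConfig, outdir: Path) -> list[str]:
    cube = msio.load_container(_require(outdir, "preprocessed.h5", "preprocess"))
    segmap = _load_segmap(outdir)
    i = config.section("interpret")
    pages = interp.build_report(segmap, cube, outdir / "interpret",
                                alpha=float(i["alpha"]), top_n=int(i["top_n"]),
                                use_q=bool(i["use_q"]))
    return [str(p.relative_to(outdir)) for p in pages.values()]


def _stage_classify(config: PipelineConfig, outdir: Path) -> list[str]:
    c = config.section("classify")
    if not c["enabled"]:
        (outdir / "classification.json").write_text(json.dumps({"enabled": False}))
        return ["classification.json"]
    import pandas as pd
    cube = msio.load_container(_require(outdir, "preprocessed.h5", "preprocess"))
    consensus = _load_consensus(outdir)
    tol = float(config.section("peaks")["tol"])
    features = us.peak_features(cube, consensus, tol=tol)
    roi_table = pd.read_csv(c["roi"])
    per_pixel = np.zeros(cube.n_pixels, dtype=int)
    coord_index = {tuple(xy): i for i, xy in enumerate(map(tuple, cube.coords))}
    for _, row in roi_table.iterrows():
        idx = coord_index.get((int(row["x"]), int(row["y"])))
        if idx is not None:
            per_pixel[idx] = int(row["label"])
    ga, gb, _, _ = clf.extract_groups(features, cube, per_pixel,
                                      int(c["group_a"]), int(c["group_b"]))
    result = clf.crossval_classify(ga, gb, consensus.mzs,
                                   folds=int(c["folds"]), seed=config.seed)
    top = clf.discriminative_mzs(result, int(c["top_n"]), cube,
                                 outdir / "discriminative")
    (outdir / "classification.json").write_text(json.dumps({
        "enabled": True,
        "accuracy": result.accuracy,
        "per_class_accuracy": list(result.per_class_accuracy),
        "group_sizes_before": list(result.group_sizes_before),
        "group_sizes_after": list(result.group_sizes_after),
        "decimation_step": result.decimation_step,
        "interpretation": result.interpretation(),
        "discriminative": top,
    }, indent=2))
    return ["classification.json"]


def _stage_report(config: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, "segmentation.csv", "segment")
    lines = ["# msipipe run summary", ""]
    for stage in STAGES[:-1]:
        mpath = _manifest_path(outdir, stage)
        if mpath.exists():
            manifest = json.loads(mpath.read_text())
            lines.append(f"- **{stage}**: {len(manifest['artifacts'])} artifact(s), "
                         f"{manifest['elapsed_s']} s")
    cls_path = outdir / "classification.json"
    if cls_path.exists():
        doc = json.loads(cls_path.read_text())
        if doc.get("enabled"):
            lines.append(f"- classification: {doc['interpretation']}")
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
    return ["summary.md"]


_BODIES: dict[str, tuple[Callable[[PipelineConfig, Path], list[str]], tuple[str, ...]]] = {
    # stage -> (body, config sections entering its manifest digest)
    "simulate": (_stage_simulate, ("synth",)),
    "ingest": (_stage_ingest, ("input", "synth")),
    "preprocess": (_stage_preprocess, ("input", "synth", "baseline", "smoothing",
                                       "normalization")),
    "peaks": (_stage_peaks, ("input", "synth", "baseline", "smoothing",
                             "normalization", "peaks")),
    "segment": (_stage_segment, ("input", "synth", "baseline", "smoothing",
                                 "normalization", "peaks", "segment")),
    "interpret": (_stage_interpret, ("input", "synth", "baseline", "smoothing",
                                     "normalization", "peaks", "segment",
                                     "interpret")),
    "classify": (_stage_classify, ("input", "synth", "baseline", "smoothing",
                                   "normalization", "peaks", "classify")),
    "report": (_stage_report, ("input", "synth", "baseline", "smoothing",
                               "normalization", "peaks", "segment", "interpret",
                               "classify")),
}


def run_stage(name: str, config: PipelineConfig, outdir: str | Path,
              force: bool = False) -> dict[str, Any]:
    """Run one pipeline stage into *outdir*; no-op when already up to date."""
    if name not in _BODIES:
        raise ValueError(f"unknown stage '{name}'; choose from "
                         f"{('simulate',) + STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    body, sections = _BODIES[name]
    digest = config.digest(*sections)
    if not force and _up_to_date(outdir, name, digest):
        log.info("stage %s: up to date", name)
        return {"stage": name, "skipped": True}
    start = time.perf_counter()
    artifacts = body(config, outdir)
    elapsed = time.perf_counter() - start
    _write_manifest(outdir, name, digest, artifacts, elapsed)
    log.info("stage %s: %d artifact(s) in %.2f s", name, len(artifacts), elapsed)
    return {"stage": name, "skipped": False, "artifacts": artifacts,
            "elapsed_s": elapsed}


def run_all(config: PipelineConfig, outdir: str | Path, force: bool = False,
            simulate: bool = False) -> list[dict[str, Any]]:
    """Run every stage in order (optionally generating a synthetic input)."""
    results = []
    stages = (("simulate",) if simulate else ()) + STAGES
    for stage in stages:
        results.append(run_stage(stage, config, outdir, force=force))
    return results


def run_batch(inputs: list[str | Path], config: PipelineConfig,
              outdir: str | Path, force: bool = False) -> dict[str, Any]:
    """Process many datasets, isolating per-dataset failures.

    Each input gets its own subdirectory of *outdir*; one failing dataset
    does not stop the batch.  An ``index.md`` lists successes and
    failures.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    successes, failures = [], []
    for source in inputs:
        source = Path(source)
        run_dir = outdir / source.stem
        cfg = config.with_overrides(input=str(source))
        try:
            run_all(cfg, run_dir, force=force)
            successes.append(source.name)
        except Exception as exc:  # isolate per-dataset failures
            failures.append((source.name, f"{type(exc).__name__}: {exc}"))
            log.error("dataset %s failed: %s", source.name, exc)
    lines = ["# msipipe batch index", "", f"{len(successes)} succeeded, "
             f"{len(failures)} failed", ""]
    lines += [f"- OK: [{name}]({Path(name).stem}/summary.md)" for name in successes]
    lines += [f"- FAILED: {name} — {reason}" for name, reason in failures]
    (outdir / "index.md").write_text("\n".join(lines) + "\n")
    return {"succeeded": successes, "failed": failures}
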