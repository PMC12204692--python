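"""End-to-end pipeline: smoothing, consensus initialisation, FHMM fit,
decoding, occupancy statistics, within-state FPCA and feature export.

``run_pipeline`` is a pure function of (input files, configuration,
seed): every stochastic step takes a seed derived from the master
seed, all tunables land in the run manifest, and numeric artifacts are
hashed so reruns can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import Curve, FrequencyGrid, FunctionalSeries
from .fhmm import (
    FHMMModel,
    ViterbiPath,
    baum_welch,
    functional_kmeans,
    group_centroids,
    make_initial_model,
    relabel_states,
    split_by_segments,
    subsample_initialise,
    viterbi,
)
from .fpca import (
    FPCAModel,
    choose_n_components,
    fit_fpca,
    scree_data,
    subset_by_state,
)
from .io import export_feature_table, read_dataset
from .occupancy import (
    OccupancySummary,
    combinations_to_frame,
    summaries_to_frame,
    summarise_path,
    visited_combinations,
)
from .smooth import SpectralSettings, fit_spectral_model

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "save_model", "load_model", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    "smooth": "none",  # none | spectral | bspline
    "init": "subsample",  # subsample | kmeans | file
    "n_states": 4,
    "n_models": 10,
    "subsample_fraction": 0.8,
    "states_per_model": 8,
    "tol": 1e-6,
    "max_iter": 200,
    "break_at_segments": False,
    "dominant_threshold": 0.8,
    "fpca_penalty": 1e-4,
    "retention_threshold": 0.70,
    "n_score_components": 5,
    "min_state_curves": 10,
}


def save_model(model: FHMMModel, path) -> None:
    payload = {
        "n_states": model.n_states,
        "initial_distribution": model.initial_distribution.tolist(),
        "transition_matrix": model.transition_matrix.tolist(),
        "grid": model.grid.points.tolist(),
        "centroids": [c.values.tolist() for c in model.centroids],
        "emission_epsilon": model.emission_epsilon,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> FHMMModel:
    payload = json.loads(Path(path).read_text())
    grid = FrequencyGrid(np.array(payload["grid"]))
    return FHMMModel(
        n_states=payload["n_states"],
        initial_distribution=np.array(payload["initial_distribution"]),
        transition_matrix=np.array(payload["transition_matrix"]),
        centroids=[Curve(grid, np.array(v)) for v in payload["centroids"]],
        emission_epsilon=payload["emission_epsilon"],
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _paths_frame(paths: Sequence[ViterbiPath], dataset) -> pd.DataFrame:
    by_id = {s.individual_id: s for s in dataset}
    rows = []
    for p in paths:
        series = by_id[p.individual_id]
        for curve, state in zip(series.curves, p.states):
            rows.append(
                {
                    "individual_id": p.individual_id,
                    "time_index": curve.time_index,
                    "state": int(state),
                }
            )
    return pd.DataFrame(rows)


def _segment_starts(series: FunctionalSeries) -> list[int]:
    starts = []
    prev: Hashable = object()
    for k, c in enumerate(series.curves):
        if k > 0 and c.segment_id != prev:
            starts.append(k)
        prev = c.segment_id
    return starts


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: Mapping[str, Any],
    out_dir,
    dataset: Sequence[FunctionalSeries] | None = None,
) -> dict[str, Any]:
    """Run the full analysis and write all artifacts to ``out_dir``.

    ``config`` must carry ``seed`` and either ``curves``/``meta``
    input paths or an in-memory ``dataset``; all other keys fall back
    to :data:`DEFAULTS`.  Returns a dict of in-memory artifacts; the
    manifest (settings, seeds, stage log, objective history, artifact
    hashes) is written as ``manifest.json``.
    """
    cfg = dict(DEFAULTS)
    cfg.update(config)
    if "seed" not in cfg:
        raise ValueError("config must set a seed")
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "settings": {k: v for k, v in cfg.items()},
        "stages": [],
        "artifacts": {},
    }
    artifacts: dict[str, Any] = {}

    def stage(name: str):
        def deco(fn):
            t0 = time.perf_counter()
            logger.info("stage %s ...", name)
            try:
                result = fn()
            except Exception as exc:
                _write_manifest(out, manifest)
                raise PipelineError(name, exc) from exc
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3)}
            )
            return result

        return deco

    @stage("load")
    def _load():
        if dataset is not None:
            return list(dataset)
        return read_dataset(cfg["curves"], cfg["meta"])

    data = _load

    @stage("smooth")
    def _smooth():
        mode = cfg["smooth"]
        if mode == "none":
            return data
        if mode != "spectral":
            raise ValueError(f"unsupported smoothing mode {mode!r} in pipeline")
        settings = SpectralSettings()
        smoothed = []
        for series in data:
            fits = [fit_spectral_model(c, settings) for c in series.curves]
            curves = []
            for c, f in zip(series.curves, fits):
                pc = f.peak_curve
                pc.individual_id = c.individual_id
                pc.time_index = c.time_index
                pc.segment_id = c.segment_id
                curves.append(pc)
            smoothed.append(FunctionalSeries(series.individual_id, curves))
        return smoothed

    data = _smooth
    fit_data = (
        [seg for s in data for seg in split_by_segments(s)]
        if cfg["break_at_segments"]
        else data
    )

    @stage("initialise")
    def _init():
        mode = cfg["init"]
        n_states = int(cfg["n_states"])
        if mode == "file":
            init_model = load_model(cfg["init_file"])
            manifest["settings"]["grouping"] = "skipped (file init)"
            return init_model
        if mode == "kmeans":
            curves = [c for s in fit_data for c in s.curves]
            centroids = functional_kmeans(curves, n_states, seed=seed)
            manifest["settings"]["grouping"] = "skipped (k-means init)"
            return make_initial_model(centroids)
        pool = subsample_initialise(
            fit_data,
            n_models=int(cfg["n_models"]),
            subsample_fraction=float(cfg["subsample_fraction"]),
            states_per_model=int(cfg["states_per_model"]),
            seed=seed,
            baum_welch_kwargs={"tol": cfg["tol"], "max_iter": int(cfg["max_iter"])},
        )
        grouping = group_centroids(pool, n_groups=n_states)
        np.savetxt(out / "centroid_pool_distances.csv",
                   grouping.distance_matrix, delimiter=",")
        return make_initial_model(grouping.initial_centroids)

    init_model = _init

    @stage("baum_welch")
    def _fit():
        model, history = baum_welch(
            fit_data, init_model, tol=float(cfg["tol"]), max_iter=int(cfg["max_iter"])
        )
        manifest["objective_history"] = history.objective
        manifest["converged"] = history.converged
        return model

    model = _fit

    @stage("viterbi")
    def _decode():
        if cfg["break_at_segments"]:
            paths = []
            for s in data:
                segs = split_by_segments(s)
                states = np.concatenate([viterbi(seg, model).states for seg in segs])
                score = sum(viterbi(seg, model).path_log_score for seg in segs)
                paths.append(ViterbiPath(s.individual_id, states, float(score)))
            return paths
        return [viterbi(s, model) for s in data]

    paths = _decode

    @stage("relabel")
    def _relabel():
        return relabel_states(model, paths)

    model, paths = _relabel

    @stage("occupancy")
    def _occupancy():
        summaries = []
        for s, p in zip(data, paths):
            starts = _segment_starts(s) if cfg["break_at_segments"] else ()
            summaries.append(summarise_path(p, model.n_states, segment_starts=starts))
        return summaries

    summaries: list[OccupancySummary] = _occupancy

    @stage("fpca")
    def _fpca():
        models: dict[int, FPCAModel] = {}
        for state in range(1, model.n_states + 1):
            curves = subset_by_state(data, paths, state)
            if len(curves) < int(cfg["min_state_curves"]):
                logger.warning(
                    "state %d has only %d curves; skipping FPCA", state, len(curves)
                )
                continue
            fp = fit_fpca(curves, penalty=float(cfg["fpca_penalty"]),
                          state_label=state)
            c_keep = choose_n_components(
                fp.variance_fractions, threshold=float(cfg["retention_threshold"])
            )
            manifest.setdefault("fpca", {})[str(state)] = {
                "n_curves": len(curves),
                "n_retained": c_keep,
                "cumulative_variance": float(
                    np.cumsum(fp.variance_fractions)[c_keep - 1]
                ),
            }
            scree_data(fp.variance_fractions).to_csv(
                out / f"fpca_state{state}_scree.csv", index=False
            )
            models[state] = fp
        return models

    fpca_models = _fpca

    @stage("export")
    def _export():
        save_model(model, out / "model.json")
        _paths_frame(paths, data).to_csv(out / "paths.csv", index=False)
        summaries_to_frame(summaries).to_csv(out / "occupancy.csv", index=False)
        combos = visited_combinations(summaries, n_states=model.n_states)
        combinations_to_frame(combos).to_csv(out / "combinations.csv", index=False)
        features = export_feature_table(
            summaries,
            fpca_models,
            threshold=float(cfg["dominant_threshold"]),
            n_score_components=int(cfg["n_score_components"]),
        )
        features.to_csv(out / "features.csv", index=False)
        return features

    features = _export

    for f in sorted(out.glob("*.csv")) + [out / "model.json"]:
        manifest["artifacts"][f.name] = _sha256(f)
    _write_manifest(out, manifest)

    artifacts.update(
        model=model,
        paths=paths,
        summaries=summaries,
        fpca_models=fpca_models,
        features=features,
        manifest=manifest,
    )
    return artifacts


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
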