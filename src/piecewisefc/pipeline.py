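"""Configuration-driven end-to-end orchestration.

A single YAML/JSON config describes data (simulation parameters or paths
to epoched HDF5 files), the connectivity metric and bands, the window
scheme (fixed tau, classifier-derived variable, or whole-epoch), the
thresholding rule and the seeds.  ``run_pipeline`` executes

    simulate/load -> preprocess -> connectivity -> windows ->
    thresholding -> combination -> graph summaries

and writes a manifest recording package and library versions, the
per-stage seeds, a hash of the resolved configuration and the SHA-256 of
every numeric output, so that two runs of the same config are verifiably
byte-identical.

All randomness flows from the single root ``seed`` through
``numpy.random.SeedSequence`` spawns, one per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .connectivity import subject_connectivity
from .data_model import (DEFAULT_BANDS, MultiSubjectDataset, baseline_correct,
                         get_band, preprocess_filters, read_epochs,
                         write_epochs)
from .decoding import detect_change_points, time_resolved_accuracy
from .errors import ParameterError
from .graphs import (channel_relevance_counts, network_density,
                     node_strength_links, unfold_to_channels,
                     write_adjacency, write_node_strength)
from .relevance import export_link_table, psth, puth
from .simulate import PlantedCoupling, SimulationParams, simulate_dataset
from .windows import (make_fixed_windows, make_variable_windows,
                      stack_windowed, whole_window)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("piecewisefc")


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (see module docstring for keys)."""

    simulate: dict | None = None
    dataset_paths: list[str] = field(default_factory=list)
    preprocess: dict | None = None
    baseline: list[float] | None = None
    metric: str = "wpli"
    bands: list[str] = field(default_factory=lambda: ["theta"])
    windowing: dict = field(default_factory=lambda: {"mode": "fixed",
                                                     "tau": 0.1})
    extent: list[float] | None = None  # default: post-stimulus [0, end]
    threshold: dict = field(default_factory=lambda: {"rule": "psth",
                                                     "alpha": 0.05})
    classifier: dict = field(default_factory=dict)
    fc: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "pipeline_out"

    def __post_init__(self):
        if self.simulate is None and not self.dataset_paths:
            raise ParameterError("config needs either 'simulate' or 'dataset'")
        if self.simulate is not None and self.dataset_paths:
            raise ParameterError("'simulate' and 'dataset' are exclusive")
        mode = self.windowing.get("mode")
        if mode not in ("fixed", "variable", "whole"):
            raise ParameterError(f"windowing mode must be fixed/variable/whole,"
                                 f" got {mode!r}")
        keys = set(self.windowing) - {"mode"}
        if mode == "fixed" and (keys - {"tau"} or "tau" not in keys):
            raise ParameterError("fixed windowing takes exactly 'tau'")
        if mode == "variable" and keys not in ({"change_points"},
                                               {"from_classifier"}):
            raise ParameterError(
                "variable windowing takes 'change_points' or 'from_classifier'"
            )
        if mode == "whole" and keys:
            raise ParameterError("whole windowing takes no parameters")
        rule = self.threshold.get("rule")
        if rule not in ("psth", "puth"):
            raise ParameterError(f"threshold rule must be psth or puth, "
                                 f"got {rule!r}")
        for b in self.bands:
            get_band(b)

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        obj = dict(obj)
        dataset = obj.pop("dataset", None)
        if dataset:
            obj["dataset_paths"] = list(dataset.get("paths", dataset)
                                        if isinstance(dataset, dict)
                                        else dataset)
        return cls(**obj)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _build_sim_params(cfg: dict, seed: int) -> SimulationParams:
    cfg = dict(cfg)
    couplings = [PlantedCoupling(
        pair=tuple(c["pair"]), band_center=c["band_center"],
        phase_lag=c.get("phase_lag", np.pi / 2),
        window=tuple(c.get("window", (0.2, 0.5))),
        condition=c.get("condition", "target"),
    ) for c in cfg.pop("couplings", [])]
    cfg.pop("seed", None)
    if "epoch" in cfg:
        cfg["epoch"] = tuple(cfg["epoch"])
    return SimulationParams(couplings=couplings, seed=seed, **cfg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: "PipelineConfig | dict", out_dir=None) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    root = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(ss.generate_state(1)[0] % (2 ** 31))
                   for name, ss in zip(
                       ["simulate", "fc", "classifier", "consistency"],
                       root.spawn(4))}
    log.info("stage seeds: %s", stage_seeds)
    outputs: dict[str, str] = {}

    # -- stage 1: data ------------------------------------------------------
    if config.simulate is not None:
        params = _build_sim_params(config.simulate, stage_seeds["simulate"])
        dataset, truth = simulate_dataset(params)
        truth_path = out / "ground_truth.json"
        with open(truth_path, "w") as f:
            json.dump({"n_channels": truth.n_channels,
                       "couplings": [asdict(c) for c in truth.couplings]},
                      f, indent=2, default=list)
        outputs["ground_truth"] = str(truth_path)
        for sub in dataset:
            p = out / f"{sub.subject_id}.h5"
            write_epochs(sub, p)
            outputs[f"dataset/{sub.subject_id}"] = str(p)
    else:
        subs = [read_epochs(p) for p in config.dataset_paths]
        dataset = MultiSubjectDataset(subs)
        truth = None
    log.info("dataset: M=%d C=%d", dataset.n_subjects, dataset.n_channels)

    # -- stage 2: preprocessing --------------------------------------------
    if config.preprocess is not None:
        dataset = MultiSubjectDataset(
            [preprocess_filters(s, **config.preprocess) for s in dataset])
    if config.baseline is not None:
        dataset = MultiSubjectDataset(
            [baseline_correct(s, tuple(config.baseline)) for s in dataset])

    # -- stage 3: windows ---------------------------------------------------
    times = dataset.times
    extent = tuple(config.extent) if config.extent is not None else \
        (max(0.0, float(times[0])), float(times[-1] + 1.0 / dataset.fs))
    mode = config.windowing["mode"]
    curve = None
    if mode == "fixed":
        scheme = make_fixed_windows(extent, config.windowing["tau"])
    elif mode == "whole":
        scheme = whole_window(extent)
    else:
        if "change_points" in config.windowing:
            cps = config.windowing["change_points"]
        else:
            cl = dict(config.classifier)
            max_segments = cl.pop("max_segments", 8)
            smooth_s = cl.pop("smooth_s", 0.05)
            curve = time_resolved_accuracy(
                dataset, random_state=stage_seeds["classifier"], **cl)
            cp = detect_change_points(curve, max_segments=max_segments,
                                      smooth_s=smooth_s)
            cps = [t for t in cp.times if extent[0] < t < extent[1]]
            curve_path = out / "classifier_curve.json"
            with open(curve_path, "w") as f:
                json.dump({"times": curve.times.tolist(),
                           "accuracy": curve.accuracy.tolist(),
                           "change_points": list(cp.times)}, f, indent=2)
            outputs["classifier_curve"] = str(curve_path)
        scheme = make_variable_windows(cps, extent)
    scheme_path = out / "window_scheme.json"
    scheme.to_json(scheme_path)
    outputs["window_scheme"] = str(scheme_path)
    log.info("windows (%s): %d", scheme.kind, scheme.n_windows)

    # -- stage 4-6: connectivity, thresholding, graphs ----------------------
    fc_opts = dict(config.fc)
    fc_rng = np.random.default_rng(stage_seeds["fc"])
    results = {}
    for band_name in config.bands:
        band = get_band(band_name)
        per_subject = [
            subject_connectivity(sub, band, metric=config.metric,
                                 split_by_label=True, rng=fc_rng, **fc_opts)
            for sub in dataset
        ]
        wc = stack_windowed(per_subject, scheme)
        rule = config.threshold["rule"]
        if rule == "psth":
            alpha = config.threshold.get("alpha", 0.05)
            sel = psth(wc, alpha,
                       family=config.threshold.get("family", "per_window"))
            combined = sel["combined"].values
            table_path = out / f"link_table_{band.name}.tsv"
            export_link_table(table_path, wc, sel["tests_windows"],
                              dataset.channel_names)
            outputs[f"link_table/{band.name}"] = str(table_path)
            masks_obj = {
                "combined": combined.astype(int).tolist(),
                "window_masks": sel["window_masks"].values.astype(int).tolist(),
                "subject_masks": sel["subject_masks"].values.astype(int).tolist(),
            }
        else:
            q = config.threshold.get("q", 0.7)
            window_masks = puth(wc, q)
            combined = window_masks.any_link()
            masks_obj = {
                "combined": combined.astype(int).tolist(),
                "window_masks": window_masks.values.astype(int).tolist(),
            }
        mask_path = out / f"relevance_{band.name}.json"
        with open(mask_path, "w") as f:
            json.dump(masks_obj, f)
        outputs[f"relevance/{band.name}"] = str(mask_path)

        # graph summaries use the condition-mean subject series
        y_stack = np.stack([
            np.mean([cs.values for cs in sub.values()], axis=0)
            for sub in per_subject
        ])
        gamma_v = node_strength_links(y_stack, combined)
        gamma_c = unfold_to_channels(gamma_v, dataset.n_channels)
        adj_path = out / f"adjacency_{band.name}.txt"
        write_adjacency(adj_path, gamma_v.mean(axis=1),
                        dataset.channel_names)
        outputs[f"adjacency/{band.name}"] = str(adj_path)
        ns_path = out / f"node_strength_{band.name}.tsv"
        write_node_strength(ns_path, gamma_c, dataset.times,
                            dataset.channel_names)
        outputs[f"node_strength/{band.name}"] = str(ns_path)
        results[band.name] = {
            "density": network_density(combined),
            "n_selected": int(np.sum(combined)),
            "channel_counts": channel_relevance_counts(
                combined, dataset.n_channels).tolist(),
        }
        log.info("band %s: %d links selected (density %.3f)", band.name,
                 results[band.name]["n_selected"],
                 results[band.name]["density"])

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config_hash": config.config_hash(),
        "config": json.loads(config.canonical_json()),
        "stage_seeds": stage_seeds,
        "scheme": {"kind": scheme.kind,
                   "intervals": [list(iv) for iv in scheme.intervals]},
        "results": results,
        "outputs": {k: {"path": v, "sha256": _sha256(Path(v))}
                    for k, v in outputs.items()},
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
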