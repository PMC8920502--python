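"""End-to-end orchestration: ingest or simulate -> reactive extraction ->
SOM transition paths -> DTW clustering -> per-path string method ->
quasi-potentials -> CK test -> Fokker-Planck prediction.

A single YAML config drives the run; every stage default is the analysis
protocol's published value (30 string images, w=10, smooth factor 1, 12x12
SOM trained 50 epochs with radius/std 1, prune 0.01, community radius 0.7,
3 extrapolation images, 200x200 density grid smoothed with sigma=2 truncated
at 2).  All randomness flows from one top-level seed through fixed offsets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .clustering import align_to_rcs, cluster_paths, dtw_distance_matrix
from .fokker_planck import solve_fokker_planck, stationary_stats
from .potential import QuasiPotentialModel, ck_test
from .regions import RegionSpec, extract_reactive, reactive_density_map, ridge_modes
from .simulate import (
    TWO_PATH_E_CENTER,
    TWO_PATH_M_CENTER,
    simulate_two_path_ensemble,
)
from .som import build_transition_network, shortest_transition_paths, train_som
from .string_method import StringMethod, _region_means, extrapolate_string

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_full_pipeline"]

# seed offsets for the independent random stages
_SEED_SIM, _SEED_SOM, _SEED_CLUSTER = 11, 23, 37


@dataclass
class PipelineConfig:
    """Parameters of a full run; defaults follow the published protocol."""

    # input: a trajectory table path, or None to use the two-path simulator
    input_path: str | None = None
    simulate_n_per_channel: int = 60
    simulate_control: float = 1.0
    # regions (defaults: the two-channel landscape's actual attractors)
    E_center: tuple = tuple(TWO_PATH_E_CENTER)
    M_center: tuple | None = None
    E_radius: float = 3.5
    M_radius: float = 5.0
    deadline: float = 48.0
    # SOM / network
    som_grid: tuple = (12, 12)
    som_epochs: int = 50
    som_radius: float = 1.0
    som_std: float = 1.0
    prune: float = 0.01
    community_radius: float = 0.7
    # density map
    density_bins: int = 200
    density_sigma: float = 2.0
    density_truncate: float = 2.0
    # string
    n_images: int = 30
    w: float = 10.0
    smooth: float = 1.0
    n_extra: int = 3
    max_iter: int = 100
    # potential / FP
    min_count: int = 5
    kBT: float = 0.5
    pseudocount: float = 0.5
    fp_grid_n: int = 200
    # bookkeeping
    seed: int = 0
    output_dir: str = "statepath_run"

    def __post_init__(self) -> None:
        from .string_method import MIN_IMAGES

        if self.n_images < MIN_IMAGES:
            raise ValueError(
                f"string module requires n_images >= {MIN_IMAGES}, got {self.n_images}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["som_grid"] = list(self.som_grid)
        data["E_center"] = [float(v) for v in self.E_center]
        if self.M_center is not None:
            data["M_center"] = [float(v) for v in self.M_center]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def regions(self) -> RegionSpec:
        if self.M_center is None:
            from .simulate import two_path_regions

            base = two_path_regions(self.E_radius, self.M_radius)
            return RegionSpec(
                np.asarray(self.E_center, float),
                base.M_center,
                self.E_radius,
                self.M_radius,
            )
        return RegionSpec(
            np.asarray(self.E_center, float),
            np.asarray(self.M_center, float),
            self.E_radius,
            self.M_radius,
        )


@dataclass
class RunReport:
    """Per-stage summaries plus the parameter echo for reproducibility."""

    config: PipelineConfig
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def save(self, path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "stages": self.stages,
            "warnings": self.warnings,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def run_full_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in dependency order, persisting tables as it goes."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report = RunReport(config)
    regions = config.regions()

    # --- stage 1: input ----------------------------------------------------
    if config.input_path:
        ensemble = tio.read_trajectories(config.input_path)
        true_labels = None
    else:
        ensemble, true_labels = simulate_two_path_ensemble(
            n_per_channel=config.simulate_n_per_channel,
            control=config.simulate_control,
            seed=config.seed + _SEED_SIM,
        )
        tio.write_trajectories(ensemble, out / "ensemble.csv")
    report.stages["input"] = {
        "n_trajectories": len(ensemble),
        "n_frames": int(sum(tr.n_frames for tr in ensemble)),
        "dt": ensemble.dt,
        "condition": ensemble.condition_label,
    }

    # --- stage 2: reactive extraction --------------------------------------
    reactive = extract_reactive(ensemble, regions, config.deadline)
    report.stages["reactive"] = {
        "n_reactive": len(reactive),
        "fraction": len(reactive) / len(ensemble),
    }
    if len(reactive) < 4:
        raise RuntimeError(
            "reactive stage: fewer than 4 reactive trajectories; "
            "check region geometry or deadline"
        )

    # --- stage 3: SOM transition network ------------------------------------
    # discretize the transition passes themselves (trajectories truncated
    # shortly after first M entry), not the long product-basin dwell
    segments = reactive.transition_segments()
    som = train_som(
        segments.stacked(),
        grid=tuple(config.som_grid),
        epochs=config.som_epochs,
        radius=config.som_radius,
        std=config.som_std,
        seed=config.seed + _SEED_SOM,
    )
    net = build_transition_network(segments, som, prune=config.prune)
    # community centers are the empirical E/M data means (same anchors the
    # string method uses); if no neuron falls within the configured radius
    # the radius is widened to just include the nearest neuron
    e_mean, m_mean = _region_means(reactive.ensemble, regions)
    radius = config.community_radius
    min_needed = max(
        np.linalg.norm(som.codebook - e_mean, axis=1).min(),
        np.linalg.norm(som.codebook - m_mean, axis=1).min(),
    )
    if min_needed > radius:
        logger.warning(
            "no neuron within community radius %.3g; widening to %.3g",
            radius, min_needed,
        )
        radius = float(min_needed) * 1.001
    paths = shortest_transition_paths(net, som, e_mean, m_mean, radius=radius)
    net.to_edge_table().to_csv(out / "transition_edges.csv", index=False)
    report.stages["som_network"] = {
        "n_states": net.n_states,
        "n_edges": int(np.count_nonzero(net.P)),
        "n_shortest_paths": paths.n_paths,
        "E_community": net.E_states,
        "M_community": net.M_states,
    }

    # --- stage 4: reactive density map --------------------------------------
    dmap = reactive_density_map(
        reactive,
        n_bins=config.density_bins,
        sigma=config.density_sigma,
        truncate=config.density_truncate,
    )
    np.savetxt(out / "density_map.csv", dmap.values, delimiter=",")
    modes = ridge_modes(dmap, regions.E_center, regions.M_center)
    report.stages["density_map"] = {
        "n_ridges": len(modes),
        "ridge_modes": modes,
        "bounds": dmap.bounds,
    }

    # --- stage 5: DTW clustering --------------------------------------------
    D = dtw_distance_matrix(reactive)
    labels = cluster_paths(D, k=2, seed=config.seed + _SEED_CLUSTER, reactive=reactive)
    np.savetxt(out / "path_labels.csv", labels, fmt="%d", delimiter=",")
    cluster_info = {
        "group_sizes": [int((labels == 1).sum()), int((labels == 2).sum())],
    }
    if true_labels is not None:
        reactive_ids = {tr.cell_id for tr in reactive}
        truth = np.array(
            [
                lab
                for tr, lab in zip(ensemble, true_labels)
                if tr.cell_id in reactive_ids
            ]
        )
        acc = max((labels == truth).mean(), (labels == 3 - truth).mean())
        cluster_info["label_recovery"] = float(acc)
    report.stages["clustering"] = cluster_info

    # --- stage 6: per-group strings ------------------------------------------
    rcs = {}
    for g in (1, 2):
        members = [i for i, lab in enumerate(labels) if lab == g]
        group = reactive.ensemble.subset(members)
        group_reactive = extract_reactive(group, regions, config.deadline)
        res = StringMethod(
            group_reactive,
            regions,
            n_images=config.n_images,
            w=config.w,
            smooth=config.smooth,
        ).fit(max_iter=config.max_iter)
        rc = extrapolate_string(res.rc, config.n_extra)
        rcs[g] = rc
        np.savetxt(
            out / f"rc{g}_images.csv",
            np.column_stack([rc.s, rc.images]),
            delimiter=",",
            header="s," + ",".join(ensemble.feature_names),
        )
        report.stages[f"string_{g}"] = {
            "n_iter": res.n_iter,
            "converged": res.converged,
            "arc_length": float(rc.s[-1]),
        }

    # --- stage 7: part-aligned quasi-potentials ------------------------------
    assignments = [align_to_rcs(tr, rcs[1], rcs[2]) for tr in ensemble]
    fp_stats = {}
    for g in (1, 2):
        model = QuasiPotentialModel.from_path_assignments(
            ensemble, rcs[g], assignments, g, min_count=config.min_count
        )
        qp = model.fit()
        qp.to_frame().to_csv(out / f"quasipotential_rc{g}.csv", index=False)
        report.stages[f"potential_{g}"] = {
            "estimated_cells": int((~qp.mask).sum()),
            "masked_cells": int(qp.mask.sum()),
            "mean_D": float(np.nanmean(qp.D)),
            "phi_range": float(np.nanmax(qp.phi_cells) - np.nanmin(qp.phi_cells)),
        }
        sol = qp.solve_fokker_planck(kBT=config.kBT, grid_n=config.fp_grid_n)
        mean, sd = stationary_stats(sol)
        fp_stats[g] = (mean, sd)
        report.stages[f"fokker_planck_{g}"] = {
            "stationary_mean": mean,
            "stationary_sd": sd,
        }

    # --- stage 8: CK test on RC 1 cells ---------------------------------------
    ck = ck_test(ensemble, rcs[1], tau=1, ks=(2, 3, 4, 5))
    report.stages["ck_test"] = {
        "deviations": {int(k): float(v) for k, v in ck.deviations.items()}
    }

    report.save(out / "report.json")
    return report
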