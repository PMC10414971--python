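"""End-to-end orchestration of the synthetic study pipeline.

``run_pipeline`` executes simulate -> gradients -> profiles -> change maps
-> contrasts -> spin tests -> prediction on fully synthetic inputs, writes
every stage's numeric tables to a run directory, and records a provenance
manifest (config snapshot, seeds, file hashes, wall times). Stages
communicate only through files, so any stage's outputs can be regenerated
or inspected in isolation, and a rerun with the same seed reproduces every
table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .equivolume import build_laminar_stack, compartment_means, depth_zscore, parcel_profiles, sample_field
from .errors import ConfigError, PipelineError
from .gradients import (
    diffusion_embedding,
    eccentricity,
    network_summary,
    normalized_angle,
    procrustes_align,
    threshold_rows,
)
from .io_core import RunConfig, child_seeds, logger, write_design, write_matrix, write_table
from .longitudinal import change_maps, fit_contrast
from .prediction import cross_validate, feature_names
from .spatial import spin_test
from .synthetic import (
    EffectSpec,
    LatentManifold,
    fibonacci_sphere,
    make_behavior,
    make_cohort,
    make_connectome,
    make_cortex,
    make_grid_parcellation,
    make_network_weights,
    make_qt1_field,
    make_reference_embedding,
    sheet_depth_geometry,
)

__all__ = ["SimulationSpec", "RunManifest", "run_pipeline"]


@dataclass
class SimulationSpec:
    """Scale and planted-effect settings for the synthetic study.

    Defaults mirror the study's dimensionality: 400 parcels and on the
    order of 100 subjects per arm, with an attention-module (Presence)
    eccentricity increase and a socio-cognitive (Perspective) decrease of
    0.2 metric units in 40 parcels each, subject drift and interval noise
    of 0.1, and behavior tied to 7 of the 35 features.
    """

    n_tc1: int = 100
    n_tc2: int = 100
    n_rcc: int = 100
    effect_size: float = 0.2
    n_effect_parcels: int = 40
    subject_sd: float = 0.1
    residual_sd: float = 0.1
    kernel_scale: float = 1.0
    connectome_noise_sd: float = 0.01
    n_cortex_vertices: int = 1600
    behavior_noise_sd: float = 0.5
    n_true_behavior_features: int = 7

    @classmethod
    def from_dict(cls, data: dict | None) -> "SimulationSpec":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunManifest:
    """Provenance record: enough to re-run the pipeline identically."""

    config: dict
    simulate: dict
    seed: int
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {outputs: {path: sha256}, wall_s}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _effect_maps(spec: SimulationSpec, n_parcels: int) -> dict[str, np.ndarray]:
    k = min(spec.n_effect_parcels, n_parcels // 2)
    presence = np.zeros(n_parcels)
    presence[:k] = spec.effect_size
    perspective = np.zeros(n_parcels)
    perspective[k : 2 * k] = -spec.effect_size
    return {"Presence": presence, "Affect": np.zeros(n_parcels), "Perspective": perspective}


def run_pipeline(config: RunConfig, out_dir: str | Path, seed: int | None = None) -> RunManifest:
    """Run every stage on synthetic data and write tables plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)
    sim = SimulationSpec.from_dict(config.simulate)
    seeds = child_seeds(seed, 8)
    manifest = RunManifest(config=config.to_dict(), simulate=dataclasses.asdict(sim),
                           seed=seed, version=__version__)
    n_parcels = config.n_parcels
    parcel_ids = [f"p{i:03d}" for i in range(n_parcels)]

    def finish(stage: str, t0: float, outputs: list[Path]):
        manifest.stages[stage] = {
            "wall_s": round(time.perf_counter() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        logger.info("stage %s done (%.2fs)", stage, manifest.stages[stage]["wall_s"])

    # --- simulate: connectome ------------------------------------------------
    t0 = time.perf_counter()
    try:
        manifold = LatentManifold.random(n_parcels, seed=int(seeds[0]),
                                         kernel_scale=sim.kernel_scale,
                                         noise_sd=sim.connectome_noise_sd)
        cm, coords = make_connectome(manifold, seed=int(seeds[0]))
        fc_path = out / "fc.tsv"
        write_matrix(cm, fc_path)
        coords_path = out / "latent_coords.tsv"
        write_table(pd.DataFrame(coords, index=parcel_ids, columns=["x", "y", "z"]), coords_path)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate_connectome", str(e)) from e
    finish("simulate_connectome", t0, [fc_path, coords_path])

    # --- gradients -----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        thr = threshold_rows(cm, density=config.density)
        emb = diffusion_embedding(normalized_angle(thr),
                                  embedding_alpha=config.embedding_alpha,
                                  diffusion_time=config.diffusion_time,
                                  k=config.n_components)
        ref = make_reference_embedding(n_parcels, k=config.n_components,
                                       density=config.density,
                                       embedding_alpha=config.embedding_alpha)
        aligned = procrustes_align(emb, ref, n_components=config.n_components_report,
                                   ref_name="synthetic-template")
        ecc = eccentricity(aligned)
        grad_path = out / "gradients.tsv"
        gdf = pd.DataFrame(aligned.scores, index=parcel_ids,
                           columns=[f"G{i+1}" for i in range(aligned.k)])
        gdf["eccentricity"] = ecc.values
        write_table(gdf, grad_path)
        eig_path = out / "eigenvalues.tsv"
        write_table(pd.DataFrame({"eigenvalue": emb.eigenvalues,
                                  "variance_explained": emb.variance_explained}), eig_path)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("gradients", str(e)) from e
    finish("gradients", t0, [grad_path, eig_path])

    # --- simulate: cohort ----------------------------------------------------
    t0 = time.perf_counter()
    try:
        effects = EffectSpec(effect_maps=_effect_maps(sim, n_parcels),
                             subject_sd=sim.subject_sd, residual_sd=sim.residual_sd,
                             baseline_mean=1.0, baseline_sd=0.1)
        design, maps = make_cohort(sim.n_tc1, sim.n_tc2, sim.n_rcc, effects,
                                   n_parcels=n_parcels, seed=int(seeds[1]))
        design_path = out / "design.tsv"
        write_design(design, design_path)
        maps_path = out / "metric_maps.tsv"
        mdf = pd.DataFrame(
            {f"{sid}:{tp}": maps[(sid, tp)] for sid, tp in sorted(maps)},
            index=parcel_ids,
        ).T
        mdf.columns = parcel_ids
        write_table(mdf, maps_path)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate_cohort", str(e)) from e
    finish("simulate_cohort", t0, [design_path, maps_path])

    # --- profiles ------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        thickness = 3.0
        sp = make_cortex("sheet", n_vertices=sim.n_cortex_vertices, thickness=thickness)
        analytic, _ = make_qt1_field(
            lambda depth, region: 1400.0 + 500.0 * depth + 100.0 * region,
            sheet_depth_geometry(thickness, region_split_x=10.0),
        )
        stack = build_laminar_stack(sp, n_surfaces=config.n_surfaces)
        samples = sample_field(stack, analytic)
        parc = make_grid_parcellation(sp.n_vertices, n_parcels)
        profiles = parcel_profiles(samples, parc)
        prof_path = out / "qt1_profiles.tsv"
        depth_cols = [f"depth{i+1:02d}" for i in range(config.n_surfaces)]
        write_table(pd.DataFrame(profiles.values, index=parcel_ids, columns=depth_cols),
                    prof_path)
        z_path = out / "qt1_profiles_z.tsv"
        write_table(pd.DataFrame(depth_zscore(profiles).values, index=parcel_ids,
                                 columns=depth_cols), z_path)
        comp_path = out / "qt1_compartments.tsv"
        write_table(pd.DataFrame(compartment_means(profiles), index=parcel_ids), comp_path)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("profiles", str(e)) from e
    finish("profiles", t0, [prof_path, z_path, comp_path])

    # --- change maps & contrasts --------------------------------------------
    t0 = time.perf_counter()
    try:
        ct = change_maps(maps, design)
        contrasts = [("Presence", "Perspective"), ("Presence", "RCC")]
        contrast_paths = []
        tmaps = {}
        for tm_a, tm_b in contrasts:
            res = fit_contrast(ct, (tm_a, tm_b),
                               use_interval_index=config.use_interval_index,
                               center_ages=config.center_ages, q_level=config.fdr_q)
            cpath = out / f"contrast_{tm_a}_vs_{tm_b}.tsv"
            write_table(pd.DataFrame({"t": res.t, "p": res.p, "q": res.q, "d": res.d,
                                      "estimate": res.estimate}, index=parcel_ids), cpath)
            contrast_paths.append(cpath)
            tmaps[(tm_a, tm_b)] = res.t
    except Exception as e:  # noqa: BLE001
        raise PipelineError("contrasts", str(e)) from e
    finish("contrasts", t0, contrast_paths)

    # --- spatial correspondence ----------------------------------------------
    t0 = time.perf_counter()
    try:
        centroids = fibonacci_sphere(n_parcels)
        micro_change = depth_zscore(profiles).values[:, :4].mean(axis=1)
        spin = spin_test(tmaps[("Presence", "Perspective")], micro_change, centroids,
                         n_perm=config.n_perm, seed=int(seeds[2]))
        spin_path = out / "spin_test.tsv"
        write_table(pd.DataFrame({"observed_r": [spin.observed_r],
                                  "p_spin": [spin.p_spin],
                                  "n_perm": [len(spin.null_rs)]}), spin_path, index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("spatial", str(e)) from e
    finish("spatial", t0, [spin_path])

    # --- prediction ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        nets = make_network_weights(n_parcels, seed=int(seeds[3]))
        pres = ct.frame["tm"] == "Presence"
        pres_first = ct.frame.loc[pres].drop_duplicates("subject_id").index
        dmaps = ct.values[pres_first]
        names = feature_names()
        rng = np.random.default_rng(int(seeds[4]))
        Xf = rng.standard_normal((dmaps.shape[0], len(names)))
        for i, net in enumerate(nets.names):
            Xf[:, names.index(f"{net}_ecc")] = [
                network_summary(row, nets)[net] for row in dmaps
            ]
        w = np.zeros(len(names))
        true_idx = rng.choice(len(names), size=sim.n_true_behavior_features, replace=False)
        w[true_idx] = rng.uniform(0.5, 1.0, size=len(true_idx))
        y = make_behavior(Xf, w, noise_sd=sim.behavior_noise_sd, seed=int(seeds[5]))
        covs = ct.frame.loc[pres].drop_duplicates("subject_id")[["age", "sex"]].to_numpy(float)
        pred = cross_validate(Xf, y, covariates=covs, folds=config.folds,
                              reps=config.reps, seed=int(seeds[6]),
                              n_select=config.n_select, alpha_grid=config.alpha_grid())
        pred_path = out / "prediction_repeats.tsv"
        write_table(pd.DataFrame({"r": pred.per_repeat_r, "nmae": pred.per_repeat_nmae}),
                    pred_path, index=False)
        sel_path = out / "prediction_selection.tsv"
        write_table(pd.DataFrame({"feature": names,
                                  "selection_frequency": pred.selection_frequency,
                                  "mean_coefficient": pred.mean_coefficients,
                                  "true_weight": w}), sel_path, index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("prediction", str(e)) from e
    finish("prediction", t0, [pred_path, sel_path])

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
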