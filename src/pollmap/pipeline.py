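"""End-to-end pipeline: simulate -> prep -> sdm -> ensemble -> service.

Each stage writes its artifacts (ESRI ASCII rasters, CSV tables) under the
output directory and registers them in a manifest with stage, seed, and
SHA-256 checksum; a fixed config therefore yields bit-identical artifacts on
re-run. Stages can be run separately: a stage whose inputs are not in memory
reloads them from the files a previous invocation wrote.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import io as pio
from . import maxent, occurrences as occ, service as srv, synthetic as syn
from .config import RunConfig
from .grids import GridSpec, PredictorStack

__all__ = ["run_pipeline", "PipelineState", "ALL_STAGES"]

log = logging.getLogger("pollmap")

ALL_STAGES = ("simulate", "prep", "sdm", "ensemble", "service")


def _grid_from_config(cfg: RunConfig) -> GridSpec:
    g = cfg["grid"]
    return GridSpec(g["n_rows"], g["n_cols"], g["cell_size"], tuple(g.get("origin", (0.0, 0.0))))


def _safe(name: str) -> str:
    return name.replace(" ", "_")


@dataclass
class PipelineState:
    """In-memory objects shared between stages, plus the artifact manifest."""

    cfg: RunConfig
    outdir: Path
    stack: PredictorStack | None = None
    effort: syn.EffortLayer | None = None
    records: pd.DataFrame | None = None
    species_meta: dict[str, dict] = field(default_factory=dict)
    grids: dict[str, occ.OccurrenceGrid] = field(default_factory=dict)
    profiles: dict[str, occ.SpeciesProfile] = field(default_factory=dict)
    crop_coarse: syn.CropMap | None = None
    foragers: np.ndarray | None = None
    cv_results: dict[str, maxent.CVResult] = field(default_factory=dict)
    final_maps: dict[str, np.ndarray] = field(default_factory=dict)
    capture: dict[str, float] = field(default_factory=dict)
    manifest: list[dict] = field(default_factory=list)

    def register(self, path: Path, stage: str, seed: int | None = None) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.manifest.append(
            {
                "path": str(path.relative_to(self.outdir)),
                "stage": stage,
                "seed": seed,
                "sha256": digest,
            }
        )

    def write_manifest(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2))
        return path


def stage_simulate(state: PipelineState) -> None:
    cfg, out = state.cfg, state.outdir
    spec = _grid_from_config(cfg)
    seeds = cfg["seeds"]
    log.info("stage=simulate grid=%sx%s seeds=%s", spec.n_rows, spec.n_cols, seeds)
    state.stack = syn.generate_landscape(
        spec, cfg["landscape"]["n_layers"], cfg["landscape"]["smoothness"], seeds["landscape"]
    )
    for p in pio.write_stack(out / "layers", state.stack):
        state.register(p, "simulate", seeds["landscape"])
    state.effort = syn.make_effort(spec, cfg["effort"]["kind"], cfg["effort"].get("ratio", 100.0))
    p = pio.write_ascii_grid(out / "effort.asc", state.effort.raster, spec)
    state.register(p, "simulate")

    frames = []
    for i, sp_cfg in enumerate(cfg["species"]):
        sp = syn.generate_virtual_species(
            state.stack,
            sp_cfg["responses"],
            occupancy_threshold=sp_cfg.get("occupancy_threshold", 0.5),
            species_id=sp_cfg["id"],
            foraging_distance=sp_cfg.get("foraging_distance", 1.0),
        )
        state.species_meta[sp.species_id] = {
            "foraging_distance": sp.foraging_distance,
            "occupied_fraction": sp.occupied_fraction,
        }
        p = pio.write_ascii_grid(
            out / f"true_suitability_{_safe(sp.species_id)}.asc", sp.true_suitability, spec
        )
        state.register(p, "simulate")
        frames.append(
            syn.sample_occurrences(
                sp, sp_cfg.get("n_records", 400), state.effort, seed=seeds["sampling"] + i, spec=spec
            )
        )
    state.records = pd.concat(frames, ignore_index=True)
    p = pio.write_occurrence_csv(out / "occurrences.csv", state.records)
    state.register(p, "simulate", seeds["sampling"])

    state.crop_coarse = syn.generate_crop_map(
        spec, cfg["crop"]["n_patches"], cfg["crop"]["patch_radius"], seeds["crop"]
    )
    p = pio.write_ascii_grid(out / "crop_coarse.asc", state.crop_coarse.raster, state.crop_coarse.spec)
    state.register(p, "simulate", seeds["crop"])

    apiaries = syn.generate_apiaries(
        spec, cfg["apiaries"]["n"], cfg["apiaries"]["max_colonies"], seeds["apiaries"]
    )
    apiaries.to_csv(out / "apiaries.csv", index=False)
    state.register(out / "apiaries.csv", "simulate", seeds["apiaries"])
    state.foragers = syn.forager_counts(state.crop_coarse.spec, apiaries)
    p = pio.write_ascii_grid(out / "foragers_coarse.asc", state.foragers, state.crop_coarse.spec)
    state.register(p, "simulate")

    (out / "species_meta.json").write_text(json.dumps(state.species_meta, indent=2))
    state.register(out / "species_meta.json", "simulate")


def _load_simulated(state: PipelineState) -> None:
    out = state.outdir
    layer_dir = out / "layers"
    paths = {p.stem: p for p in sorted(layer_dir.glob("*.asc"))}
    state.stack = pio.read_stack(paths)
    effort, _, _ = pio.read_ascii_grid(out / "effort.asc")
    state.effort = syn.EffortLayer(np.nan_to_num(effort))
    state.records = pio.read_occurrence_csv(out / "occurrences.csv")
    crop, crop_spec, _ = pio.read_ascii_grid(out / "crop_coarse.asc")
    state.crop_coarse = syn.CropMap(np.nan_to_num(crop).astype(np.uint8), crop_spec)
    foragers, _, _ = pio.read_ascii_grid(out / "foragers_coarse.asc")
    state.foragers = np.nan_to_num(foragers)
    meta_path = out / "species_meta.json"
    if meta_path.exists():
        state.species_meta = json.loads(meta_path.read_text())


def stage_prep(state: PipelineState) -> None:
    cfg, out = state.cfg, state.outdir
    if state.stack is None:
        _load_simulated(state)
    spec = state.stack.spec
    min_samples = cfg["sdm"]["min_samples"]
    profiles = []
    for sp_id in state.records["species"].unique():
        grid = occ.grid_records(state.records, spec, species_id=sp_id)
        kept = state.records[
            (state.records["species"] == sp_id) & (state.records["accuracy"] <= 1000.0)
        ]
        profile = occ.species_profile(grid, kept)
        if profile.n_occurrences < min_samples:
            log.warning(
                "stage=prep species=%s skipped: %d occurrences below minimum sample size %d",
                sp_id, profile.n_occurrences, min_samples,
            )
            continue
        state.grids[sp_id] = grid
        profiles.append(profile)
        mask = np.zeros(spec.shape)
        mask[grid.cells[:, 0], grid.cells[:, 1]] = 1.0
        p = pio.write_ascii_grid(out / f"occmask_{_safe(sp_id)}.asc", mask, spec)
        state.register(p, "prep")
    occ.assign_prevalence(profiles)
    state.profiles = {pr.species_id: pr for pr in profiles}
    table = pd.DataFrame(
        [
            {
                "species": pr.species_id,
                "n_records": pr.n_records,
                "n_occurrences": pr.n_occurrences,
                "n_years_nonzero": pr.n_years_nonzero,
                "min_easting": pr.bbox[0],
                "min_northing": pr.bbox[1],
                "max_easting": pr.bbox[2],
                "max_northing": pr.bbox[3],
                "q3_longest_distance": pr.q3_longest_distance,
                "prevalence_tau": pr.prevalence_tau,
            }
            for pr in profiles
        ]
    )
    table.to_csv(out / "profiles.csv", index=False)
    state.register(out / "profiles.csv", "prep")
    log.info("stage=prep species_kept=%d", len(profiles))


def _load_prepped(state: PipelineState) -> None:
    out = state.outdir
    table = pd.read_csv(out / "profiles.csv")
    spec = state.stack.spec
    for _, row in table.iterrows():
        sp_id = row["species"]
        mask, _, _ = pio.read_ascii_grid(out / f"occmask_{_safe(sp_id)}.asc")
        cells = np.column_stack(np.nonzero(np.nan_to_num(mask) > 0))
        state.grids[sp_id] = occ.OccurrenceGrid(sp_id, cells, spec)
        state.profiles[sp_id] = occ.SpeciesProfile(
            species_id=sp_id,
            n_records=int(row["n_records"]),
            n_occurrences=int(row["n_occurrences"]),
            n_years_nonzero=int(row["n_years_nonzero"]),
            bbox=(row["min_easting"], row["min_northing"], row["max_easting"], row["max_northing"]),
            q3_longest_distance=row["q3_longest_distance"],
            prevalence_tau=row["prevalence_tau"],
        )


def stage_sdm(state: PipelineState) -> None:
    cfg, out = state.cfg, state.outdir
    if state.stack is None:
        _load_simulated(state)
    if not state.grids:
        _load_prepped(state)
    sdm = cfg["sdm"]
    seeds = cfg["seeds"]
    spec = state.stack.spec
    if sdm["background_origin"] == "target-group":
        pool = np.unique(
            np.concatenate([g.cells for g in state.grids.values()]), axis=0
        )
        origin = "target-group"
    else:
        pool = spec.all_cells()
        origin = "uniform"
    for i, (sp_id, grid) in enumerate(sorted(state.grids.items())):
        tau = 0.5
        if sdm["tau_mode"] == "profile" and state.profiles[sp_id].prevalence_tau:
            tau = state.profiles[sp_id].prevalence_tau
        background = maxent.sample_background(
            pool, n=sdm["n_background"], seed=seeds["background"] + i, origin=origin
        )
        cv = maxent.cross_validate(
            grid.cells,
            state.stack,
            background,
            k=sdm["k"],
            classes=tuple(sdm["classes"]),
            tau=tau,
            seed=seeds["cv"] + i,
            beta0=sdm["beta0"],
            n_hinge_knots=sdm["n_hinge_knots"],
            min_samples=sdm["min_samples"],
            background_pool=pool,
            predict_all=True,
            species_id=sp_id,
        )
        state.cv_results[sp_id] = cv
        log.info(
            "stage=sdm species=%s tau=%.1f mean_test_auc=%.3f auc_sd=%.3f",
            sp_id, tau, cv.mean_test_auc, cv.auc_sd,
        )
        if sdm["n_null"]:
            null = maxent.null_model_test(
                cv.mean_test_auc,
                grid.n_occurrences,
                spec.all_cells(),
                state.stack,
                background,
                n_null=sdm["n_null"],
                k=sdm["k"],
                classes=tuple(sdm["classes"]),
                tau=tau,
                seed=seeds["null"] + i,
                min_samples=min(sdm["min_samples"], grid.n_occurrences),
                background_pool=pool,
            )
            log.info("stage=sdm species=%s null_p=%.4f", sp_id, null.p_value)
        mean_surface = np.mean(cv.surfaces, axis=0)
        p = pio.write_ascii_grid(out / f"mean_prob_{_safe(sp_id)}.asc", mean_surface, spec)
        state.register(p, "sdm", seeds["cv"] + i)
        for run, surf in enumerate(cv.surfaces):
            p = pio.write_ascii_grid(out / f"runs_{_safe(sp_id)}_{run}.asc", surf, spec)
            state.register(p, "sdm", seeds["cv"] + i)


def stage_ensemble(state: PipelineState) -> None:
    cfg, out = state.cfg, state.outdir
    if state.stack is None:
        _load_simulated(state)
    if not state.grids:
        _load_prepped(state)
    if not state.cv_results:
        raise RuntimeError("ensemble stage needs sdm results; run the sdm stage first")
    spec = state.stack.spec
    pct = cfg["ensemble"]["percentile"]
    for sp_id, cv in state.cv_results.items():
        binaries = [
            ens.training_presence_threshold(surf, cells, spec, percentile=pct)
            for surf, cells in zip(cv.surfaces, cv.fold_train_cells)
        ]
        min_agree = cfg["ensemble"]["min_agree"] or len(binaries)
        cons, mask = ens.consensus(binaries, min_agree=min_agree)
        final = ens.final_suitability(np.mean(cv.surfaces, axis=0), mask)
        state.final_maps[sp_id] = final
        state.capture[sp_id] = ens.capture_fraction(final, state.grids[sp_id])
        p = pio.write_ascii_grid(out / f"consensus_{_safe(sp_id)}.asc", cons.counts, spec)
        state.register(p, "ensemble")
        p = pio.write_ascii_grid(out / f"final_{_safe(sp_id)}.asc", final, spec)
        state.register(p, "ensemble")
        log.info("stage=ensemble species=%s capture_fraction=%.3f", sp_id, state.capture[sp_id])
    (out / "capture_fractions.json").write_text(json.dumps(state.capture, indent=2))
    state.register(out / "capture_fractions.json", "ensemble")


def stage_service(state: PipelineState) -> None:
    cfg, out = state.cfg, state.outdir
    if state.stack is None:
        _load_simulated(state)
    if not state.final_maps:
        finals = sorted(state.outdir.glob("final_*.asc"))
        if not finals:
            raise RuntimeError("service stage needs final maps; run the ensemble stage first")
        for p in finals:
            sp_id = p.stem.removeprefix("final_").replace("_", " ")
            values, _, _ = pio.read_ascii_grid(p)
            state.final_maps[sp_id] = np.nan_to_num(values).astype(float)
    crop_fine = srv.resample_crop(state.crop_coarse)
    svc = cfg["service"]
    per_species = []
    distances = {m_id: m.get("foraging_distance", 1.0) for m_id, m in state.species_meta.items()}
    for sp_id, final in state.final_maps.items():
        a_s = distances.get(sp_id, srv.DEFAULT_FORAGING_DISTANCES.get(sp_id, 1.0))
        sm = srv.service_single_species(
            final, crop_fine, a_s, svc["kernel_radius_factor"], species_id=sp_id
        )
        per_species.append(sm)
        p = pio.write_ascii_grid(out / f"service_{_safe(sp_id)}.asc", sm.values, sm.spec)
        state.register(p, "service")
    compat = svc["compatibility"] or {sm.species_id: 1 for sm in per_species}
    total = srv.total_service(per_species, compat)
    p = pio.write_ascii_grid(out / "service_total.asc", total.values, total.spec)
    state.register(p, "service")
    _, summary = srv.low_service_mask(total, svc["low_quantile"])
    (out / "service_summary.json").write_text(json.dumps(summary, indent=2))
    state.register(out / "service_summary.json", "service")
    log.info("stage=service %s", summary)

    bee = srv.honeybee_layer(state.foragers, state.crop_coarse.spec, svc["absence_percentile"])
    p = pio.write_ascii_grid(out / "honeybee_score.asc", bee.score, bee.spec)
    state.register(p, "service")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "sdm": stage_sdm,
    "ensemble": stage_ensemble,
    "service": stage_service,
}


def run_pipeline(
    cfg: RunConfig, outdir: str | Path, stages: tuple[str, ...] = ALL_STAGES
) -> list[dict]:
    """Execute the requested stages in order and return the artifact manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stages {unknown}")
    state = PipelineState(cfg=cfg, outdir=outdir)
    for stage in ALL_STAGES:
        if stage in stages:
            try:
                _STAGE_FUNCS[stage](state)
            except Exception:
                log.error("stage=%s failed; pipeline halted", stage)
                state.write_manifest()
                raise
    state.write_manifest()
    return state.manifest
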