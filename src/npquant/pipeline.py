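"""End-to-end driver: simulate -> (deconvolve) -> segment -> count -> dose report.

Every stage logs its object counts so the per-cell summaries are auditable,
and every artifact is written together with a provenance record (config hash,
seed, library versions).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import agglomerates, dose, synthetic
from .cellmask import segment_cell
from .detect import classify_inside, detect_particles, objects_to_dataframe, summarize
from .dosimetry import MediumSpec, ParticleSpec, simulate_deposition
from .io import provenance_record, save_config, write_objects, write_stack
from .preprocess import gaussian_psf, richardson_lucy

log = logging.getLogger("npquant")


@dataclasses.dataclass
class RunConfig:
    """Parameters of one simulated exposure-and-counting experiment.

    Defaults are the reference acquisition and processing settings: ball
    radius 2 voxels for the open-close step, watershed sigma 2.0 um, 5%
    intensity discard, particle density 1.8 g cm^-3, 5 h exposure of 1 mL
    over a 5 mm column.
    """

    seed: int = 0
    # scene
    n_inside: int = 117
    n_outside: int = 30
    particle_diameter_nm: float = 85.0
    cluster_sizes: tuple[int, ...] = (1,)
    emitter_brightness: float = 2.0e4
    margin_nm: float = 600.0
    min_separation_nm: float = 350.0
    cell_semiaxes_um: tuple[float, float, float] = (10.0, 8.0, 5.0)
    nucleus_semiaxes_um: tuple[float, float, float] = (4.0, 3.2, 2.0)
    # preprocessing
    deconvolve: bool = False
    rl_iterations: int = 40
    # segmentation / detection
    structuring_radius: int = 2
    watershed_sigma_um: float = 2.0
    discard_fraction: float = 0.05
    # exposure / dosimetry
    administered_per_ml: float = 9.2e10
    particle_density_g_cm3: float = 1.8
    exposure_h: float = 5.0
    medium: MediumSpec = dataclasses.field(default_factory=MediumSpec)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["medium"] = dataclasses.asdict(self.medium)
        return d


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full workflow and write all artifacts under ``outdir``.

    Returns the result dictionary (per-cell summary, agglomerate estimates,
    dose report, provenance).  Deterministic for a fixed config and seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    phantom = synthetic.build_phantom(
        cell_semiaxes_um=config.cell_semiaxes_um,
        nucleus_semiaxes_um=config.nucleus_semiaxes_um,
    )
    emitters = synthetic.sample_particles(
        phantom,
        n_inside=config.n_inside,
        n_outside=config.n_outside,
        particle_diameter_nm=config.particle_diameter_nm,
        cluster_sizes=list(config.cluster_sizes),
        brightness=config.emitter_brightness,
        margin_nm=config.margin_nm,
        min_separation_nm=config.min_separation_nm,
        seed=config.seed,
    )
    scene = synthetic.simulate_scene(phantom, emitters, seed=config.seed)
    gt = scene["ground_truth"]
    log.info("scene: %d emitters (%d inside), %d expected inside objects",
             len(emitters), gt.n_inside, gt.n_expected_objects_inside)

    np_grid = scene["nanoparticle"]
    if config.deconvolve:
        psf = gaussian_psf(synthetic.STED)
        np_grid = richardson_lucy(np_grid, psf, iterations=config.rl_iterations)
        log.info("deconvolved NP channel: %d iterations, flux change %.3g",
                 config.rl_iterations, np_grid.meta.get("flux_change", 0.0))

    mask = segment_cell(scene["membrane"], structuring_radius=config.structuring_radius)
    log.info("cell mask: %.0f um^3, projected %.0f um^2 (threshold %.1f)",
             mask.volume_um3, mask.projected_area_um2, mask.provenance["threshold"])

    objects = detect_particles(
        np_grid,
        watershed_sigma_um=config.watershed_sigma_um,
        discard_fraction=config.discard_fraction,
    )
    log.info("detected %d objects after the discard rule", len(objects))
    objects = classify_inside(objects, mask.on_grid(np_grid), np_grid)
    summary = summarize(objects, mask)
    log.info("inside objects: %d (%.3g per um^2)",
             summary.n_objects_inside, summary.objects_per_um2)

    inside_widths = [o.lateral_width_nm for o in objects if o.inside]
    agg = (
        agglomerates.total_particles(inside_widths, config.particle_diameter_nm)
        if inside_widths
        else None
    )

    particle = ParticleSpec(config.particle_diameter_nm, config.particle_density_g_cm3)
    deposition = simulate_deposition(
        particle, config.medium, duration_h=config.exposure_h,
        concentration_per_ml=config.administered_per_ml,
    )
    report = dose.build_dose_report(
        diameter_nm=config.particle_diameter_nm,
        density_g_cm3=config.particle_density_g_cm3,
        administered_per_ml=config.administered_per_ml,
        delivered_fraction=deposition.fraction,
        column_height_cm=config.medium.height_cm,
        internalized_per_cell=summary.n_objects_inside,
        cell_volume_um3=phantom.volume_um3,
        cell_area_um2=mask.projected_area_um2,
    )

    # ---- artifacts ---------------------------------------------------------
    for name in ("nanoparticle", "membrane", "lamina"):
        write_stack(scene[name], out / f"{name}.tif")
    gt.to_csv(out / "ground_truth.csv")
    write_objects(objects_to_dataframe(objects), out / "objects.csv")
    result = {
        "summary": dataclasses.asdict(summary),
        "ground_truth": {
            "n_inside_emitters": gt.n_inside,
            "n_expected_objects_inside": gt.n_expected_objects_inside,
        },
        "agglomerates": agg.summary() if agg else None,
        "deposition": {
            "fraction": deposition.fraction,
            "per_area_cm2": deposition.per_area_cm2,
            **deposition.diagnostics,
        },
        "dose_report": report.as_dict(),
        "provenance": provenance_record(config.as_dict(), config.seed),
    }
    with open(out / "result.json", "w") as fh:
        json.dump(result, fh, indent=2, default=float)
    save_config(config.as_dict(), out / "config.yaml")
    return result
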