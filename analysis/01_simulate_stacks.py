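#!/usr/bin/env python
"""Generate the two ground-truthed exposure scenes.

One adherent-cell phantom per particle size, with the per-cell internalized
object counts set to the study's per-cell means (117 objects for 25 nm
particles, 338 for 85 nm) plus 20 membrane-attached particles each.  The
nanoparticle channel is rendered in STED mode, membrane and lamina in
confocal mode.  TIFF stacks go to scratch/ (large, binary); the ground-truth
emitter tables go to results/.
"""

import sys
import time
from pathlib import Path

from npquant import synthetic as syn
from npquant.io import write_stack

ROOT = Path(__file__).resolve().parents[1]
CONDITIONS = {
    # name: (n_inside, particle diameter nm, emitter brightness)
    "si25": (117, 25.0, 1.2e4),
    "si85": (338, 85.0, 2.0e4),
}


def main(seed: int = 1) -> None:
    out_tables = ROOT / "results" / "stacks"
    out_stacks = ROOT / "scratch" / "stacks"
    out_tables.mkdir(parents=True, exist_ok=True)
    for name, (n_inside, diameter, brightness) in CONDITIONS.items():
        t0 = time.time()
        phantom = syn.build_phantom()
        emitters = syn.sample_particles(
            phantom, n_inside=n_inside, n_outside=20,
            particle_diameter_nm=diameter, brightness=brightness,
            margin_nm=600.0, min_separation_nm=4.0 * syn.STED.lateral_fwhm_nm,
            seed=seed,
        )
        scene = syn.simulate_scene(phantom, emitters, seed=seed)
        stack_dir = out_stacks / name
        stack_dir.mkdir(parents=True, exist_ok=True)
        for channel in ("nanoparticle", "membrane", "lamina"):
            write_stack(scene[channel], stack_dir / f"{channel}.tif")
        gt = scene["ground_truth"]
        gt.to_csv(out_tables / f"{name}_ground_truth.csv")
        print(
            f"{name}: {len(emitters)} emitters ({gt.n_inside} inside, "
            f"{gt.n_expected_objects_inside} expected inside objects), "
            f"NP stack {scene['nanoparticle'].shape}, {time.time() - t0:.0f}s"
        )
    print(f"stacks -> {out_stacks}, ground truth -> {out_tables}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
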