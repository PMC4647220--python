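#!/usr/bin/env python
"""Convert the simulated dynamic PET volumes into B'max densities.

For each subject: sum frames 8-12 into the static image, fit the
partial-saturation Scatchard line (free ligand from the pons, bound range
from the occipital ROI across frames), build the B'max parametric image,
smooth with the 15 x 15 x 21 mm kernel, and aggregate the total receptor
density over the unique V1-PET voxel set plus the whole-brain control.
Writes results/density.csv and results/confounds.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gabagamma import io
from gabagamma.containers import PETDynamic
from gabagamma.gaba_gamma_stats import gm_density_confound
from gabagamma.geometry import CohortGeometry
from gabagamma.pet_parametric import (bmax_map, fit_scatchard, smooth_map,
                                      static_image, total_density,
                                      v1_total_density)
from gabagamma.synthetic_cohort import (CohortConfig, make_cohort,
                                        simulate_gm_map)

SIM = Path("results/sim")
OUT = Path("results")
SEED = 42  # must match 01_simulate_cohort.py


def main() -> None:
    geom = CohortGeometry.reduced()
    config = CohortConfig.calibrated(geom, seed=SEED)
    subjects = {s.subject_id: s for s in make_cohort(config, geom)}
    dens_rows, conf_rows = [], []
    for nii in sorted(SIM.glob("pet_S*.nii.gz")):
        subject_id = nii.name.split("_")[1].split(".")[0]
        vol, pg = io.load_volume(nii)
        meta = json.loads(nii.with_suffix("").with_suffix(".json").read_text())
        dyn = PETDynamic(np.moveaxis(vol, -1, 0),
                         np.array(meta["frame_times_min"]), geom.pet,
                         geom.roi_pons, geom.roi_occipital, geom.v1_pet)
        fit = fit_scatchard(dyn)
        bmap = smooth_map(bmax_map(static_image(dyn), fit))
        io.save_volume(SIM / f"bmax_{subject_id}.nii.gz", bmap.values, geom.pet)
        dens_rows.append({
            "subject_id": subject_id,
            "total_v1_bmax": v1_total_density(bmap, geom.v1_mr_coords,
                                              geom.pet),
            "total_brain_bmax": total_density(
                bmap, np.arange(geom.pet.n_voxels)),
            "kd_app": fit.kd_app, "free_conc": fit.free_conc,
            "fit_r2": fit.fit_r2,
        })
        subj = subjects[subject_id]
        rng = np.random.default_rng((config.seed, int(subject_id[1:]) - 1))
        gm = simulate_gm_map(subj, geom, rng)
        conf_rows.append({"subject_id": subject_id,
                          "v1_surface_area_mm2": subj.v1_surface_area,
                          "gm_density": gm_density_confound(gm, geom.v1_pet)})
        print(f"{subject_id}: kd_app {fit.kd_app:.2f}, "
              f"V1 total {dens_rows[-1]['total_v1_bmax']:.0f}")
    pd.DataFrame(dens_rows).to_csv(OUT / "density.csv", index=False)
    pd.DataFrame(conf_rows).to_csv(OUT / "confounds.csv", index=False)
    print(f"wrote {OUT / 'density.csv'} and {OUT / 'confounds.csv'}")


if __name__ == "__main__":
    main()
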