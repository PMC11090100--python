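"""Run the entire analysis end-to-end on a small synthetic dataset.

Harmonization -> per-seed interaction GLMs -> permutation TFCE-FWE ->
Meff-adjusted masks -> union mask -> target ROIs -> fingerprints with
per-center and sex-stratified validation -> clinical association, with every
artifact written to disk and listed (with SHA-256 hashes) in a manifest.
"""

import tempfile
from pathlib import Path

from amycov import (GridSpec, PlantedEffect, RunConfig, TruthSpec,
                    generate_cohort, generate_gmv_stack,
                    generate_parcellation, generate_seed_volumes,
                    run_pipeline)
from amycov.tfce import TFCEParams

grid = GridSpec()
cohort = generate_cohort(40, 3, rng_seed=7)
seeds = generate_seed_volumes(cohort, rng_seed=17)
truth = TruthSpec(effects=(PlantedEffect("L_AAA", 0.08, 0.0),), sigma=0.3)
stack, gt = generate_gmv_stack(cohort, seeds, truth, grid, rng_seed=7)
parc = generate_parcellation(grid, 60, rng_seed=77)

out = Path(tempfile.mkdtemp(prefix="amycov_run_"))
config = RunConfig(output_dir=out, rng_seed=7,
                   seeds=("L_AAA", "R_CAT"), n_perm=300,
                   tfce=TFCEParams(n_steps=50))
manifest = run_pipeline(config, stack, cohort, seeds, parc)

print(f"output directory: {out}")
print(f"Meff = {manifest['meff']:.2f} -> adjusted alpha "
      f"= {manifest['adjusted_alpha']:.4f}")
print(f"significant seeds: {manifest['significant_seeds']}")
print(f"target ROIs: {manifest['target_rois']}")
print(f"artifacts written: {len(manifest['artifacts'])}")
print("The planted L_AAA cluster drives the selected target ROIs; "
      "correlated seeds (here R_CAT, r ~ 0.5 with L_AAA) can share the "
      "disrupted covariance and reach significance too.")
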