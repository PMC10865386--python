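"""Choose the SVD truncation rank with the 30% validation rule.

On noiseless data whose snapshot matrix has rank exactly 5 (latent
dimension 4 plus one impulse-input row) the scan should land on V=5
with vanishing validation error; with measurement noise the selected
rank stays parsimonious.
"""

import numpy as np

from pdmdc import (
    DietInputMatrix,
    PopulationSpec,
    generate_population,
    standardize_per_diet,
    subtract_baseline,
)
from pdmdc.evaluation import select_rank
from pdmdc.parametric import concat_response_snapshots, tensor_observations


def build_instance(noise_sd, seed=11):
    spec = PopulationSpec(M=8, T=8, I=1, D=6, S_true=4, l=1, noise_sd=noise_sd,
                          within_cluster_cv=0.0, baseline_sd=0.0,
                          diet_mean=(100.0,), diet_sd=(20.0,), seed=seed)
    tensor, diets, _ = generate_population(spec)
    proc, scales = standardize_per_diet(subtract_baseline(tensor), mode="pooled")
    diets = DietInputMatrix(diets.inputs / scales[0][None, :],
                            diets.input_names, diets.diet_ids)
    keys = [(i, d) for i in proc.individual_ids for d in proc.diet_ids]
    ms = concat_response_snapshots(tensor_observations(proc, diets, keys[:4]))
    return ms, tensor_observations(proc, diets, keys[4:])


for noise in (0.0, 0.05):
    snapshots, val_obs = build_instance(noise)
    model, V, diag = select_rank(snapshots, val_obs)
    print(f"noise_sd = {noise}:")
    for rank, rmse_train, rmse_val in diag["visited"]:
        marker = " <- selected" if rank == V else ""
        print(f"  V={rank}: train RMSE {rmse_train:.2e}, "
              f"val RMSE {rmse_val:.2e}{marker}")
    print(f"  selected rank {V} "
          f"({'stopped early' if diag['stopped_early'] else 'full scan'})")
print("On noiseless rank-5 data the validation error collapses at V=5;")
print("with noise the scan stops once validation deviates from training.")
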