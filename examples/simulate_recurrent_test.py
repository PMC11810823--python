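"""Simulate a small recurrent test and look at the working datasets.

Daughters of each test sire are housed together in half-sib cages; feather
score (10 intact / 15 damaged / 20 bald patches) is generated from a
Gaussian liability cut at calibrated thresholds, and survival to each
scoring age is genetically correlated with feather score.
"""

from featherblup import SimConfig, simulate_dataset

config = SimConfig(n_sires=100, seed=1)
sim = simulate_dataset(config)

ind, cages = sim.individuals, sim.cages
print(f"{len(ind)} birds in {len(cages)} cages from {config.n_sires} sires\n")

print("realized vs target descriptives:")
print(f"  survival 45 wk : {100 * (ind.surv45 == 2).mean():5.1f}%  (target 98%)")
print(f"  survival 70 wk : {100 * (ind.surv70 == 2).mean():5.1f}%  (target 94%)")
for trait, target in [("back45", 11.32), ("neck45", 12.42), ("back70", 13.98), ("neck70", 14.78)]:
    print(f"  mean FS {trait:7s}: {ind[f'fs_{trait}'].mean():6.2f}  (target {target})")

print("\none cage-level record (what the cage-level models consume):")
print(cages.iloc[0][["cage_id", "sire_id", "n_original", "surv_frac45",
                     "mean_back45", "representative_animal_id"]].to_string())
print("\nThe cage mean is the average score of survivors; the representative")
print("animal is the random member that carries the record in the CUAM model.")
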