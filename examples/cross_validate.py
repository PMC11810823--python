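"""Cage-masked cross-validation of estimated sire effects.

Folds mask whole cages; the masked cages' fixed-effect-corrected mean
scores serve as proxies for the true sire effects.  Accuracy is the fold
correlation divided by the analytic correlation between true sire effects
and cage proxies; the dispersion slope compares the spread of the
estimates to the phenotypes (1 = correctly dispersed BLUP).
"""

from featherblup import ModelData, SimConfig, cross_validate, simulate_dataset

sim = simulate_dataset(SimConfig(n_sires=100, seed=1))
data = ModelData.from_sim(sim)

res = cross_validate(
    data, "CUSiM", "BACK45", k=10, seed=1, component_model="IUSiM"
)

print(res.folds.round(3).to_string(index=False))
print(f"\naccuracy          : {res.accuracy:.3f}  "
      "(corrected correlation with true sire effects)")
print(f"expected accuracy : {res.mean_expected_accuracy:.3f}  "
      "(from the cage-level formula and fitted components)")
print(f"dispersion slope  : {res.mean_slope:.3f} +- {res.se_slope:.3f}  "
      "(1 = correct scale; < 1 over-dispersed)")
print(f"mean T2           : {res.mean_T2:.3f}  "
      "(total heritable variance / phenotypic variance)")
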