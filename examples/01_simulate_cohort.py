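"""Simulate a small BrainSpan-like cohort and inspect its structure.

Generates 20 donors (3 of them sparsely sampled), ~500 genes with a
planted target-gene trajectory and +/-0.8 co-expression modules, then
prints what the specimen-inclusion rule keeps.
"""

from cbrel import select_specimens
from cbrel.synth import SimulationConfig, calibrate_effects, simulate

cfg = SimulationConfig(
    n_donors=20,
    n_sparse_donors=3,
    n_null_genes=500,
    n_positive_module=15,
    n_negative_module=15,
    seed=1,
)
effects = calibrate_effects(cfg)
ds, truth = simulate(cfg, effects)

print(f"cohort: {len(ds.genes)} genes x {ds.values.shape[1]} (donor, region) samples")
print(f"module loadings: +{effects.loading_positive:.3f} / {effects.loading_negative:.3f}")

included, excluded = select_specimens(ds)  # cerebellum + >= 4 other regions
print(f"included {len(included.specimens)} of {cfg.n_donors} donors")
for e in excluded:
    print(f"  excluded {e.donor_id}: {e.reason}")
print("ages span", included.specimens[0].age.raw_label,
      "to", included.specimens[-1].age.raw_label)
# The exclusions come from the sparse donors: heavy region dropout costs
# them either the cerebellar sample or the 4-other-region minimum.
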