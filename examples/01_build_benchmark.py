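"""Build the synthetic reactive benchmark and inspect its energetics.

Constructs the 8-atom double-well H-transfer surface (rigid-scan barrier
calibrated to 20 kcal/mol, product well +5 kcal/mol above the reactant),
samples a capped training set, and reports the held-out region.
"""

import numpy as np

from pesuq import SamplerConfig, ToyPES, default_params, make_benchmark

pes = ToyPES(default_params())
barrier, asymmetry = pes.rigid_scan_barrier()
print(f"rigid-scan barrier      : {barrier:.3f} kcal/mol")
print(f"well asymmetry          : {asymmetry:.3f} kcal/mol")
print(f"transfer coordinate q at reactant/saddle/product: "
      f"{pes.transfer_coordinate(pes.reactant_geometry):+.3f} / "
      f"{pes.transfer_coordinate(pes.saddle_geometry):+.3f} / "
      f"{pes.transfer_coordinate(pes.product_geometry):+.3f} Å")
lo, hi = pes.default_ood_window()
print(f"held-out window on q    : ({lo:+.3f}, {hi:+.3f}) Å")

config = SamplerConfig(n_samples=500, seed=1)
trainval, test, flags = make_benchmark(pes, config, n_test_id=200,
                                       n_test_ood=50)
rel = trainval.energies() - pes.min_energy
print(f"\ntrain/validation        : {len(trainval)} structures, "
      f"relative energies {rel.min():.1f}-{rel.max():.1f} kcal/mol "
      f"(cap {config.energy_cap:.0f})")
print(f"test set                : {len(test)} structures, "
      f"{int(flags.sum())} inside the held-out transition-state window")
# The flagged structures are the ground-truth outliers: geometries the
# training distribution never covers, at moderate (not maximal) energies.
e_test = test.energies() - pes.min_energy
print(f"median relative energy  : in-distribution {np.median(e_test[~flags]):.1f}, "
      f"held-out {np.median(e_test[flags]):.1f} kcal/mol")
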