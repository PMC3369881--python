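"""Score transcript periodicity with DFT features on simulated raw intensities.

Simulates one multi-cycle oscillation experiment, computes per-gene
amplitudes, phase angles, scaled amplitudes and permutation p-values at the
phenotypic cycle number, and prints the strongest oscillators.
"""

import numpy as np

from oscillome import OscillomeSpec, fourier_features, generate_oscillome

spec = OscillomeSpec(n_genes=300, seed=1)
exp1, exp2, truth = generate_oscillome(spec)
print(f"experiment 1: {exp1.matrix.shape[0]} genes x {exp1.matrix.shape[1]} samples, "
      f"period {exp1.period} h, {exp1.k_osc} phenotypic cycles")

feats = fourier_features(exp1.matrix, k_osc=exp1.k_osc, n_permutations=199, seed=2)
top = feats.sort_values(f"S_{exp1.k_osc}", ascending=False).head(5)
print("\nstrongest oscillators (S = scaled amplitude, phase in degrees):")
for gene, row in top.iterrows():
    print(f"  {gene}  S={row[f'S_{exp1.k_osc}']:6.2f}  "
          f"phase={np.rad2deg(row[f'phi_{exp1.k_osc}']) % 360:6.1f}  "
          f"p_perm={row.p_perm:.3f}  planted={truth.loc[gene, 'cohort']}")

sig = (feats.p_perm <= 0.05).mean()
print(f"\n{sig:.0%} of genes significantly periodic at p<=0.05 "
      f"(70% of genes carry a planted oscillation; the scaled amplitude is "
      f"normalization-free, so raw intensities can be used directly)")
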