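"""Evolve the two-gene model until it acquires phenotypic plasticity.

Runs the simplified preset with the environment switching every
generation (IT = 1).  A short verification window keeps this demo to
about a minute; the headline analyses use the standard 1e5-generation
window.
"""

import plastevo as pv

params = pv.preset("simplified", IT=1, T_max=400_000)
record = pv.run(params, seed=42, threshold=0.95, window=5_000)

print("success:", record.success)
print("acquisition generation Tp:", record.acquisition_generation)
print("final generation:", record.final_generation)
for g in (0, record.acquisition_generation, record.final_generation):
    print(f"  T={g:>8}: mean w1 = {record.mean_w1[g]:.3f}, "
          f"mean w2 = {record.mean_w2[g]:.3f}")
# Both environment-wise mean fitnesses start near exp(-1) ~ 0.37 and end
# near 1: the population now develops the E1-optimal phenotype when grown
# in E1 and the E2-optimal one in E2, from the same genotypes.
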