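"""Reaction norms along a sensor gradient: is the plasticity discrete?

Grows genotypes at 101 sensor activation levels between fully off (E2)
and fully on (E1) and counts intermediate phenotypes: those fitting
neither optimum well (both w1 and w2 below 0.95).
"""

import numpy as np

import plastevo as pv

fx = pv.make_fixture("bistable_diag")
res = pv.discreteness_assay(fx.genotype, fx.params, grid_size=101)

print("bistable switch genotype:")
print("  intermediate fraction:", res.intermediate_fraction)
print("  discrete (< 5%):", res.is_discrete)
w1, w2 = res.fitness_curves[0, :, 0], res.fitness_curves[0, :, 1]
flip = int(np.argmax(w1 > w2))
print(f"  reaction norm flips between levels "
      f"{res.levels[flip - 1]:.2f} and {res.levels[flip]:.2f}")
# The adult phenotype jumps from the E2 optimum to the E1 optimum between
# two adjacent gradient levels: essentially no environment produces an
# intermediate phenotype, the signature of discrete plasticity.

ancestor = pv.Genotype.initial(pv.preset("full_default"))
res0 = pv.discreteness_assay(ancestor, pv.preset("full_default"),
                             grid_size=101)
print("\nancestral genotype:")
print("  intermediate fraction:", res0.intermediate_fraction)
# The unevolved network produces the same mediocre phenotype everywhere:
# every (genotype, level) pair is intermediate.
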