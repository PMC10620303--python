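"""Build the per-genotype reaction-diffusion systems of one simulated cross.

Loads the packaged admissible parameter set (the complete heritable
description of an F1 hybrid), enumerates the F2 genotypes of a selfed F1,
and shows how each genotype inherits a subset of the 16 binding constants
and contracts to a 2-, 3- or 4-species system.
"""
from turingcross import (
    F2_GENOTYPES,
    count_kappa,
    enumerate_f2,
    genotype_system,
    load_fixture,
)

params = load_fixture("admissible").params

print("F2 genotype distribution from selfing the F1 (U:AB,V:AB):")
for genotype, prob in enumerate_f2().genotypes:
    print(f"  {genotype}  probability {prob}")

print("\nPer-genotype systems (species count after contracting homozygous loci,")
print("and how many of the F1's 16 binding constants the genotype uses):")
for genotype in F2_GENOTYPES:
    system = genotype_system(params, genotype)
    print(
        f"  {genotype}: {system.n_species} species {system.names},"
        f" kappa used = {count_kappa(genotype)}"
    )

# The two parents and the F1 are the corner/center entries of the 3x3 grid;
# doubly homozygous genotypes contract to the classic 2-species
# activator-inhibitor form with doubled production terms.
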