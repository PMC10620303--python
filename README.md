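# turingcross

A multigenerational, explicitly diploid Turing model of petal pigmentation
patterning in hybrid monkeyflowers (*Mimulus*), for theorists and
quantitative geneticists studying how crossing two unpatterned inbred lines
can produce spotted — transgressive — offspring.

## The model

Anthocyanin spots are laid down by an activator–inhibitor gene regulatory
network at two unlinked loci: an activator `u` (an R2R3-MYB–containing
complex, short range) and an inhibitor `v` (an R3-MYB, faster-diffusing).
The haploid network is the reaction–diffusion system

```
∂u/∂t = D_u ∇²u + α_u − β_u u + γ_u ( κ_uu u / (1 + κ_uu u + κ_uv v) )²
∂v/∂t = D_v ∇²v + α_v − β_v v + γ_v ( κ_vu u / (1 + κ_vu u + κ_vv v) )²
```

where the squared Hill terms describe competitive binding of activator and
inhibitor to a pair of identical, independent regulatory sites, and the
κ's are equilibrium association constants (first subscript: the regulated
gene product; second: the binding TF).

Diploidy duplicates each locus: the four gene products (u, v, û, v̂) carry
per-allele rate constants α, β, γ (superscripts A/B) and 16 binding
constants κ_xy^PQ — the affinity of the allele-Q copy of TF y for the
site regulating the allele-P copy of product x.  Mendelian inheritance is
parameter bookkeeping: the doubly heterozygous F1 defines the full set;
homozygous parents use the 4 all-A (or all-B) constants, and the nine F2
genotypes of a selfed F1 use 4, 9 or 16 of them.  At a homozygous locus
the two identical gene products can be summed ("contraction"), doubling
the zeroth-order rates α and γ while leaving β unchanged.

Pattern formation follows standard Turing analysis: a genotype patterns
when its reaction Jacobian is stable but J − k² diag(D) is unstable for
some spatial frequency k, which requires the diffusion ratio d = D_v/D_u
to exceed a genotype-specific critical value d★.  A *cross* is admissible
for transgressive patterning when

```
d★(F1)  <  d  <  min( d★(parent A), d★(parent B) )
```

— one diffusion ratio, uniform parents, spotted hybrid.  In the limit of
phenotypically identical parents the F1 differs only through the trans/cis
binding-efficacy ratios m_xy = κ_xy^trans / κ_xy^cis ∈ [0, 1); weakening
the cross-regulatory pathways (m_vu or m_uv) lowers d★ and is the
mechanism by which two identical unpatterned parents yield a spotted F1.

## Worked example

```
$ python examples/02_stability_analysis.py
working diffusion ratio d = D_v/D_u = 49.453

parent A (U:AA,V:AA): steady state (0.315, 0.988)
   d_star = 65.103;  max growth rate at d: -0.0426 (stable - uniform)
parent B (U:BB,V:BB): steady state (0.674, 0.112)
   d_star = 205.225;  max growth rate at d: -0.2044 (stable - uniform)
F1 (U:AB,V:AB): steady state (0.244, 0.559, 0.134, 0.0173)
   d_star = 37.564;  max growth rate at d: +0.0464 (Turing UNSTABLE - patterns)

admissibility verdict: True (d_star_F1 = 37.56 < d = 49.45 < min parent d_star = 65.10)
```

Both parents sit below their Turing thresholds (all spatial modes decay;
solid petal color), while the F1's fastest mode grows at rate +0.046 —
simulated on a 2D domain it produces red spots on a yellow background:

```
$ python examples/04_simulate_f1_pattern.py
parent A: patterned=False, spatial CV=1.94e-04 (uniform petal)
F1: max linear growth rate +0.0464 at k=0.393 (predicted wavelength 16.0)
F1: patterned=True, 39 spots, measured wavelength 16.0, activator range [0.21, 1.54]
wrote f1_pattern.png (total activator, yellow-to-red)
```

The measured spot wavelength equals the linear prediction 2π/k_max, and
the spot maxima (1.54) exceed both parents' uniform activator levels — the
phenotype is transgressive.  The other examples cover genotype
enumeration (`01`), random search for admissible parameter sets (`03`) and
the trans-efficacy sweeps of the symmetric-parent mechanism (`05`).

A thin CLI wraps the same pipeline:

```
turingcross search --seed 11 --out params.json
turingcross stability --params params.json --genotype U:AB,V:AB
turingcross simulate --params params.json --genotype U:AB,V:AB --outdir run/
turingcross f2grid --params params.json --outdir grid/
turingcross msweep --params symmetric.json --which vu --outdir sweep/
```

## Packaged parameter sets

Two admissible parameter sets ship under `turingcross/data/`, both produced
by the package's own seeded search (`turingcross.fixtures` documents the
deterministic curation rules; `scripts/regenerate_fixtures.py` rebuilds
them byte-for-byte).  `load_fixture("admissible")` is a general cross with
distinct parents; `load_fixture("symmetric")` has identical parents and a
reduced trans efficacy m_vu = 0.3.

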