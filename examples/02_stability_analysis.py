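"""Linear stability analysis: dispersion relations and critical ratios.

For the packaged cross, computes each core genotype's uniform steady
state, the growth rate of spatial modes at the working diffusion ratio d,
and the critical ratio d_star at which the Turing bifurcation occurs.
The admissibility window d_star(F1) < d < min(d_star(A), d_star(B)) is
what makes the parents uniform and the hybrid spotted.
"""
import numpy as np

from turingcross import (
    F1,
    PARENT_A,
    PARENT_B,
    check_admissibility,
    critical_diffusion_ratio,
    dispersion,
    find_steady_state,
    genotype_system,
    load_fixture,
)

params = load_fixture("admissible").params
d = params.d
print(f"working diffusion ratio d = D_v/D_u = {d:.3f}\n")

for label, genotype in (("parent A", PARENT_A), ("parent B", PARENT_B), ("F1", F1)):
    system = genotype_system(params, genotype)
    ss = find_steady_state(system)
    dstar = critical_diffusion_ratio(system, ss)
    curve = dispersion(system, ss, d=d, k_grid=np.linspace(0, 1.5, 300))
    sigma = curve.max_growth
    state = ", ".join(f"{c:.3g}" for c in ss.concentrations)
    print(f"{label} ({genotype}): steady state ({state})")
    print(
        f"   d_star = {dstar:.3f};  max growth rate at d: {sigma:+.4f}"
        f" ({'Turing UNSTABLE - patterns' if sigma > 0 else 'stable - uniform'})"
    )

report = check_admissibility(params)
print(
    f"\nadmissibility verdict: {report.verdict} "
    f"(d_star_F1 = {report.d_star_F1:.2f} < d = {report.d_used:.2f} "
    f"< min parent d_star = {min(report.d_star_A, report.d_star_B):.2f})"
)
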