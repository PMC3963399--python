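"""Cross-rate correlations in simulated eye populations.

Treats each grid point of a parameter sweep as an individual eye and
correlates its end-of-infusion elevations across rates.  A population that
differs only in instantaneous modulus produces perfectly linear cross-rate
relationships (the volume constraint makes the pressure affine in any
modulus), while a population that differs in a relaxation time constant
produces genuinely curved ones -- the quadratic-fit residual reduction
quantifies that curvature.
"""

from iopsim import OracleEngine, population_from_sweep
from iopsim.studies import PARAMETER_SPECS

engine = OracleEngine()

for name in ("instantaneous_modulus", "equilibrium_modulus", "long_time_constant"):
    pop = population_from_sweep(PARAMETER_SPECS[name], engine, n_eyes=5)
    fit = pop.fits.set_index(["x", "y"])
    r_fi = pop.correlation.loc["fast", "intermediate"]
    r_fs = pop.correlation.loc["fast", "slow"]
    gain = fit.loc[("fast", "slow"), "quadratic_ss_reduction"]
    print(
        f"{name:>24s}: R(fast, intermediate) = {r_fi:.4f}, R(fast, slow) = {r_fs:.4f}, "
        f"quadratic SS reduction (fast-slow) = {gain:+.3f}"
    )

print(
    "\nmodulus-varied populations are exact straight lines (R = 1); only the"
    "\ntime-constant populations bend, because tau enters the response nonlinearly"
)
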