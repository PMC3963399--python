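"""Closed-loop test: synthesize a porcine-like population, then recover it.

Generates eleven synthetic eyes (log-normal 20% scatter on the
instantaneous modulus, 0.5 mmHg measurement noise on each dIOP reading at
11 volume levels x 3 rates), calibrates the four viscoelastic parameters
per eye by bounded least squares against the closed-form engine, and
reports how well the hidden stiffnesses are recovered.
"""

import numpy as np

from iopsim import OracleEngine, PopulationSpec, calibrate_parameters, generate_population

engine = OracleEngine()
dataset = generate_population(PopulationSpec(n_eyes=11, seed=7), engine)
dataset.save("scratch/synthetic_population")

true = dataset.true_parameters["instantaneous_modulus"].to_numpy()
estimates = []
for eye in range(11):
    cal = calibrate_parameters(dataset.eye_curves(eye), engine)
    estimates.append(cal.parameters["instantaneous_modulus"])
    flag = f"  weakly identifiable: {cal.weakly_identifiable}" if cal.weakly_identifiable else ""
    print(
        f"eye {eye:2d}: true E_inst = {true[eye]:.3f} MPa, "
        f"estimated {estimates[-1]:.3f} MPa, residual {cal.residual_norm:.2f} mmHg{flag}"
    )

r = np.corrcoef(true, estimates)[0, 1]
print(f"\nPearson R(true, estimated E_inst) = {r:.3f} over 11 eyes")
print("dataset and hidden parameters written to scratch/synthetic_population/")
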