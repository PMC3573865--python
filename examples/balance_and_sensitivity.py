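"""Balance primer concentrations and read the assay's limit of detection.

With standardised templates (equal copies per target), signal differences
reflect primer efficiency. The balancer nudges concentrations in 0.1 µM
steps until all targets sit within ±25% of the panel median; the LOD is
the smallest copy number detected (>= 0.1 RFU) in every replicate.
"""

import tempfile

from plexcal import BalanceState, lod_from_grid, run_balancing
from plexcal.balancing import CONDITIONS
from plexcal.fixtures import generate_fixture, toy_response_model
from plexcal.io import read_readings

# --- balancing against a monotone response (stand-in for a bench PCR) ------
eff, start = toy_response_model(seed=11)
response = lambda conc: {t: eff[t] * conc[t] for t in conc}
state = BalanceState(concentrations=start, signals=response(start))
outcome = run_balancing(state, response)
print(f"balanced after {outcome.iterations} adjustment rounds")
for t in sorted(start):
    print(f"  {t:<22} {start[t]:.1f} -> {outcome.final_state.concentrations[t]:.1f} uM")

# --- LOD from the synthetic sensitivity grid --------------------------------
with tempfile.TemporaryDirectory() as tmp:
    fx = generate_fixture(tmp, seed=1)
    readings = read_readings(fx.directory / "readings.csv")

res = lod_from_grid(readings, "Collembola", "mix_plus_background")
print()
print(f"Collembola, all targets mixed plus 300 ng non-target DNA:")
print(f"  LOD: {res.lod_copies:g} template copies "
      f"(every replicate >= 0.1 RFU at and above this level)")
print(f"  unstable levels (partial detection): "
      f"{', '.join(f'{v:g}' for v in res.unstable_range)}")
print()
print("An LOD of 20 copies with instability at 7 means the assay detects")
print("tens of template molecules reliably; single-digit inputs amplify")
print("only sometimes, as expected near the stochastic detection limit.")
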