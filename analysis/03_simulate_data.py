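"""Simulate the pseudo-experimental data table used for inference.

The six kinetic observables (k_cat and K_M of wild type, E238Q, E485Q)
are taken from the packaged asymmetric fixture and perturbed with
independent Gaussian noise at 15% relative uncertainty, emulating the
structure of the real kinetic measurements (which are not shipped).
"""

from pathlib import Path

from twinsite.inference import KINETIC_IDS
from twinsite.synthetic import asymmetric_fixture, simulate_measurements

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

truth = asymmetric_fixture()
data = simulate_measurements(truth, sigma_rel=0.15, seed=12, ids=list(KINETIC_IDS))
data.to_csv(RESULTS / "synthetic_data.csv")

print(data.entries.to_string(index=False))
print(f"written to {RESULTS / 'synthetic_data.csv'}")
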