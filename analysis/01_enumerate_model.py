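"""Enumerate the Markov model classes and their parameter layouts.

Writes the canonical state table, the transition table with shared
labels, and the free-parameter counts of the four model classes to
results/.  The non-allosteric wild-type class has 13 states, 20
reversible transitions carrying 10 forward coefficient labels, and 17
free parameters once detailed balance removes 3 of the 20 unique
coefficients.
"""

from pathlib import Path

import pandas as pd

from twinsite.model import ModelClass, count_free_parameters

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

mc = ModelClass()
states = pd.DataFrame(
    [
        {
            "index": s.index,
            "key": s.key,
            "conformation": s.conformation,
            "occupancy_I": s.occupancy_I,
            "occupancy_II": s.occupancy_II,
            "n_ATP": s.n_atp,
            "n_ADP": s.n_adp,
        }
        for s in mc.states
    ]
)
states.to_csv(RESULTS / "states.csv", index=False)

transitions = pd.DataFrame(
    [
        {
            "source": t.source.key,
            "target": t.target.key,
            "kind": t.kind,
            "label": t.label,
            "site": t.site or "",
        }
        for t in mc.transitions
    ]
)
transitions.to_csv(RESULTS / "transitions.csv", index=False)

counts = pd.DataFrame(
    [
        {"allostery": allo, "mutation_model": mut,
         "free_parameters": count_free_parameters(allo, mut)}
        for allo in (False, True)
        for mut in ("fixed_factor", "free_factor_and_affinity")
    ]
)
counts.to_csv(RESULTS / "parameter_counts.csv", index=False)

print(f"{len(mc.states)} states ({sum(s.conformation == 'open' for s in mc.states)} open), "
      f"{len(mc.transitions)} forward transitions, {len(mc.labels)} coefficient labels")
print(counts.to_string(index=False))
print(f"tables written to {RESULTS}")
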