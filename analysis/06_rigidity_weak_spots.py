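#!/usr/bin/env python
"""Rigidity dilution and weak-spot ranking over helix conformers.

Builds constraint networks (covalent bars, H-bonds below -1.0 kcal/mol,
hydrophobic tethers) for jittered copies of the ideal all-atom helix,
removes H-bonds weakest-first while tracking the giant rigid cluster,
and ranks residues by how often they leave the giant cluster at the
unfolding transition.
"""

import warnings
from pathlib import Path

import numpy as np

from allokin.rigidity import build_constraint_network, hb_dilution, weak_spot_frequency
from allokin.synthetic import make_allatom_helix

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rng = np.random.default_rng(9)
base = make_allatom_helix(12)
results = []
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for k in range(20):
        s = make_allatom_helix(12)
        s.coords = base.coords + rng.normal(0.0, 0.04, base.coords.shape)
        net = build_constraint_network(s)
        results.append(hb_dilution(net))

sizes0 = results[0].giant_sizes
print(f"conformer 0: {len(results[0].removal_energies)} H-bonds diluted, "
      f"giant cluster {sizes0[0]} -> {sizes0[-1]} atoms, "
      f"transition at step {results[0].transition_step}")

prof = weak_spot_frequency(results)
(OUT / "weak_spots.tsv").write_text(prof.to_tsv())
order = np.argsort(prof.ranks)
print("weak-spot ranking (residue: frequency):")
for k in order[:6]:
    print(f"  {prof.residue_ids[k][1]:3d}: {prof.frequencies[k]:.2f}")
print("thermal jitter spreads the H-bond energies, so fraying starts at "
      "whichever turn is weakest in each conformer")
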