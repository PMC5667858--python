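#!/usr/bin/env python
"""Perturbation response scan of the two-lobe toy network.

Applies a unit perturbation at each residue (Hooke's-law response via
the Kirchhoff pseudo-inverse) and ranks effector propensities: the
normalized variant peaks at well-connected lobe-core residues, the
ability to propagate perturbations through the fold.
"""

from pathlib import Path

import numpy as np

from allokin.gnm import build_kirchhoff
from allokin.prs import effector_profile, prs_scan, sensor_profile
from allokin.structures import ResidueProfile
from allokin.synthetic import make_two_lobe_toy

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

toy = make_two_lobe_toy(20, 20, seed=1)
km = build_kirchhoff(toy, r_c=7.0)
s = prs_scan(km, normalized=True)
eff = effector_profile(s)
sen = sensor_profile(s)

np.savetxt(OUT / "prs_matrix.tsv", s.values, delimiter="\t", fmt="%.6g")
(OUT / "effector.tsv").write_text(
    ResidueProfile(list(toy.residue_ids), eff.values, "effector").to_tsv()
)

top = np.argsort(eff.values)[-5:][::-1]
deg = np.diag(km.matrix)
print("top effector residues (normalized PRS):",
      [(int(i) + 1, f"degree {int(deg[i])}") for i in top])
print(f"mean degree of top-5 effectors: {deg[top].mean():.1f} "
      f"vs chain average {deg.mean():.1f} -- effectors sit in packed cores")
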