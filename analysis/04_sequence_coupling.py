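#!/usr/bin/env python
"""Conservation and coevolution recovery from a planted alignment.

Builds a 5000-sequence alignment with two fully conserved columns and
one covarying pair, applies the <50% coverage filter, and checks that
KL conservation and mutual information recover the planted signal
(KL = ln 20 for conserved columns, MI = ln 2 for the coupled pair).
"""

from pathlib import Path

import numpy as np

from allokin.coupling import column_mi, filter_msa, kl_conservation, write_msa
from allokin.synthetic import make_synthetic_msa

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

msa = make_synthetic_msa(
    5000, 40, conserved_cols={3, 17}, covarying_pairs=[(8, 28)], seed=8,
    gap_rate=0.1,
)
msa = filter_msa(msa, min_coverage=0.5)
print(f"alignment after coverage filter: {msa.n_sequences} sequences x "
      f"{msa.n_columns} columns")

kl = kl_conservation(msa, background=np.full(20, 0.05))
top2 = sorted(np.argsort(kl.scores)[-2:].tolist())
print(f"top KL columns: {top2} (planted: [3, 17]); "
      f"score {kl.scores[3]:.4f} nats vs ln 20 = {np.log(20):.4f}")

mi = column_mi(msa).values
v = np.where(np.isnan(mi), -1.0, mi)
np.fill_diagonal(v, -1.0)
i, j = np.unravel_index(np.argmax(v), v.shape)
print(f"top MI pair: ({i}, {j}) (planted: (8, 28)); "
      f"MI {v[i, j]:.4f} nats vs ln 2 = {np.log(2):.4f}")

lines = ["column\tkl_nats"] + [f"{c}\t{s:.6g}" for c, s in enumerate(kl.scores)]
(OUT / "kl_conservation.tsv").write_text("\n".join(lines) + "\n")
(OUT / "planted_msa.fasta").write_text(write_msa(msa))
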