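# allokin

Ensemble dynamics, allosteric networks and rigidity analysis for protein
kinase domains.

Protein kinases with the same fold can differ sharply in how rigid,
cooperative and chaperone-dependent they are.  This package implements
the computational machinery used to probe those differences on
coarse-grained ensembles: it simulates a structure's conformational
ensemble, extracts its collective motions and hinge centres, maps which
residues propagate perturbations, builds correlation-weighted residue
interaction networks with communication pathways and communities, and
ranks unfolding "weak spots" from constraint-network rigidity.  It is
aimed at structural bioinformaticians who want these stages as tested,
composable library functions that run end to end on synthetic systems
with planted ground truth — no structure downloads required.

## The models

**Square-well DMD (Go model).** Each residue is a Cα bead.  Chain
neighbours and native contacts (r⁰_ij ≤ r_c = 8 Å) are joined by
infinite square wells: the pair distance moves freely between
d_min = (1−σ)·r⁰_ij and d_max = (1+σ)·r⁰_ij (σ = 0.05 bonded, 0.1
native) and reflects elastically at the walls.  Dynamics is
event-driven — ballistic flight between collisions — with an
Andersen-style thermostat (ghost collisions at rate ν).

**GNM and PRS.** The Kirchhoff matrix Γ has Γ_ij = −1 for residue pairs
within 7.0 Å and degree on the diagonal.  The mobility profile over the
m slowest nonzero modes is

    ⟨M_i⟩|m = Σ_k λ_k⁻¹ [u⁽ᵏ⁾]_i² / Σ_k λ_k⁻¹ ,

whose minima are hinge centres.  Perturbation response scanning applies
a unit force at each residue and reads the Hooke's-law response
ΔR⁽ⁱ⁾ = H⁻¹F⁽ⁱ⁾ through the pseudo-inverse: S_ij = [(Γ⁺)_ij]², with row
means (diagonal excluded) as effector propensities.

**Residue interaction networks.** Conservation is the per-column
KL divergence Σ_a P(a) ln(P(a)/Q(a)); sequence coupling is column
mutual information; dynamic coupling is the generalized correlation
r_MI = √(1 − exp(−2·MI/3)) from Gaussian MI of fluctuation vectors.
Edges (Cα contacts at ≥ 50% frame occupancy) get lengths
w_ij = −ln r_MI.  On that graph: Floyd–Warshall shortest-path
ensembles, betweenness C_b(i) = Σ_{j<k} g_jk(i)/g_jk, Girvan–Newman
partitions selected by modularity, k-clique percolation (k−1 or k−2
sharing), and a >75% cross-frame community-stability rule.

**Rigidity.** Atoms are bodies with 6 degrees of freedom; rotatable
covalent bonds are 5 bars, locked (peptide/planar) bonds 6, hydrogen
bonds 5 and hydrophobic tethers 2.  H-bonds are scored by
E = V₀[5(d₀/d)¹² − 6(d₀/d)¹⁰]·cos²θ and kept below −1.0 kcal/mol.  The
(6,6) pebble game yields rigid clusters; removing H-bonds weakest-first
emulates thermal unfolding, and residues leaving the giant cluster at
the transition are weak spots, ranked by frequency over conformers.

## Worked example

```
$ python analysis/01_simulate_ensemble.py
two-lobe toy: 43 residues, 185 tethers (42 bonded)
1000 snapshots; max wall violation 0.00e+00 A; mean KE 65.40 (equipartition: 64.5)

$ python analysis/02_collective_dynamics.py
slowest-mode minimum at residue 21 (linker spans residues 21-23)
hinge residues (m=10, window 5, 25th pct): [20, 26, 35]
PCA cumulative variance of first 3 components: 79.1%

$ python analysis/04_sequence_coupling.py
top KL columns: [3, 17] (planted: [3, 17]); score 2.9957 nats vs ln 20 = 2.9957
top MI pair: (8, 28) (planted: (8, 28)); MI 0.6930 nats vs ln 2 = 0.6931
```

The 43-residue two-lobe toy is the built-in study system: two compact
helical lobes joined by a 3-residue linker.  The DMD run conserves
every hard-wall constraint exactly (violation 0.00e+00 Å) and
equilibrates to the thermostat temperature (mean kinetic energy 65.4 vs
the equipartition value (3/2)·N·T = 64.5).  The slowest elastic-network
mode is immobile exactly at the linker — the hinge about which the
lobes open and close — and the three leading PCA components of the
simulated ensemble carry 79% of the fluctuation variance.  The
conservation/coevolution stage recovers planted alignment signals at
their closed-form values (ln 20 for a conserved column, ln 2 for a
perfectly coupled pair).

The numbered scripts under `analysis/` run the remaining stages
(perturbation scanning, interaction networks and communities, rigidity
dilution) the same way; each writes its tables to `results/`.  The same
pipeline runs from the command line, e.g.
`allokin all --seed 7 --out run/`.

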