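# Methods

This note documents the models, the numerical choices and the synthetic
study systems, and states what the tests do and do not demonstrate.

## Coarse-grained event-driven dynamics

The simulation engine (`allokin.dmd`) implements a Cα-bead Go model
with infinite square-well pair potentials.  From the native trace,
chain neighbours receive walls at (1±0.05)·r⁰ — keeping Cα–Cα virtual
bonds near 3.8 Å — and non-consecutive pairs with native separation
r⁰ ≤ 8 Å receive walls at (1±0.1)·r⁰.  Untethered pairs interact
through a hard core (4.0 Å default; a pair already closer than that in
the native structure keeps a core just below its native separation, so
the native state is always admissible).  All masses are 1 and units are
reduced (k_B = 1, length in Å); with infinite wells there is no energy
scale, so temperature only sets the velocity distribution.

The event loop keeps a table of absolute next-crossing times per pair
and executes the global minimum: positions advance ballistically, the
radial component of the pair's relative velocity is reversed (exact
momentum and kinetic-energy conservation for equal masses), the pair is
nudged 10⁻⁹ Å off the wall to avoid re-detection, and only the two
affected particles' rows are recomputed.  Temperature control is an
Andersen-style thermostat: ghost events at total rate N·ν resample one
particle's velocity from the Maxwell–Boltzmann distribution.  Ghost
events count toward the event budget.  Snapshot cadence is in events
(default every 10³), and frame "times" are event counts — robust across
densities where the physical time per event varies.  The inner loop is
a numba kernel seeded from the run seed, so trajectories are
bit-identical across reruns.  Equal masses are assumed in the kernel;
the pure-Python `reflect` handles unequal masses for unit checks.

Hard-wall conservation is checked at every snapshot: over 10⁶-event
runs of the study system the maximum wall violation is 0 at 10⁻⁶ Å
resolution and microcanonical kinetic-energy drift is ~10⁻¹⁴ relative.

## Elastic network, PCA, PRS

The Kirchhoff matrix uses a uniform spring within 7.0 Å (bonded and
nonbonded pairs alike, γ = 1; the absolute scale cancels in normalized
profiles).  Eigendecomposition is dense (`numpy.linalg.eigh`; N here is
≤ a few hundred) with zero modes flagged at 10⁻⁸·λ_max; their count
must equal the number of connected components, which the tests verify
against a union-find oracle.  The mobility profile weights squared mode
shapes by λ⁻¹ over the m slowest nonzero modes and sums to 1 by
orthonormality.  Hinges are local minima within a ±2-residue window
that fall below the 25th percentile of the profile — window and
percentile are pragmatic defaults with no special status.

PCA operates on Cα coordinates of the ensemble after two passes of
mean-structure superposition (mean, fit all frames, re-mean) — a cheap,
stable protocol.  The per-residue displacement profile over the first
three components is eigenvalue-weighted and normalized to sum to 1;
the λ-weighting is an interpretation choice (an unweighted average of
normalized mode shapes is equally defensible) and is documented as
such.  For planted-covariance recovery tests superposition is skipped
(`fit=False`): fitting projects out the rigid-body content of a random
planted mode, which is correct behaviour but breaks exact recovery.

PRS is formulated over the GNM (scalar) network: S_ij = [(Γ⁺)_ij]²,
which folds the direction-averaging of Hessian-based PRS into the
isotropic model.  Row means exclude the diagonal (self-response is not
propagation).  The unnormalized matrix is symmetric, so effector and
sensor profiles coincide; the row-normalized variant (divide by S_ii)
breaks the symmetry and is the variant in which effector peaks localize
to well-packed cores rather than floppy termini — profile plots intended
to highlight "mediating" residues should use it.

## Sequence conservation and coupling

Column conservation is the standard KL divergence Σ_a P(a) ln(P(a)/Q(a))
in nats, gaps excluded, with an optional pseudocount.  The background Q
defaults to a bundled Swiss-Prot-style amino-acid frequency table and
is configurable; the closed-form checks use a uniform background, for
which a fully conserved column scores ln 20.

Column MI uses pairwise gap exclusion, optional sequence weighting
(1/cluster-size at 62% identity, default on) and a Miller–Madow
finite-sample bias correction (default on): without it a pair of
independent uniform 20-letter columns at n = 5000 scores ≈ (19·19)/(2n)
≈ 0.036 nats of pure bias; with it the null is < 0.01 nats while a
perfectly coupled two-state pair stays at ln 2.  APC is available but
off by default.

Dynamic coupling uses the Gaussian (linearized) MI estimator on
per-residue fluctuation vectors — ½·ln(det C_i det C_j / det C_ij) from
3×3/6×6 covariance blocks — mapped to r_MI = √(1 − e^(−2·MI/3)).  The
Gaussian estimator is deterministic and testable against closed forms;
for strongly non-Gaussian ensembles it underestimates MI, which is a
known limitation.  In the scalar case the identity r_MI = |ρ| holds
exactly and is tested.  Edge lengths follow w = −ln max(r, 10⁻⁴); the
floor keeps uncorrelated pairs at finite distance (≈ 9.21).  Natural
logarithms are used throughout.  How sequence MI should be blended into
the edge weight is genuinely open; the default uses dynamic r_MI only.

## Interaction networks

Graphs are built from Cα contacts (7.5 Å) per frame with edges kept at
≥ 50% occupancy; an atom-level mode scores side-chain interaction
strength I_ij = 100·n_ij/√(N_i·N_j) against a bundled per-residue-type
normalization table (threshold I_min = 3.0) for all-atom conformer
input.  Shortest paths use Floyd–Warshall for distances and a
per-source DAG accumulation for path counts, with a 10⁻¹² relative tie
tolerance.  Node and edge betweenness are computed from those counts
(for pairs ending at an edge's endpoint the endpoint contributes its
single empty path); both agree with independent Brandes (networkx) and
exhaustive-enumeration oracles to 10⁻⁹ in the tests.

Girvan–Newman removes the highest-betweenness edge (ties broken by
lexicographic edge id), recomputes after every removal, records the
partition at each component split and returns the one maximizing
Newman modularity.  Modularity needs affinities, not lengths, so edges
enter it as r_MI = e^(−w): strongly coupled edges are strong community
ties.  On the two-lobe study graph the optimum is finer than the
two-lobe split (each lobe's two helical arms separate), but no
community ever spans the hinge.  k-clique communities enumerate
k-cliques (from maximal cliques), connect them at ≥ k−1 shared nodes by
default (the k−2 relaxation is exposed) and union connected components;
communities may overlap.  Community stability matches a consensus
frame's communities (the frame most similar on average to all others)
against every frame by Jaccard ≥ 0.6 and keeps those recurring in
strictly more than 75% of frames; both thresholds are tunable, and the
Jaccard matching is our resolution of how "the same community" should
be identified across frames.

## Rigidity and dilution

Bodies are atoms with 6 DOF; bar counts follow FIRST conventions
(5 rotatable / 6 locked / 5 H-bond / 2 hydrophobic; configurable).
H-bond energies use the geometric form V₀[5(d₀/d)¹² − 6(d₀/d)¹⁰]·F(θ)
with V₀ = 8 kcal/mol, d₀ = 2.8 Å, F = cos²θ_DHA for θ > 90°, candidates
at donor–acceptor distance ≤ 3.6 Å, cutoff −1.0 kcal/mol.  The angular
factor is a deliberate simplification of the full hybridization-
dependent empirical function.  Hydrophobic tethers join side-chain C/S
atoms within r_vdw(i)+r_vdw(j)+0.25 Å (C 1.7, S 1.8 Å).

The (6,6) body-bar pebble game inserts each bar through a directed
pebble search (7 pebbles on the endpoints accept a bar; failures are
redundant bars), giving free pebbles = 6·B − independent bars — verified
exhaustively against a generic linear-algebra rank oracle on random
small networks.  Rigid clusters merge constraint-linked body pairs on
which no seventh pebble can be gathered; the decomposition partitions
bodies, so a single body shared by two otherwise-independent rigid
regions would merge them — a known approximation that does not arise in
backbone-dominated networks like those here.

Dilution removes H-bonds one per step, weakest (least negative energy)
first, ties by donor then acceptor index, keeping covalent and
hydrophobic constraints.  The transition is the largest single-step
drop in giant-cluster size (earliest on ties); weak spots are residues
whose Cα is in the giant cluster immediately before and outside it
immediately after; a residue counts as flexible when its Cα is in a
rigid cluster of fewer than four atoms.  On a geometrically ideal helix
every backbone H-bond has identical energy, so the schedule is decided
entirely by the tie rule, the termini fray *before* the transition and
the weak spots land beside the final rigid remnant — a degenerate
limit worth knowing about.  With realistic energy spread (the jittered
conformers used by the pipeline), fraying starts at the weakest turn of
each conformer and the frequency ranking spreads accordingly.

## Synthetic study systems

The generators (`allokin.synthetic`) are pure functions of their
arguments and a seed.

- **Two-lobe toy** (default 20+3+20 residues): two helical hairpins
  (an ideal helix rigidly folded at its midpoint, preserving bond
  lengths exactly) joined by an extended linker, with seeded placement
  jitter re-drawn until the lobes are clash-free and ≥ 15 Å apart.  It
  plants one fact: the linker is the hinge.  It has no secondary-
  structure diversity, no side chains and no binding partners.
- **All-atom helix** (12 residues): ideal backbone geometry at
  (φ, ψ) = (−57.8°, −47.0°), giving n−4 identical i→i−4 H-bonds at
  d(N···O) = 3.05 Å.  Pipeline conformers add 0.04 Å Gaussian
  coordinate jitter, chosen to spread H-bond energies without breaking
  any below the −1.0 kcal/mol cutoff.
- **Planted MSA**: conserved columns (single letter), covarying pairs
  (two-state (A,V)/(L,I) at 50/50 — exactly ln 2 of MI), all else
  i.i.d. uniform; optional gap rate for exercising the coverage filter.
- **Gaussian ensembles**: exact planted 3N covariance from orthonormal
  modes, for PCA and r_MI recovery at closed-form values.

Passing these recoveries shows the estimators are correct at their
closed forms and that the pipeline is internally consistent; it does
not show that the defaults are tuned for real kinase-sized proteins,
that the Gaussian MI captures anharmonic couplings, or that weak-spot
rankings on 12-residue fixtures transfer to multi-domain structures.
Problem sizes throughout (43-residue toy, 10⁶ events, 5000-sequence
alignments, 200-trial oracles) are the package's study conditions,
chosen so every closed-form comparison has negligible sampling error.

## Degenerate inputs and tie-breaks (summary)

Chain breaks (> 6 Å consecutive Cα) are errors, unusual bond lengths
warnings; frozen ensembles are rejected by PCA; disconnected graphs are
rejected by PRS (ambiguous pseudo-inverse) and warned about elsewhere;
all-gap columns score 0; singular covariance pairs are marked missing;
shortest-path ties use a 10⁻¹² relative tolerance; Girvan–Newman ties
take the lexicographically smallest edge; equal-energy H-bond removal
is ordered by donor index; equal weak-spot frequencies rank by residue
order.
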