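# Methods

## Scope and units

`rampclamp` analyses trajectories of two-chain receptor–ligand complexes
under mechanical load and simulates that load at coarse-grained scale.
One unit system is used throughout: Å, ns, pN, kcal/mol, amu, elementary
charges, kelvin. All conversion constants live in `rampclamp.units`
(Coulomb constant 332.0636 kcal·Å·mol⁻¹·e⁻², k_B = 0.0019872
kcal·mol⁻¹·K⁻¹, 1 pN·Å = 0.0143836 kcal/mol); no other module carries
its own factors, which is the main defence against silent pN/nm vs
kcal/mol/Å² errors.

## Structures and IO

The PDB reader covers the ATOM/HETATM/MODEL/ENDMDL/TER subset.
Multi-MODEL files become trajectories (policy `all`, the default) or a
single structure (`first`). Alternate locations keep altloc `'A'` or
blank by default — the common crystallographic convention. Pyroglutamate
(PCA) is parsed as an ordinary residue and residue numbering follows the
file as-is; whether downstream analysis uses all or heavy atoms of a
modified residue is left to the caller's selection. Elements are
inferred from the atom-name columns when the element field is blank.
Crystal structures usually lack hydrogens; H-bond analysis then runs in
an explicit distance-only fallback (flagged in the report manifest)
rather than guessing hydrogen positions.

Selections use a small VMD-flavoured grammar (`name`, `chain`,
`resname`, `resseq` ranges, `element`, `and/or/not`, parentheses) and
always resolve to file-ordered, deterministic index lists. Loop and
strand definitions (CD loop = residues 50–60 of the receptor's first
domain, etc.) are configuration, not inference: the package never
assigns secondary structure.

## Geometry metrics

Superposition is Kabsch via SVD with the proper-rotation correction
(det = +1 enforced), optionally mass-weighted; the default for Cα-RMSD
is unweighted, matching common practice. RMSF superposes frames onto an
iteratively refined mean structure (two passes) before computing
√⟨|rᵢ−⟨rᵢ⟩|²⟩; whether superposition uses the whole complex or one
chain is a caller choice (`selection`), since both conventions exist.

A β-strand axis is the first principal component of the ordered Cα
coordinates, sign-fixed so that direction·(last−first) > 0. This makes
the axis orientation-aware (N→C): reversing the residue order flips it,
and the inter-strand angle *θ* is reported in [0°, 180°] from oriented
axes. An unoriented convention would fold θ at 90°; the oriented one is
the default because the pocket metrics of interest straddle 90° and the
fold would hide sign changes. Angles clamp the cosine to [−1, 1] before
arccos; near 0° and 180° arccos loses ~√ε precision, so invariance
tests use 1e-5 degrees rather than 1e-9.

## SASA

Shrake–Rupley with a deterministic golden-spiral point set (default 960
points, probe 1.4 Å). Determinism was preferred over random sphere
sampling so that repeated runs are bitwise identical; 960 points give
≲0.5% sampling error on protein-like clusters and doubling the count
changes totals by <0.5%. Neighbour culling uses a k-d tree. Buried
interface area is reported as the full ΔSASA = SASA(A)+SASA(B)−SASA(AB)
in nm²; the per-side ΔSASA/2 convention is available behind a flag
(`halved=True`) because both conventions appear in the literature.

## Hydrogen bonds

A triplet D–H···A is bonded when dist(D,A) ≤ 3.5 Å and the deviation of
D–H···A from linearity is ≤ 30°. The cutoff is deliberately the
*deviation* from 180°, not the raw angle — the convention of the
standard visualisation/analysis tools this mirrors. Donors are N/O
atoms with a covalently attached hydrogen (< 1.2 Å in the topology
frame); acceptors are N/O. Occupancy (survival ratio) of a residue pair
is the fraction of frames in which *any* atom-level triplet of that
pair is present (per-frame union), because interface tables are
reported at residue-pair, not atom-triplet, resolution.

Two dissociation-probability estimators are provided and are **not**
equivalent to each other or to literature values computed with other
formulas: `independence_product` = Π(1−occᵢ) assumes independent bonds;
`empirical_all_broken` counts frames with a fully broken interface and
reports a rule-of-three 95% upper bound (3/n) when none is observed.

Force-response typing compares per-pair occupancies between a static
and a loaded condition: Δ = mean(force) − mean(static); type II if
Δ ≥ +δ_min, type III if Δ ≤ −δ_min, otherwise type I, with δ_min = 0.05
by default (the smallest change we regard as meaningful at three
replicates; no canonical threshold exists). An optional Welch-test gate
demotes non-significant changes to type I; degenerate zero-variance
inputs fall back to the Δ rule. Typing is antisymmetric under swapping
the conditions.

## Binding energetics

E_B per frame is the single-trajectory MM-GBSA-style difference
Δ(complex − A − B) evaluated on the complex geometry:

- ΔE_gas: pairwise Coulomb + Lennard-Jones (CHARMM combination rules,
  no cutoff — systems are small); intra-chain pairs cancel exactly in
  the Δ, so only cross-interface pairs are summed.
- ΔG_polar: Generalized Born with Still's f_GB =
  √(r² + RᵢRⱼ exp(−r²/4RᵢRⱼ)) and Hawkins–Cramer–Truhlar pairwise
  descreening for effective radii (scale 0.8); ε_in = 1, ε_out = 78.5.
  A lone ion reduces exactly to the Born formula, which anchors the
  closed-form tests. GB was chosen over a Poisson–Boltzmann solver as a
  desk-scale polar model that is testable against closed forms.
- ΔG_nonpolar: γ·ΔSASA with γ = 0.00542 kcal/mol/Ų. The constant
  offset β = 0.92 kcal/mol applies to *absolute* nonpolar energies
  only; in a three-species difference it would contribute a spurious
  −β and break the physical requirement that E_B → 0 at infinite
  separation, so it is excluded from Δ terms.

Entropy terms are not modelled. Charges, LJ parameters and intrinsic
Born radii come from a plain-text table keyed by (residue, atom name);
synthetic fixtures ship complete tables so nothing external is needed.
The decomposition identity E_B = ΔE_gas + ΔG_polar + ΔG_nonpolar is
exact by construction and asserted in tests.

## Pulling engine

The molecular system is an elastic-network model: Cα beads, harmonic
springs at native distances within a 10 Å cutoff, stiffness k_enm
(default 1 kcal/mol/Å², the typical ENM scale). Inter-chain springs are
weaker (k_enm/10) and breakable: a spring stretched past 2× its rest
length is removed permanently. The breakage rule is an engine-specific
device to make rupture exist at this scale — coarse-grained harmonic
networks do not rupture on their own — and is not a claim about real
bond chemistry.

Dynamics are overdamped (Brownian) Euler–Maruyama:
x ← x + (Δt/γ)F + √(2k_BTΔt/γ)ξ. Default friction γ = 0.005
kcal·ns·mol⁻¹·Å⁻² gives a bead diffusion constant k_BT/γ ≈ 120 Å²/ns,
i.e. ~10⁻⁶ cm²/s, the right order for a small protein domain; the
default step Δt = 10 fs sits well inside the explicit-Euler stability
bound Δt < 2γ/k, and the engine refuses configurations outside half
that bound with a suggested step. At T = 0 the integrator matches an
independent Euler reference to 10⁻⁶ Å and the analytic exponential
relaxation to ~(kΔt/γ)² per step; at T > 0 the discrete stationary
variance carries the known Euler bias kΔt/2γ (0.5–1% at defaults),
which the equipartition checks absorb.

Loading protocol: a dummy point starts at the steered bead and moves at
v_pull (default 5 Å/ns) along a direction fixed from the t = 0 geometry
— mode 1: from the single fixed bead to the steered bead; mode 2: from
the midpoint of the two fixed beads to the steered bead. The applied
force is the virtual-spring extension (k_spring, default 34.74 pN/nm)
projected on that direction. The direction is held constant for the
whole run (the convention of constant-velocity SMD in the major MD
engines); per-step recomputation is available behind a flag. At the
first crossing of the clamp setpoint (default 25 pN) the run switches
to force clamp: the same constant force applied to the steered bead. A
ramp that never reaches the setpoint is reported as protocol-incomplete,
not raised. With the steered bead immobilised the ramp force is exactly
k_spring·v_pull·t (17.37 pN/ns at the defaults), which calibrates the
unit bridge end to end.

Rupture force is the global maximum of the running-mean-smoothed
ramp-phase force–time curve; the window is a parameter (0 disables
smoothing) and a constant trace degenerates to a warning plus the
constant.

## Synthetic data

The generators emulate the *statistical structure* of a bound-complex
trajectory, not protein geometry. `build_complex` lays out one bond
unit per prescribed residue pair: acceptor oxygen on chain A, donor
nitrogen plus explicit hydrogen on chain B, at D–A 2.9 Å and 5°
deviation (comfortably inside the cutoffs), units spaced 8 Å apart,
plus decoys that fail the distance or the angle criterion and one
intra-chain bond that must be removed by the interfacial filter. The
default twelve residue pairs and their occupancy targets reproduce the
wild-type CD47/CD172a interface table (e.g. GLU35–ARG69 at 0.82,
PCA1–SER66 at 0.52, two pairs at 0); a second table gives the
unmodified (N-terminal glutamine) variant. `jitter_trajectory` toggles
each bond per frame — iid Bernoulli at the target occupancy, or a
two-state Markov chain whose `p_stay` parameter is the lag-1
autocorrelation and whose stationary occupancy equals the target — by
moving the acceptor radially out by +1.5 Å (to 4.4 Å, unambiguously
beyond the 3.5 Å cutoff). The off state is deliberately far from the
cutoff so tests never sit on the decision boundary.

Because bonds toggle geometrically, the detector's output must equal
the generator's presence matrix *exactly*, and it does — this identity
is what lets estimator statistics be tested against binomial/Markov
closed forms. What passing these tests does **not** show: behaviour on
real structural fluctuations near the cutoffs, cooperative bond
dynamics, or force-field realism; the generators have none of these by
design.

## Replicate statistics

Experiments run three seeded replicates per condition (configurable).
Aggregation is the sample mean ± sample SD (n−1); a single replicate
reports SD 0 with a warning. Condition comparisons use Welch's unequal-
variance t-test by default — safer than the pooled test at n = 3 — with
the classical pooled variant behind a flag; star codes at 0.05/0.01/
0.001. Multi-factor ANOVA is out of scope. All pipeline outputs are
deterministic functions of (config, seeds): reruns are byte-identical,
and the manifest records the config hash, seeds and package version.

## Problem sizes

Defaults were chosen so the full battery runs on one CPU in minutes:
analysis trajectories of a few hundred frames × ~70 atoms (statistics
tests use 2000 frames), ENM pulling systems of ~10 beads over 1–3 ns of
overdamped time, SASA at 960 sphere points (oracles use 2×10⁵–10⁶).
These sizes are the package's validation scale; production analyses of
real trajectories simply pass larger inputs through the same code
paths.

## Known limitations

- No all-atom dynamics, explicit solvent or force-field import; the
  engine's rupture forces and occupancy shifts are engine-scale
  quantities, not predictions of experimental magnitudes.
- The GB model uses one radii/scale convention; absolute polar
  solvation values depend on that choice (all constants are exposed).
- Distance-only H-bond mode cannot apply the angle criterion and will
  overcount borderline contacts; it exists for hydrogen-free crystal
  structures and is always flagged.
- The dissociation-probability estimators bound simple models; neither
  reproduces literature values derived from different formulas.
- mmCIF, bond-order perception and secondary-structure assignment are
  out of scope.
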