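# Methods

## Scope and model

`clawpore` treats claudin assembly as a rigid-body, residue-resolution
problem. A protein is a set of beads, one per residue, at the side-chain
heavy-atom centroid (Cα for glycine). This resolution keeps the full
charge geometry of the extracellular segments — the part of the claudin
fold that lines the paracellular channel and sets its selectivity — while
making exhaustive rotational sampling and brute-force verification
affordable on one CPU. Flexibility, solvent, membrane lipids and entropic
contributions are deliberately absent: energies are interaction scores
for ranking orientations and decomposing interfaces, not binding free
energies.

### Charges and classes

Integer charges at pH 7.4: LYS, ARG +1; ASP, GLU −1; everything else 0.
Charge classes follow the convention used for pore-lining maps: positive,
negative, polar (exactly ASN, GLN, SER, THR, TYR), apolar. HIS is treated
as neutral/apolar at pH 7.4; both HIS handling and the per-residue bead
radii are config-exposed because neither is dictated by the model itself.
The generic bead radius is 2.64 Å (half of a 5.28 Å coarse-grained bead
diameter).

### Energy function

Between two rigid groups,

    E_LJ   = Σ 4ε[(σ/r)¹² − (σ/r)⁶]
    E_Coul = Σ f·qᵢqⱼ/(ε_r·r_nm),   f = 138.935458 kJ·mol⁻¹·nm·e⁻²

summed over inter-group pairs with r ≤ cutoff. Defaults σ = 4.7 Å,
ε = 2.0 kJ/mol, ε_r = 15, cutoff 12 Å — magnitudes typical of 4-to-1
coarse-grained force fields, chosen once and exposed in config. A pair
closer than 0.1 Å raises an error rather than returning a singular value.

## Rotational landscapes

Monomers are membrane-aligned (largest-variance direction of the TM beads
mapped to +z, TM centroid at the origin; the transform is rigid to 1e-6 Å).
For each grid cell (θ₁, θ₂) the second monomer approaches along +x until
the minimal bead-surface separation equals the contact gap (default
0.5 Å). That contact distance is computed in closed form: for each
inter-model pair the offset at which the pair reaches the gap is
`dx + sqrt((gap + rᵢ + rⱼ)² − c²)` with c the in-plane offset, and the
contact distance is the maximum over pairs — the binding pair then sits
exactly at the gap and no pair is closer. The closed form replaces an
iterative bisection: it is exact, deterministic and an order of magnitude
faster, and tests cross-check it against a 0.01 Å translation scan.

The default increment is 1°, giving a complete 129,600-cell landscape;
the stable states are the cells below the rank-based 10th percentile
(count = floor(0.1·N) exactly, ties broken lexicographically by angles),
i.e. 12,960 states on the 1° grid. The pore-forming window at
270° ± 10° is half-open per axis ([260°, 280°)), giving 20 × 20 = 400
member cells at 1°; a closed 21-value window is selectable by flag. The
half-open convention is used because a closed ±10° window at 1° cannot
produce a 400-cell count.

## Tetramer assembly and refinement

A *cis* dimer (a stable landscape state, or user-specified angles) is
duplicated or paired with a second dimer; the partner is rotated 180°
about the x axis so its extracellular segments face the first, laterally
centred on it, and offset vertically so the facing extracellular surfaces
sit a fixed gap apart (default 2 Å — the template geometry leaves this
open, so it is config-exposed). Dimer-internal geometry is never
modified. Overlapping placements are refused with a suggestion to widen
the gap.

Local refinement replaces external docking with deterministic
Nelder-Mead over the partner dimer's four rigid degrees of freedom (gap,
x/y shift, twist about z) from a fixed start simplex, followed by one
polish restart with a shrunken simplex; infeasible poses carry a large
penalty, so refined energy never exceeds the input energy. Fluctuation
averaging over a trajectory is out of scope — the reported interface
energy is a single-pose value, which is why claudin-specific interface
energies from relaxed-ensemble pipelines are not comparable targets for
this package.

The trans interface energy sums strictly over pairs with one bead in each
dimer group, reported as (E_LJ, E_Coul, E_total); tests verify the group
masking against a brute-force loop and the symmetry of the construction.

## Pore profiling

Slice-chained maximization (HOLE-style) rather than a Voronoi tunnel
graph: at each z (step 0.5 Å by default) the in-plane point maximizing
clearance c(p) = min(|p − bᵢ| − radiusᵢ) is found by Nelder-Mead, seeded
from the previous slice's centre with one restart at the local slice
centroid, plus a soft wall at the structure's lateral extent so open
slices cannot send the maximizer to infinity. This choice is exact on the
tube-like geometry of claudin channels and is fully checkable against a
brute-force in-plane grid. The probe radius is max(c, 0); a lateral
centre jump larger than 2·z_step breaks the tunnel. Broken or blocked
channels report minimum diameter 0 Å with `pore_exists` false — they are
reported, never omitted — and the pore-lining stage then refuses with an
explicit no-pore error. The existence threshold (default probe 0.9 Å, a
common minimum tunnel probe) is re-appliable because profiles store raw
radii.

The ring-stack generator provides the analytic oracle: for coaxial rings
with tight walls (adjacent beads touching or overlapping) the axis is
provably the in-plane argmax, so the clearance at height z is exactly
`min_k sqrt(R_k² + dz_k²) − r_bead`, reducing to `R − r_bead` at a ring
plane of a uniform stack. Configurations whose inter-bead gaps open a
path through the wall are flagged leaky instead of being given a fake
truth.

## Pore-lining residues

A bead is a member when its distance to the channel is ≤ 6 Å (default).
Distance is measured to the channel *surface* (distance to the nearest
centre-line sample minus that sample's probe radius); a pure centre-line
mode is selectable. Surface distance is the default because a 6 Å
centre-line cutoff would exclude the walls of any pore wider than ~12 Å.
Regions split the profiled interval into z-thirds (mouth / center /
mouth); tallies are reported per region and whole-pore, and the net
charge is the signed sum over members. Whole-pore and per-region tallies
can legitimately differ — both are exposed rather than adjudicated.

## Electrophysiology

All GHK arithmetic models the three monovalent ions Na⁺, Cl⁻, Li⁺ at
37 °C (310.15 K) with activity coefficients 1; divalents and buffer
species are GHK-silent. The standard baths are 140 mM NaCl Ringer, the
1:4 saline:mannitol dilution (28 mM NaCl) and the 140 mM Li⁺ replacement
Ringer. Potentials are basal-minus-apical by default with a sign flag,
since instrument conventions vary.

* Dilution inversion: V = (RT/F)·ln[(β[Na]_b + [Cl]_a)/(β[Na]_a + [Cl]_b)]
  solved for β in closed form; potentials at or beyond either single-ion
  Nernst limit raise an error naming the bound (the cation-only limit is
  β → ∞).
* Bi-ionic inversion: the three-ion relation solved for P_Li/P_Na given β.
* Absolute permeabilities: Kimizuka–Koketsu,
  P_Na = (RT/F²)·G·β/((1+β)·c) with c in mol/cm³, P_Cl = P_Na/β. The
  upstream experimental protocol defers this formula to its own
  literature; pinning this standard form is a package decision and its
  identity P_Na/(P_Na+P_Cl) = β/(1+β) is tested exactly.
* P_app: least-squares slope of receiver amount vs time over (area ×
  donor concentration), with warnings (not errors) for negative slopes
  and sink-condition violations. The synthetic flux generator assumes the
  sink condition (constant donor concentration), matching the analysis
  formula; saturating receivers are outside the generator's scope.

## Synthetic data: what it does and does not emulate

The toy monomer reproduces the claudin topology that the analysis
operates on — four TM bead columns spanning a 30 Å slab, a longer ECS1
and shorter ECS2 arc above it, and user-placed charges at arc positions —
with a small seeded positional jitter so toys are not artificially
symmetric. It does not mimic real claudin sequences, side-chain packing,
or bilayer physics; passing tests demonstrate the correctness of the
geometric and energetic machinery, not the claudin-specific numeric
results (interface energies in the −1000 kJ/mol range, pore diameters of
specific claudin pairs, their net charges), which depend on homology
models and long relaxed-ensemble simulations outside this package's
scope. Ephys and flux records are forward simulations of the exact
relations the estimators invert, plus Gaussian noise; they validate the
inversion arithmetic and its noise robustness, not electrode or chamber
artefacts.

Problem sizes used by the test-suite and the acceptance script: 48-bead
toy monomers for the full 1° landscape (129,600 contact placements and
energies, ~15 s); 100 randomized three-ring stacks for the profiler
oracle suite with a 0.02 Å brute-force grid per slice; 500 noisy
dilution records and 200 noisy flux series for the recovery checks; a
4-bead toy for the exhaustive 0.1 Å/1° refinement oracle.

## Numerical choices

* Percentiles are rank-based (floor of fraction × N) so stable-state
  counts are integer-exact; ties break lexicographically by (θ₁, θ₂).
* Minimum-diameter ties resolve to the smallest z.
* Landscape statistics use the sample SD (ddof = 1).
* Seeds: every stochastic generator takes an explicit integer seed; all
  analysis stages are deterministic. The pipeline default seed is 1729.
* Determinism: rerunning a pipeline config byte-matches summary and
  manifest JSON (sorted keys, fixed float repr).

## Known limitations

* Rotation-only *cis* sampling: no tilt or z-offset degrees of freedom,
  no flexible side chains.
* Single-pose energies; no ensemble averaging, no entropy or solvent.
* The pore profiler assumes an approximately z-aligned, unbranched
  channel; branched tunnel networks are out of scope.
* GHK treats three monovalent ions only; divalent corrections and
  activity coefficients are not modelled.
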