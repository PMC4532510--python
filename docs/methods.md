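# Methods

`nucleomd` simulates partial unwrapping of protein-wrapped DNA — the
nucleosome being the motivating system — with a residue/nucleotide-level
coarse-grained model: one bead per amino acid at the Cα position, three
beads per nucleotide (base, sugar, phosphate), Langevin dynamics, and a
total energy

    V_total = V_pro + V_dna + V_pro-dna.

## Energy model

**Protein (structure-based Gō).** Harmonic virtual bonds
k_bd (r − r⁰)² and angles k_ba (θ − θ⁰)², dihedrals
k_φ1[1 − cos(φ − φ⁰)] + k_φ3[1 − cos 3(φ − φ⁰)], a 12-10 native-contact
attraction ε_go[5(r⁰/r)¹² − 6(r⁰/r)¹⁰] for residue pairs in proximity in
the reference structure with sequence separation |i − j| > 3, and a generic
ε_ev(σ/r)¹² excluded volume for non-native pairs. All superscript-0
quantities are measured on the reference structure, which is therefore the
exact minimum of every bonded term and of each contact.

**DNA (three sites per nucleotide).** Backbone bonds carry a
quadratic-plus-quartic restraint k₂(r − r⁰)² + k₄(r − r⁰)⁴, angles
(k_ba/2)(θ − θ⁰)², backbone dihedrals k_φ[1 − cos(φ − φ⁰)]. Intra-strand
neighbouring bases stack through 4ε_st[(r⁰/r)¹² − (r⁰/r)⁶] (zero and
inward-pulling at the native distance, minimum −ε_st at 2^{1/6} r⁰);
complementary bases pair through ε_bp[5(σ_bp/r)¹² − 6(σ_bp/r)¹⁰] with
(ε_bp, σ_bp) per pair type (G:C deeper than A:T in a 3:2 ratio, two vs
three hydrogen bonds). Non-bonded site pairs repel through a
truncated-shifted (Weeks–Chandler–Andersen) 12-6 term that vanishes
continuously at 2^{1/6}σ. A Morse-like solvation term
ε_s{[1 − e^{−α(r − r_s)}]² − 1} acts across the duplex to assist pairing.
All DNA reference values (r⁰, θ⁰, φ⁰, stacking distances) are taken from
the package's ideal B-form helix, not from the input structure, so a bent
crystal conformation is pre-stressed exactly as the physics requires.

**Electrostatics.** Charged beads (phosphates, Asp/Glu at −1; Lys/Arg at
+1; His +1 or 0, a configurable protonation toggle) interact through the
Debye–Hückel screened Coulomb energy q_i q_j e^{−r/λ_D}/(4π ε₀ ε r) with
the water dielectric fixed at ε = 78. The Debye length follows from the
1:1 ionic strength, λ_D = √(ε₀ ε k_B T / 2 N_A e² I) (9.62 Å at 100 mM,
300 K), so salt concentration is the experiment's principal control
variable. The same term couples protein to DNA; it is what makes
unwrapping salt-dependent.

**Protein–DNA coupling.** A weakened Gō contact potential connects protein
beads to DNA *sugar and base* sites (never phosphates, which are
represented by their charge) in proximity in the reference complex, with
strength ε_go^pro-dna = s·ε_go^pro. The scaling s defaults to 0.8 and is
the model's single calibrated knob: s ≈ 0.5 behaves like a weak-affinity
positioning sequence (salt-induced dissociation), s = 1.0 like an
unrealistically stable one.

### Parameters

Every coefficient lives in a versioned plain-text file
(`src/nucleomd/data/default_v1.prm`); the evaluators contain no numeric
constants. Units: kcal/mol, Å, elementary charges, g/mol; the intrinsic
time unit t₀ = √(g/mol · Å²/(kcal/mol)) ≈ 48.9 fs. The shipped values
follow the magnitudes of the published Cα-Gō and three-site-DNA parameter
sets (e.g. k_bd = 100 kcal/mol/Å², k_ba = 20, ε_go = 0.3 kcal/mol for
protein; base pairing 1.8/2.7 kcal/mol for A:T/G:C), with geometric
parameters (σ_bp, r_s, helix constants) derived self-consistently from the
package's B-form construction. The helix is generated per base-pair frame
(rise 3.38 Å, twist 36°) with the complementary strand placed as the dyad
image rotated by a groove-asymmetry offset of −40°; equal grooves would
put the two backbones on top of each other.

### Evaluation details

Pair lists (bonded, native, excluded-volume, electrostatic) are compiled
once per (topology, parameters) into fused index arrays and evaluated
either by vectorised numpy or, when numba is importable, by jitted kernels
that compute identical sums (the equality of the two paths is itself a
test). Exclusions: 1-2 and 1-3 bonded pairs are removed from excluded
volume and electrostatics; any pair on an attractive native list is
removed from excluded volume; protein excluded volume requires |i − j| > 3
within a chain, like the contacts. Attractive native lists are evaluated
without distance truncation (they are O(N) and fixed, so exactness is
cheaper than a cutoff error budget); the r⁻¹² repulsions are truncated at
3.2σ (relative tail < 10⁻⁶) and the screened Coulomb term at 5λ_D.
Degenerate geometry is guarded: collinear angle triples and planar-collapsed
dihedral quadruples contribute their energy but zero force rather than NaN.
Pair evaluation is dense (no cell lists); this is simple and fast for the
≤ few-thousand-bead systems exercised here and is the main scalability
limitation for much larger complexes.

## Dynamics

The underdamped Langevin equation m dv = (F − mγv)dt + √(2mγk_BT) dW is
integrated with the BAOAB splitting: half kick, half drift, exact
Ornstein–Uhlenbeck velocity refresh, half drift, half kick. At γ = 0 this
is exactly velocity Verlet; energy conservation in that limit is tested
(drift < 0.1% of mean kinetic energy over 10⁵ steps at dt = 0.005 t₀ on the
wrapped-arc fixture — the fixture's compressed excluded-volume contacts
are stiffer than anything in a relaxed structure and set the stability
limit there). Defaults mirror the study conditions: dt = 0.1 t₀,
γ = 0.02 t₀⁻¹ (deliberately low to accelerate exploration), T = 300 K,
Maxwell–Boltzmann initial velocities, no boundary box. The printed form of
the friction term in some renderings carries a + sign; the implemented
equation damps velocity, as any stable Langevin integrator must. Noise
variance follows the standard fluctuation–dissipation relation
⟨ξξ⟩ = 2mγk_BT. Replicas use seed + replica-index noise streams; a run is
bit-reproducible given the same seed and platform.

**Constant-velocity pulling.** One virtual particle per duplex end links
the 5′-terminal bead of one strand and the 3′-terminal bead of the other
(sugar sites) through harmonic springs whose rest vectors equal the
initial offsets, so the apparatus is force-free at t = 0. The particles
move apart at speed v (default 10⁻⁴ Å/t₀; dt drops to 0.05 t₀) and the
reported force is the axial spring-force component averaged over beads and
ends — for a frozen bead it ramps at exactly k·v. The pulling coordinate d
is the inter-particle separation along the pulling axis. The spring
constant (default 0.5 kcal/mol/Å², ~1 pN force resolution at thermal
extension) is configurable and logged.

## Observables

* **d_DX / d_HX** — per-base-pair / per-residue deviation from the
  reference after a best-fit (Kabsch) superposition on the histone-core
  (non-tail) protein beads. The fit set is configurable; core-only fitting
  is the default because DNA deviations must be measured in the octamer
  frame.
* **n-bp unwrapped state** — the largest n such that base pairs 1…n from a
  duplex end all deviate by more than 10 Å while base pair n+1 does not;
  counted from each end independently (an exhaustive-scan oracle
  reproduces the rule exactly on random inputs). The base-pair
  representative point is the centroid of all beads of the two paired
  nucleotides.
* **Free-energy profile** — F(bp) = −ln(N·p(bp) + 1) with N the pooled
  sample count, so unsampled states sit exactly at zero. Pooled-N is the
  default; per-replica profiles provide error estimates.
* **End independence** — P(both i-th bp unwrapped) against the product of
  marginals.
* **r_HTO** — distance of each tail's first resolved N-terminal bead from
  the mass-weighted centre of the histone core.
* **Tail–unwrapping correlation** — Pearson correlation per residue
  between d_HX and the left-end unwrapped count; zero-variance inputs
  return 0 with an explicit flag instead of raising.
* **B-factors** — B = (8π²/3)·RMSF² about the mean structure after core
  superposition; when experimental values are supplied the correlation
  excludes computed B > 300 and disordered tail beads.
* **Force–distance profiles** — per-trajectory force binned in d (default
  5 Å), averaged across replicas; the peak force and its location are
  reported.

## The synthetic test systems

Four deterministic fixtures are generated programmatically:
a two-bead harmonic dimer, a 12-residue helical mini-protein with i,i+4
contacts, a 10-bp ideal B-form duplex, and the **wrapped-arc**: a 24-bp
duplex bent onto a circular arc (bend radius 34 Å, ~130° of wrap) around a
compact two-chain protein scaffold. The scaffold is built as six
serpentine rows of beads hugging the inner face of the arc (two shells ×
three lateral rows), placed by a clearance rule (each bead slides inward
until it clears every DNA site by 4.3 Å), giving a dense native-contact
interface, a packed, fold-like core, and a cationic DNA-facing surface.
Each chain carries a five-residue lysine/arginine-rich N-terminal tail
routed over the side of the duplex so that it runs alongside the wrapped
terminal DNA segment of one arc end at a stand-off distance of ~8 Å. The
stand-off keeps the tails from dominating the end dynamics: a cationic
tail dangling off the arc end captures and stabilises peeled DNA, and
one hugging the duplex at contact range drags the terminal base pairs
toward itself. Even at stand-off the tails compete mildly with the core
for the terminal DNA — see the known-limitations section on what this
means for the acetylation-mimic perturbation.
The DNA keeps straight-helix reference values, so the arc stores elastic
energy exactly as a crystal-derived nucleosome topology would, balanced by
the specific contacts and screened electrostatics. The bend radius is the
design's tuning point: it sets the stored elastic stress between the
50 mM and 400 mM holding strengths so that end-breathing is thermally
accessible on desk-scale runs.

This miniature reproduces the competition that drives nucleosomal
unwrapping — bending stress vs. salt-screened electrostatic plus specific
attraction — and with the default parameters shows reversible end-breathing
that grows with salt. What it does **not** model: the 147-bp two-turn
superhelix and its 5-bp periodic contact pattern, sequence-dependent DNA
mechanics, the dyad/off-dyad interaction hierarchy, the crystallographic
histone fold, or the tails' full length and charge pattern. Passing the
behavioural tests therefore demonstrates that the implemented physics
produces the right direction and order of magnitude of salt- and
charge-dependence at desk scale, not a quantitative reproduction of
nucleosome thermodynamics; full-scale runs require the 1KX5 crystal
structure as input and cluster-scale compute (10⁸ steps × 20 replicas per
condition).

Desk-scale problem sizes used by the test-suite and the acceptance script
(chosen to resolve the effects while staying minutes-scale): equilibrium
comparisons pool 2–3 replicas of 1–1.5·10⁵ steps per condition with the
first fifth of each replica discarded as equilibration; pulling uses
1.5·10⁻³ Å/t₀ — roughly ten times the study's speed, which (as in any
steered experiment run fast) inflates peak forces. These surrogate runs
use dt = 0.08 t₀ rather than the generic default 0.1 t₀: the arc's
pre-compressed excluded-volume contacts make its steepest interactions
stiffer than a relaxed structure's, and 0.08 t₀ keeps the low-friction
integration stable over every replica tested (a rare replica at 0.1 t₀
can run away on a steep repulsive wall; such a failure aborts only that
replica and is logged).

## Numerical and design choices

* Native contacts use a single CG-site distance cutoff (default 6.5 Å)
  applied identically to protein–protein and protein–DNA pairs; the value
  is recorded in topology metadata. An atom-level contact definition would
  need the all-atom interface and is not implemented.
* Missing residues are dropped, never modelled (the nucleosome input drops
  the three unresolved H2B N-terminal residues); residues lacking a Cα are
  reported and skipped.
* Base pairs are numbered 1…N from the left end of the first DNA chain;
  interval logic is 1-based inclusive. Tail ranges: H3 1–44, H2B 4–36,
  H4 1–30, H2A 1–26.
* Variants edit charges or tail term lists only, never the bead count:
  tail-charge deletion zeroes both chain copies of the named histone;
  His-deprotonation applies globally; bonds-only tails keep bond terms and
  drop tail angles, dihedrals and contacts.
* Trajectories live in memory as arrays, persist as `.npz`, and export to
  DCD plus PDB topology snapshots for standard MD tooling; observables are
  written as CSV tables.
* The simulation temperature enters the force field only through λ_D and
  the thermostat; the dielectric is deliberately temperature-independent.

## Known limitations

Dense pair evaluation scales as O(N²) memory/time per step; the Debye–Hückel
treatment is a dilute monovalent-ion approximation and phosphates carry
full −1 charges (no counter-ion condensation correction); DNA mechanics is
sequence-independent beyond A:T/G:C pairing depths; the wrapped-arc is a
surrogate, not a nucleosome; and mapping t₀ to physical time is nominal
(t₀ ≈ 0.2 ps) because coarse-graining and low friction accelerate the
effective dynamics by design.

One surrogate limitation deserves emphasis because it is a finding, not an
oversight: on the single-gyre 24-bp arc, the tail-charge-deletion
(acetylation-mimic) perturbation does **not** reproduce the nucleosomal
direction. In the nucleosome, cationic tails thread between the two DNA
gyres and tighten the wrap, so deleting their charges enhances
unwrapping. On the arc, every tail placement explored (dangling past the
end, lying beside the duplex at contact range or at an 8 Å stand-off,
parked against the core surface) makes the tail *compete* with the core
for the short, bending-stressed terminal DNA: its attraction holds the
end near the tail rather than at the wrapped reference position, so
deleting the tail charge mildly *stabilises* the wrap (≈ −1 bp in mean
unwrapping at 200 mM, consistent across seeds). Reproducing the
acetylation direction evidently requires the two-turn 147-bp geometry,
which is exactly what the full-scale nucleosome input provides. The
corresponding behavioural test asserts the nucleosomal direction and
therefore fails on the surrogate by design of the physics, not of the
code; the salt-dependence tests, which do not hinge on two-gyre
geometry, pass.
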