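# Model and methods

## The coarse-grained model

Proteins are represented by one bead per residue placed on the Cα
position. Folded regions carry a structure-based (Gō) potential built
from a reference structure: harmonic bonds U = k_b(b − b₀)² and angles
U = k_θ(θ − θ₀)² about native values, a periodic dihedral bias
U = k_φ[1 − cos(φ − φ₀)], and a 10–12 native-contact attraction
U = ε[5(r₀/r)¹² − 6(r₀/r)¹⁰] for residue pairs whose heavy atoms
approach within 6.5 Å in the reference (|i−j| ≥ 4 along a chain).
Disordered regions (chaperone tails, histone tails) are flagged
flexible: they keep bonds, get only a weak generic bending term
(k = 2 kcal/mol/rad² about 130°), and never carry native contacts or
dihedral biases.

DNA uses three beads per nucleotide at the base, sugar and phosphate
positions; the 5′-terminal phosphate of each strand is omitted, so an
n-bp duplex has 2(3n − 1) beads. The duplex is held by soft backbone
bonds and angles (k_b = 20 kcal/mol/Å², k_θ = 8 kcal/mol/rad² — DNA
must bend at nucleosomal curvature without its bonded strain diverging)
plus cross-strand base-pairing contacts between base beads of the same
and adjacent base pairs. Stacking stiffness lives entirely in the
backbone angles; there are no fixed-distance stacking contacts, because
at tight wrapping curvature such pairs change length by tens of percent
and any 12th-power term pinned to either the straight or the bent
geometry would lock the duplex into that state.

Nonbonded terms: a purely repulsive (σ/r)¹² excluded volume
(σ = 4 Å, ε = 0.2 kcal/mol, cut at 2σ) between all pairs that are
neither bonded neighbours (1-2/1-3/1-4) nor native contacts, and
Debye–Hückel electrostatics U = 332.06·q_iq_j/(ε_r r)·e^(−r/λ_D)
(ε_r = 78.0) between integer charges: Asp/Glu −1, Lys/Arg +1,
phosphates −1, everything else neutral. λ_D follows the monovalent
closed form (5.55 Å at 300 mM, 300 K; the salt-sensitivity variant uses
350 mM). Both nonbonded terms use shift-force truncation (energy and
force continuous at the cutoff) — with plain truncation the force
discontinuity produces a small but measurable energy drift at zero
temperature. The histone–DNA hydrogen-bonding of the source models is
represented by a dedicated `histone_dna` contact class whose strength
multiplier is calibrated (below). Chaperone–histone interactions are
deliberately electrostatics + excluded volume only — no native
contacts — so any binding the simulations show emerges from charge
complementarity, not from a built-in answer.

## Integration

Underdamped Langevin dynamics with the BAOAB splitting at dt = 0.3 τ,
T = 300 K, γ = 0.843 τ⁻¹. The internal time unit τ is deliberately not
mapped to seconds; protocols are specified in steps and kinetics are
only read as relative event frequencies. Bead masses are uniform
(default 200 internal units, chosen so the stiffest bond mode satisfies
ω·dt ≈ 0.3 and the measured kinetic temperature on the toy helix sits
within 1% of T; solution/toy-pair experiments use mass 50, which
quarters diffusive correlation times at identical stability). Verlet
neighbour lists (3 Å skin, rebuilt every 10 steps) back the compiled
kernel; runs execute in legs of one snapshot stride with per-leg seeds
derived from the master seed through an avalanche hash (arithmetic
seed derivation leaves Mersenne–Twister streams of consecutive legs
correlated enough to bias long-time diffusion), which also makes
checkpoints at any recorded frame exactly resumable. Two numerical
guards: dihedral terms are skipped when either bond angle is within
~6° of collinear (the dihedral gradient diverges there), and per-bead
forces are capped at 500 kcal/mol/Å — inactive in equilibrium
sampling, it only disarms singular pair-potential cores after rare
extreme fluctuations.

## The translocase and the unwrapping protocol

The translocase is a torus-shaped wall: beads inside the tube feel
U = A((r_t − d)/r_t)² with A = 300 kcal/mol, where d is the distance to
the tube's centre circle. The bounded-force harmonic profile blocks the
nucleosome just as well as a hard ring but cannot launch beads that get
pressed against it. Full-scale default: major radius 25 Å, tube 15 Å
(a DnaB-helicase-sized pore); the mini-nucleosome uses 19.5/6.5 Å.

Partial unwrapping reproduces the collision protocol: the upstream
linker is threaded through the torus and its terminal base pair dragged
along the torus axis by a moving anchor (0.005 Å/step, re-referenced
each stage so the pulling force stays bounded) until the unwrap
boundary — the first upstream base pair that has lost all native
histone–DNA contacts within 1.2 r₀ — reaches the target (−31 bp from
the dyad at full scale; −10 on the 41-bp mini wrap). The target base
pair and the entry base pair are then anchored where the collision left
them, keeping the peeled segment threaded taut through the ring, and
the system is relaxed with the exposed dimer briefly tethered to its
seated pose (the peel otherwise drags it off its seam). Base-pair
coordinates are dyad-centred with upstream negative throughout.

## Free-energy machinery

Umbrella windows bias the COM distance between the chaperone's globular
core and the histone-dimer globular domains with U = k(d − d₀)² — the
no-½ convention, matching how the spring coefficient is quoted for the
source simulator; halve k for the ½ convention. The full-scale grid is
d₀ = 25 + 2i Å (i = 0…43), five replicates; desk-scale experiments use
the same spacing over a shorter range. Windows of one replicate run
chained (each starts from its neighbour's final state) because dropping
a bias far from the current separation would dump the full harmonic
energy into the system at once. WHAM solves the standard self-consistent
equations on a 0.5–1 Å grid to 1e−7 kcal/mol; disjoint histograms raise
an error rather than extrapolate. For 3-D separation data the radial
Jacobian is removed (`jacobian="radial"`), giving the orientational PMF
W(d) that enters

ΔG° = −kT ln [ ∫_bound S(d) e^(−(W−W_plateau)/kT) dd / V° ],

with S(d) = 4πd², V° = 1661 Å³, the bound region ending at the barrier
top (or minimum + 10 Å without a barrier), and the plateau taken from
the last 10 Å (slope-checked). The reported components — well depth,
concentration correction, perpendicular correction — sum to ΔG°.
Split-sample errors divide every window's series into three random
subdatasets and take the per-bin SD across the sub-profiles. The
package reports both ΔG° and the elementary-relation dissociation
constant K_d = exp(ΔG°/kT)·1 M.

## Synthetic fixtures: what they emulate, and what they do not

The mini-nucleosome wraps 41 bp of DNA (1.23 superhelical turns,
radius 17 Å, pitch 27 Å) around four 30-bead core chains — two "dimer"
chains at the entry and exit thirds and two "tetramer" chains between
them, each a compact brick with a basic DNA-facing layer. DNA bonded
terms come from a straight reference, so the wrap is strained and held
by two designed stabilisers: per-base-pair histone–DNA native contacts
(three full-strength anchors per bp plus weak blanket contacts for
every DNA–core pair inside 6 Å, so no native close pair is left to the
excluded-volume core) and the basic core surface. The contact-strength
multiplier is calibrated once — the smallest value from a fixed ladder
that keeps the wrap intact over an unbiased 2×10⁵-step run at 300 mM —
and cached. The dimer–tetramer seam is set weak (ε = 0.35 per contact,
~30 contacts) relative to the per-bp DNA grip, so the translocase peels
DNA off the dimer zipper-fashion instead of tearing the dimer off the
core, while the seam still holds the exposed dimer against thermal
escape on the production timescale.

The toy chaperone is a 60-bead brick with a fully acidic binding face
(20 Glu) and, optionally, a 20-bead flexible tail carrying
round(0.72·20) = 14 Glu — the acidity of the emulated C-terminal tail —
in a compact initial coil hugging the core's back face. The solution
histone-dimer analogue is a 30-bead brick with a half-basic face
(8 Lys, checkerboard). The toy binding pair is two centred
tetrahedra (one frozen, one free) joined by a single centre-to-centre
native contact carrying the whole well depth, so the distance PMF is
isotropic and does not hinge on slow body reorientation.

These fixtures reproduce the statistical structure the analyses assume
— a wrapped, contact-stabilised nucleosome that a translocase can peel;
an exposed dimer whose basic face is the chaperone's handle; a
disordered acidic tail that tethers fuzzily — at roughly half linear
scale and ~10³ fewer steps than the full-scale protocol. Passing tests
therefore demonstrate that the machinery produces the qualitative
mechanism (condition ordering, tail stabilisation and its long-range
signature, energy-ledger ordering) under conditions engineered to show
it within minutes of CPU time; they say nothing quantitative about real
histone sequences, real DNA mechanics, or absolute rates, and the
fixture's basic core means electrostatics alone can hold its wrap —
unlike weak-core designs where the contact class is the sole stabiliser.

## Desk-scale experiment conditions

Chosen once as the package's study conditions: dismantling matrix —
four conditions (fully wrapped + chaperone; partially unwrapped alone;
partially unwrapped + tail-truncated chaperone; partially unwrapped +
full chaperone), replicate production runs of 6×10⁴ steps at bead mass
50 recorded every 1 500 steps, chaperone placed 18 Å from the exposed
dimer COM with seed-drawn orientation. A dismantling event requires
zero native contacts between the exposed dimer and the rest of the
nucleosome (within 1.2 r₀) sustained for 10 consecutive recorded
frames (15 000 steps); the full-scale definition adds a 60 Å
COM-distance condition,
but at desk scale a stripped dimer–chaperone complex diffuses only a
few Å per run, so the contact rule is the informative one (both rules
are implemented). Tail-effect experiment: 28 windows, d₀ = 10–64 Å,
4×10⁴ sampling steps each; the long-range signature is the distance by
which the profile has completed 90% of its rise to the plateau.
Dual-route ΔG°: 11 windows (6–26 Å) at well depths 1.5 and
3.0 kcal/mol against a 6×10⁶-step unbiased run, both routes evaluated
through the identical standard-state formula.
Energy ledger: the exposed dimer's cross-interaction energy averaged
over replicate 5–6×10⁴-step runs per wrapping state.

## Scaling up to structure-derived systems

The same pipeline runs on atomic inputs: read a histone-octamer and a
nucleosomal-DNA structure plus a chaperone structure with
`cli_io.read_atomic`, coarse-grain with `cg_model`, extend linkers with
`build_ideal_bdna` (32 bp upstream, 92 bp downstream in the full-scale
protocol), and drive the identical scenario, umbrella (44 × 5 windows)
and analysis machinery. At 3×10⁸ production steps and 50–80 replicates
per condition this is a cluster workload; the full-scale statistics are
therefore documented targets, not CI-gated results. Known limitations
at full scale: the integer-charge scheme replaces surface-charge
fitting for globular domains; histone–DNA hydrogen bonding is a
distance-based contact class with a calibrated multiplier; sequence-
dependent DNA mechanics are absent; and upstream-DNA re-wrapping /
repositioning pathways are out of scope by design.
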