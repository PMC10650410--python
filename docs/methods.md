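# Methods

This note documents the models and procedures hbpoly implements, the
parameters that matter, the numerical choices behind them, and what the
desk-scale tests do and do not establish.

## Polymer growth model

A polymer is a rooted tree of monomer residues. The root is a
1,1,1-tris(hydroxymethyl)propane (TMP) core exposing up to three activated
arms; every other node is a ring-opened epoxide residue joined to its
parent by an ether bond (alkoxide attack on the epoxide CH2), so residue
masses equal monomer molecular weights and the formula Mₙ is their sum.

Growth is two-staged, mirroring the two-stage synthesis of the real
copolymers. The hydrophobic block (1,2-epoxybutane for the R14-type
polymer, 1,2-epoxyhexane for R17) is laid down first as a linear run on
each arm — five units per arm by default, giving the 3 × 5 core. The
glycidol shell then grows stochastically: at each step a uniformly random
open attachment site and a uniformly random remaining monomer instance are
drawn, subject to the capping rule below.

Glycidol residues come in three species that differ only in how many of
the residue's two oxygens remain open for propagation: dendritic (2),
linear (1), terminal (0). The degree of branching is computed on the grown
tree as Frey–Hölter `DB = 2D/(2D+L)`, where D are glycidol units with both
substitution sites occupied and L those with exactly one; it is 0 when the
polymer carries no glycidol.

**Capping rule.** Terminal monomers are eligible only while two running
ratios are at or above their thresholds (both default 0.5):

* ramification ratio — placed dendritic / (placed dendritic + placed
  linear) glycidol units, defined as 1 before any glycidol is placed;
* non-terminal fraction — placed non-terminal monomers / all placed
  monomers, defined as 1 before any placement.

This prevents early capping of branches that would strand monomers. An
attempt that dead-ends (no open site, or only suppressed monomers remain)
is discarded and the growth is re-sampled from a deterministic seed
sequence (`default_rng([seed, attempt])`), up to 1,000 restarts; only
full-consumption topologies are ever returned. Each growth records a trace
of every stochastic choice with the ratios in force, so the rule can be
audited by replay.

The capping rule has a structural consequence worth noting: once all
dendritic and linear glycidol is placed, the ramification ratio is frozen
at D/(D+L), so any remaining terminals can only be placed if D ≥ L. A
monomer distribution with more linear than dendritic glycidol plus a
terminal excess is therefore unreachable under the default thresholds —
the rule itself constrains the admissible distributions. The built-in R14
and R17 pools use equal dendritic and linear counts (DB = 2/3 in the
fully-consumed tree) with totals sized so the formula Mₙ approximates the
GPC values of the purified copolymers (≈15,700 and ≈8,500 g/mol):
R14 = 15 epoxybutane + 65/65/65 glycidol D/L/T (Mₙ ≈ 15,661),
R17 = 15 epoxyhexane + 31/31/31 (Mₙ ≈ 8,526). The per-species numbers are
a design choice of this package; the experimental distribution behind the
original structures was not published.

**Rendering to chemistry.** Each monomer carries a SMILES fragment with
dummy atoms marking its inbound carbon and open oxygens. A topology is
rendered by bonding each child's inbound carbon to the oxygen of the
parent site it consumed and capping every unused oxygen as a hydroxyl; the
result is sanitized and canonicalized by RDKit. Atom bookkeeping is exact:
the rendered formula equals the fragment sum (tested by hand-summed
formulas).

## Structure preparation

SMILES are embedded with RDKit's ETKDGv3 distance geometry (fixed seed,
three attempts) and relaxed with MMFF94 (UFF fallback). This replaces the
genetic-algorithm molecular-mechanics minimization used to prepare the
original reference structures; since no reference conformations are
deposited, acceptance is geometric sanity (finite coordinates, no
non-bonded pair under 0.5 Å), not energy parity.

Protonation at a target pH uses a four-entry pKa rule table (carboxylic
acid 4.5, aliphatic amine 10.5, azole ring nitrogen 6.0, phenol 10.0)
applied by SMARTS matching; at pH 7.4 the polymers and both model drugs
(tinidazole, clotrimazole) are neutral. A rule table rather than a pKa
predictor is sufficient because only these group classes occur in scope.

Molecular weights sum IUPAC 2021 abridged standard atomic weights
(S 32.06, Cl 35.45), reported to two decimals; this reproduces
247.27 g/mol for C8H13N3O4S and 344.84 g/mol for C22H17ClN2 exactly.

## Solvated systems

Boxes are orthorhombic with edge = solute extent + 2 × margin per axis
(production default 15 Å; toy fixtures shrink this to stay within their
atom budget). Solvent is placed on a cubic lattice at the solvent's bulk
number density (water 0.0333 Å⁻³, methanol 0.01487, DMSO 0.00848),
randomly oriented, rejecting any molecule with an atom within 2.4 Å of a
solute. Water is rigid 3-site in SPC (1.0 Å, 109.47°) or TIP3P (0.9572 Å,
104.52°) geometry; methanol and DMSO are all-atom templates embedded once
from SMILES. NaCl pairs number `round(molarity × 6.022×10⁻⁴ × V[Å³])`,
plus counter-ions for any solute charge, created by converting randomly
chosen solvent molecules to ions; systems are neutral by construction and
validated as such.

Drug placement poses n randomly oriented copies just outside the polymer's
bounding sphere (radius + drug radius + 3 Å + up to 2 Å uniform), rejecting
poses within 3 Å of the polymer or of earlier copies.

## Drying and redissolution

One drying stage retains a solvent molecule iff its minimum atom-to-atom
distance to any solute atom, under the minimum-image convention of the
current box, is at most the stage's shell radius. This is the molecular
layer reading of "solvent kept within a shell around the solutes"; distances
use a periodic k-d tree and are tested against a brute-force O(N²)
minimum-image filter. Retained sets are nested under shrinking shells.
Ions evaporate with the solvent, except that the minimal counter-ion set
needed for neutrality is always re-added, nearest first — the original
protocol does not state how ions were handled, and this choice preserves
system validity while mimicking evaporation. The box is kept fixed after
removal (the drying stages are labelled NVT; a vacuum gap is allowed).

Redissolution rebuilds the box around the solutes, carries over residual
solvent and ions, and fills with water by the same lattice rules, topping
NaCl up to the target pair count for the new volume.

Preset schedules: the tinidazole route is Dissolving (methanol, NPT,
20 ns), six methanol-removal stages at shells 25/20/15/10/5/2.5 Å (NVT,
10 ns each), then Redissolving (water, NPT, 50 ns); the clotrimazole route
is the simplified four-removal variant (15/6/3/2 Å). A `duration_scale`
lets desk runs traverse the full stage structure with short trajectories.
Schedules validate that drying shells strictly decrease and that the first
and last stages are shell-free; the degenerate empty schedule is legal and
running it is a no-op.

## Engines

MD integration is injected behind a three-method contract (supported
ensembles; run(system, ensemble, duration, seed) → frames with unchanged
atom identity). Bundled: a null engine (identity frames) and a jitter
engine (cumulative Gaussian displacements, 0.05 Å sd per frame per
coordinate). These exercise composition bookkeeping, not physics: with
them, drugs placed outside the polymer stay unbound, so toy runs honestly
report zero attachment. The acceptance suite demonstrates the adapter
point with a drift engine that moves drugs toward the polymer and produces
attachment; reproducing the production-scale observables (polymer RG near
15.4/15.3 Å over 50 ns, ~3 polymer–drug hydrogen bonds after drying, 2 of
6 drugs retained after water redissolution) requires a real force-field
engine at cluster scale and is explicitly out of desk scope.

## Observables

* RG: mass-weighted, `sqrt(Σ mᵢ‖rᵢ−r̄‖²/Σ mᵢ)`; tested to 1e-10 against
  the direct sum and to 1e-9 under rigid motions.
* Polar surface area: Shrake–Rupley solvent-accessible surface (probe
  1.4 Å, 960 quasi-uniform golden-spiral points per atom by default,
  Bondi radii), summed over polar atoms only (N, O, S and hydrogens bonded
  to N/O). All atoms occlude; only polar atoms contribute area. Converges
  to <1 % on point doubling and matches analytic sphere areas for
  well-separated atoms. This is the conformation-dependent 3D quantity a
  per-frame PSA series requires, not the topological PSA of
  connectivity-only methods.
* Hydrogen bonds: D and A restricted to N/O, donor–acceptor ≤ 3.5 Å,
  ∠D–H···A ≥ 120°, both directions across the two molecule sets, each
  (D,H,A) triple once. The thresholds are configurable because the
  original analysis used an (unpublished) GUI default.
* Clustering: single linkage on minimum inter-molecular atom distance at a
  4.0 Å heavy-atom contact cutoff (configurable); partition = connected
  components, order-invariant. Attachment uses the same cutoff against the
  polymer.
* Solute molecules are made whole by a minimum-image walk over their bond
  graph before any measurement.

Series summaries report windowed mean ± sd and release events (first frame
at which a previously attached drug loses polymer contact).

## Formulation metrics

Efficiency is `round(100 × encapsulated/aimed)` (nearest integer; this
reproduces all printed efficiencies 93/88/90/83 from their count pairs).
Stock volume is `(polymer mg / Mₙ) × aimed × drug MW / stock mg·mL⁻¹`,
reported to 2 decimals. The published composition table's volumes do not
reconcile exactly with the aimed ratios under any single Mₙ choice, so the
planner is a forward calculator only and those volumes are not asserted.

## Toy fixtures and what the tests show

The toy world is fully seed-deterministic: a six-monomer pool whose legal
topologies are exhaustively enumerable, a ~40-heavy-atom polymer, a
12-heavy-atom nitroimidazole model drug, and a methanol box capped at
3,000 atoms (the solvation margin shrinks in 0.25 Å steps if a drug
arrangement would exceed the cap). The end-to-end pipeline — grow, embed,
pose six drugs, solvate, run a full preset schedule with the jitter
engine, analyze, report — completes in a few seconds.

Passing tests establish: exact bookkeeping (monomer conservation, valence
safety, charge neutrality, solvent-count monotonicity), agreement with
independent brute-force oracles (tree enumeration, O(N²) drying filter,
direct-sum RG, triple-loop hydrogen bonds, connected-component
clustering), determinism per seed, and correct protocol structure. They do
not establish anything about real solvation thermodynamics, drug binding
affinity, or release kinetics — those depend on the injected engine's
physics, which the bundled engines deliberately lack.

## Known limitations

* Monomer templates assume ether-linked epoxide ring opening; no
  stereochemistry, tacticity, or cyclic by-products.
* The lattice solvent fill approximates bulk density but is not
  equilibrated; real workflows would relax it with the injected engine.
* The pKa rule table covers four group classes; exotic ionizable groups
  are left neutral.
* PDB serial numbers wrap above 99,999 atoms and CONECT records are
  limited to solutes; systems beyond that scale should use the XYZ series
  for coordinates.
* Ion handling during drying (evaporate-with-solvent, neutrality floor) is
  a modelling choice; alternatives (always retain all ions) are one-line
  variants but change the dried system's composition.
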