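# Methods

## Scope and model

`igtandem` treats a single-chain Ig dimer as the composition of three
layers:

1. an **abstract topology algebra** over strand counts, sheet membership
   and strand directions, which decides which edge-to-edge fusions exist
   and what connects them;
2. a **measurement layer** that recovers β-architecture from coordinates
   (hydrogen bonds, strands, pairings, sheets, sandwich geometry, ABEGO
   torsion bins);
3. **screening and analysis** operating on those measurements or on
   externally produced tables (prediction confidences, fragment RMSDs,
   titrations).

The package does not run folding, structure prediction, sequence design or
molecular dynamics; it consumes their outputs (PDB models with per-residue
confidence in the B-factor column, CSV tables) and implements the
calculations layered on top of them.

## Topology algebra

A domain is `(n_strands, sheet_of, direction, loops)` in sequence order.
The two terminal strands pack on one sandwich edge; their relative
orientation is `+` (same) for odd strand counts and `−` (opposite) for even
ones. Placing a second domain against that edge admits exactly two proper
rigid arrangements, derived from the orthogonal placements of an oriented
box whose strand axis, layer axis and edge-face normal must align with the
first domain's. The head-to-head arrangement pairs the two N-terminal
strands antiparallel (the two-fold symmetric dimer); the other pairs
C-of-A with N-of-B in one layer — the sequence-local fusion — with
orientation given by A's terminal parity: parallel for odd counts (βαβ
helix connector, 12–16-residue helix, loop geometries `BAB` / `{BA, GB,
AGB, GBA}`), antiparallel for even counts (2–5-residue β-hairpin). The test
suite checks the enumeration against an independent exhaustive oracle over
the 24 rotations of the octahedral group for all strand-count pairs in
{6,7,8}².

Hairpin functionalization sites are the hairpin-classified loops of the
fused topology, numbered `EF1…EFk` along the sequence; a loop is "top" when
its preceding strand runs away from the termini side. The interdomain
bridge of antiparallel fusions is itself a site. Site equivalences for
equal-domain fusions pair sites at the same domain-local position (the two
domains are sequence repeats); this is deliberately *not* the molecular
two-fold map on strand indices, which relates a domain's first hairpin to
the other domain's last loop.

The 12→16-strand diversification series is modelled from 7+7: deletions
remove one terminal strand per interface layer (removing both domains' C
strands reproduces the 12-stranded scaffold exactly), insertions add one
or two interface strands through extra hairpin loops. Inserted strands
belong to neither domain; cross-domain top-site spacing counts strands
strictly between the sites and is non-decreasing along the series.

## Hydrogen bonds, strands, sandwich geometry

Backbone H-bonds use the DSSP electrostatic model with the amide hydrogen
rebuilt on the bisector of (C_prev→N, CA→N) at 1.01 Å, cutoff −0.5
kcal/mol, so input structures need no hydrogens. Bonds between residues
fewer than 2 positions apart *within a covalently continuous segment* are
excluded; segments are delimited by peptide-bond continuity (C–N ≤ 2.0 Å),
not by residue numbering, so ladders across chain breaks are kept.
β-bridges follow the Kabsch–Sander antiparallel/parallel patterns; strand
runs grow from bridged residues through residues that either participate
in the same ladders or have extended-bin torsions (this recovers strand
termini whose ladder phase leaves them without bonds of their own); minimum
strand length 3, minimum 2 bonds per accepted pairing. The pairing register
is the sum (antiparallel) or difference (parallel) of bridged indices.
Sheets are connected components of the pairing graph; edge strands have at
most one in-sheet partner — an isolated sandwich always has four.

A sandwich requires exactly two sheets of ≥ 2 strands whose plane normals,
oriented toward each other, are anti-aligned within 60°. Separation *d* is
the centroid distance along the mean normal; rotation *θ* is the unsigned
acute angle between mean strand directions (the sign is never needed).
Compatibility of two sandwiches for two-layer pairing is inclusive
thresholding on |Δd| and |Δθ|; the defaults (1.5 Å, 15°) are exposed
configuration, chosen here as a conservative reading of "similar" —
tighter than the mismatch that measurably strains the interface in the
pose builder (≈3 Å).

ABEGO bins (trans ω): `A` φ<0 and −75<ψ≤50; `B` φ<0 otherwise; `G` φ≥0 and
−100<ψ≤100; `E` φ≥0 otherwise; `O` |ω|<90°. These are the conventional bins
of blueprint-based design; the letters are standard but their numeric
bounds are rarely printed, so they are fixed here as a design decision.

## Synthetic fixtures

Strands are built by internal-coordinate chain construction at
(φ,ψ,ω) = (−139°, +135°, 180°) — the canonical antiparallel-sheet torsions,
which make the strand straight to <1° over 12 residues. Neighbour
placement uses two frozen pair transforms, derived once by scanning the
H-bond energy model and kept as constants: antiparallel, a 180° flip about
the sheet normal plus (0.14, 4.95, 0) Å (with a one-rung 3.465 Å shift for
even strand lengths, which keeps donors facing acceptors of matching pleat
parity); parallel, a translation (−0.02, 4.65, ∓0.95) Å. The planned
hydrogen-bond ladder then follows closed-form parity rules (donor parity
tied to the lower strand's flip state; acceptor mirrored for antiparallel,
one rung down for parallel), so detectors are tested against bookkeeping
independent of the detection code. At the frozen geometry each bond sits at
r(O·N) = 2.90 Å with energy ≈ −2.8 kcal/mol.

A sandwich is two such sheets: sheet 1 is the same construction rotated
180° about the in-sheet axis perpendicular to the strands — pleats face
inward and the terminal strands (slot 0 of each sheet) run antiparallel —
then rotated by θ about the normal and raised by *d*. The chain enters
sheet 0 at one edge and returns along sheet 1, so the N- and C-terminal
strands pack face-to-face on the same edge, as in an Ig fold. With this
construction a sequence-local edge-to-edge fusion of two copies is exactly
realizable (both interface ladders form simultaneously) when the strand
length is odd; for even lengths the two layers' ladder phases conflict by
one rung and the ideal dual-layer pose does not exist in the flat model —
pose-construction tests therefore use odd lengths, while detection tests
cover both. Loops are represented as residue-numbering gaps rather than
built coordinates; when an explicit loop length is given, feasibility is
checked against 3.8 Å per residue plus one (the Cα virtual bond), and
infeasible recipes are rejected.

What the fixtures deliberately do not model: strand twist and coherent
sheet curvature, side chains, irregular edges, β-bulges. Passing tests on
them demonstrates the correctness of the geometric rules and bookkeeping,
not robustness to the full irregularity of experimental structures.

## Edge-to-edge poses, connectors, face-to-face sampling

The pose builder places domain B so its designated terminal strands adopt
ideal partner geometry against A's terminal strands in both layers
simultaneously: antiparallel targets are the 180°-flip of A's strand about
the sheet normal moved out by 4.9 Å (4.8 Å parallel, canonical spacings),
registers shift along a common strand axis in 3.465 Å rungs, and the rigid
placement is solved by least squares over both layers at once. Poses are
scored by cross-domain H-bond count minus twice the clash count (backbone
atom pairs under 3.0 Å, intended pairings excluded); ties prefer register
0. The summed bond energy is also reported — it degrades smoothly with
geometric mismatch where the count, being thresholded, is insensitive to
strain below ≈4 Å of inter-sheet mismatch.

Connector backbones grow from an anchor residue through ideal per-letter
torsions (A −57/−47, B −120/+130, G +60/+40, E +60/−130, ω trans); closure
reports the end-to-end deviation and a feasibility flag from the anchor
span. The face-to-face sampler separates the domains 20 Å along the mean
sheet normal, then draws rotation (100–160°) about that axis, translation
(−15 to −5 Å) back along it, and tilt (−50 to −25°) about the in-plane
axis perpendicular to the strands, uniformly; these axis assignments are a
declared convention (the three parameter names alone do not fix them) and
are recorded with every output. A trial is closable when a 2–3-residue
linker can span the termini gap. One seeded generator drives each run.

## Filters

The TM-score uses d₀ = 1.24(L−15)^⅓ − 1.8 and is maximized by iterative
superposition seeded from windows of length 4, L/4, L/2 and L — an
approximation of the full alignment search, tested on self and near-self
pairs, with the frozen-superposition form exposed separately. The
composite confidence is pTM × (pLDDT/100) × TM, averaged over the top-3
models ranked by mean pLDDT ("max" is available as the alternative
reading; both the ranking metric and the aggregation are ambiguous in
common usage, so both are auditable). pLDDT is normalized to 0–1 inside
the product so the 0.6/0.7 decision thresholds are attainable. The
agreement filter takes per-model mean pLDDT and one or more RMSD
components, with strict inequalities; convergence is the all-models mode,
and the grafted-design mode screens the scaffold/linker/motif RMSD
decomposition (total excluded) at 4-of-5. Fragment quality requires, at
every position, at least one 9-mer RMSD strictly below the threshold
(presets 1.0/1.5/1.3 Å); fragment RMSDs are inputs, since fragment picking
needs an external database. Ensemble RMSF superposes frames on a selection
before computing per-residue CA fluctuations; named atom pairs yield
distance traces. The similarity network connects models at or above a
TM threshold, symmetrized as the mean of both directions, nodes annotated
with detected strand counts.

## Binding analysis

Intensities are normalized to bound fractions either min/max or — the
default — against a fitted plateau, which is robust when the curve does not
saturate. Fits are bounded least squares with K_d > 0, multi-started from
the low end, geometric mean and high end of the concentration range, on
replicate means. The hyperbolic variant matches the conventional 1:1 fit;
the depletion-corrected variant
`f = ((P+L+K_d) − sqrt((P+L+K_d)² − 4PL))/(2P)` is computed alongside
whenever P ≥ K_d/10, with a warning when P/K_d > 0.5 (at 10 µM protein and
a ~5 µM K_d the hyperbolic estimate is roughly two-fold high; the
simulator generates depletion-corrected truth, so the matched variant is
the accurate one). Concentrations are molar internally; CSV input may
declare µM/mM/nM. The competition conversion
`K_d = K_app/(1 + [probe]/K_d(probe))` is exact algebra and validated by
round trip. Fold changes propagate first-order standard deviations.

## Problem sizes and numerical choices

The test suite runs at desk scale by design: 100 randomized sandwich
fixtures (2–6 strands per sheet, 5–9 residues per strand, d 8–12 Å, θ
0–45°) for detection recovery; 200 Monte-Carlo titration draws per K_d in
{1, 5, 25} µM at 8 points, 2% multiplicative noise, 3 replicates; 4000
sampler draws for uniformity checks. Counts that required the original
large-scale design runs (tens of thousands of models) are out of scope;
the property-based suites above stand in for them. Degenerate inputs are
rejected early: fewer than 3 points for superposition, L < 16 for
TM-scores, constant titrations, non-positive concentrations, topologies
under 4 strands.

## Known limitations

* The flat-sheet fixture model omits β-twist; measured θ on real sandwiches
  mixes twist with the inter-sheet rotation the generator controls.
* The TM-score search is not a full structural alignment; unrelated
  topologies may score slightly below their true optimum (conservative for
  network edges).
* The pose builder assumes equal-length pairing strands at the interface
  and scores only backbone terms; side-chain packing and design are
  external.
* Anchor residue identities for hairpin bridges vary between published
  accounts of the same design; they are configurable input here, never
  hard-coded.
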