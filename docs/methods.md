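# Methods

This note documents the models, parameters and design choices behind
`solvinterface`, in the spirit of a package manual rather than a paper:
what is computed, under which assumptions, and what the synthetic tests
do and do not demonstrate.

## Structure model and chemical annotation

Structures are parsed from PDB text (gemmi) into a flat atom list grouped
by chain and residue. Alternate locations are collapsed to a single
conformer per atom — highest occupancy wins, ties go to altloc `A` — so
all downstream geometry is single-conformer and deterministic. Hydrogens
present in the input are discarded; polar hydrogens are re-placed
internally (below). Chain roles (`antibody-heavy`, `antibody-light`,
`antigen`) partition the complex; they are supplied, not inferred, as is
the IMGT position map (germline alignment is out of scope).

Van der Waals radii default to Bondi-like element values — C 1.70, N
1.55, O 1.52, S 1.80, H 1.20 Å — with vdW(H₂O) = 1.4 Å. All geometric
thresholds are parameterized by these radii, and the atom-type table is a
swappable columnar text file, so a different radius set changes nothing
structurally. Donor/acceptor assignments follow standard sidechain
chemistry; His is treated as NE2-protonated by default (ND1 acceptor,
NE2 donor), a choice that matters only for His-mediated hydrogen bonds.
Aromatic ring sets are Phe/Tyr six-carbon rings, the nine Trp indole ring
atoms, and the five His imidazole atoms; whether His rings count toward
the *aromatic* contact class is a classifier flag, off by default (the
aromatic class is Phe/Trp/Tyr).

Polar hydrogen placement is geometric: the amide H sits 1.00 Å from N on
the in-plane bisector pointing away from CA and the preceding carbonyl C
(proline and chain-initial residues get none); Trp HE1, His ring N–H,
Arg HE use the analogous ring/plane bisector; Arg NH1 gets two in-plane
hydrogens at 120°. The seven torsionally flexible donors (Arg NH2,
Lys NZ, Ser OG, Thr OG1, Asn ND2, Gln NE2, Tyr OH) deliberately carry
**no** fixed hydrogen: the hydrogen-bond detector scans their torsion, so
fixing a proton would only bias that test. This replaces an external
protonation step with no loss for the detectors implemented here.

## Water placement

The water-oxygen probability density map (PDM) is a voxel grid (default
spacing 0.5 Å, margin 2 × 1.9 Å beyond the bounding box). Each heavy atom
contributes a Gaussian radial shell w·exp(−(d−μ)²/2σ²) with two atom
classes: polar N/O at μ = 2.8 Å, σ = 0.35, w = 1.0 (first-shell
hydrogen-bond distance) and C/S at μ = 3.5 Å, σ = 0.5, w = 0.25 (van der
Waals contact shell). Voxels inside any vdW sphere are zeroed. This
kernel is an internal construction chosen to reproduce first-shell
geometry well enough to exercise the placement loop; the grid interface
is pluggable, so an externally trained probability map with the same
layout can be substituted without touching the placement code.

Greedy placement takes the live voxel of maximal positive value, resolves
clashes by moving the water directly away from the nearest clashing atom
to vdW(atom) + 1.4 + 0.01 Å (the 0.01 Å step-out is a numerical guard;
at most 10 cycles, then the placement is abandoned), records the water,
and retires live voxels within 1.4 Å. The seed voxel is retired in all
cases, so the loop always terminates. Ties on the maximum take the lowest
linear voxel index, making placement fully deterministic.

The interfacial space flags voxel centers whose gap to the nearest atom
(distance minus radius) is in (0, 1.9 Å] for **both** sides of the
partition; 1.9 Å = vdW(H₂O) + 0.5 Å is the solvation-layer probe. META
pooling sweeps waters by (priority rank, input order) and keeps a water
iff no kept water lies within 3.3 Å; deduplication is global, so
near-duplicates within one source are removed too. The RANDOM baseline
greedily accepts a seeded random permutation of flagged voxel centers
under the same 3.3 Å exclusion, which guarantees saturation (every
remaining flagged voxel is within 3.3 Å of an accepted water). Benchmarks
match reference oxygens to predicted oxygens at ≤ 1.4 Å and report
precision, recall and F-score with 0/0 defined as 0.

## Interaction detectors

Contact pairs use d < vdW(x) + vdW(y) + 0.5 Å over cross-partition heavy
atoms (k-d tree candidate search; unit tests pin the output to an O(n²)
enumeration). Classification is by precedence so the per-class counts
partition the pairs: antibody-side aromatic ring carbon → aromatic;
both carbons → non-aromatic C–C; carbon vs N/O → carbon–polar;
donor–donor / acceptor–acceptor by flags; otherwise other-polar. The
non-aromatic C–C class accepts any antigen-side carbon, aromatic or not.

Direct hydrogen bonds: rigid donors need an attached hydrogen with
D–H–A ≥ 150° and D–A ≤ 3.5 Å. Flexible donors replace the angle cutoff
with a hydrogen-between test: candidate hydrogens are generated at ideal
bond geometry (O–H 0.96 Å / N–H 1.00 Å; tetrahedral or trigonal X–D–H
angle) on a 36°-step torsion cone around the antecedent–donor axis, and
the bond is accepted iff some candidate has H···A ≤ 2.8 Å and
D–H–A ≥ 120°. This is deliberately weaker than the rigid 150° rule —
the flexible donors' angle criterion is off by construction — while
still requiring a proton oriented between donor and acceptor.

Water-mediated bonds treat the water as a rigid body (O–H 0.9572 Å,
H–O–H 104.52°, the experimental gas-phase geometry) rotated through ZYZ
Euler angles α, β ∈ {0°, 36°, …, 324°} and γ ∈ {0°, 36°, …, 144°} —
10 × 10 × 5 = 500 orientations, the half-range of γ exploiting the C₂
symmetry of water. Donating to a protein acceptor requires O–A ≤ 3.5 Å
and O–H–A ≥ 150° for an oriented hydrogen; accepting from a protein
donor reuses the rigid/flexible direct-bond test with the water oxygen as
acceptor and is orientation-independent (the lone pairs are not modeled).
A bridge is emitted per (antibody partner, antigen partner) pair with at
least one **common** satisfying orientation — the stricter of the two
possible readings; per water and atom pair, one bridge is reported.

## CDR statistics

Position profiles report, per IMGT position and residue type, the
percentage of complexes showing an interaction class there; per-complex
profiles report the percentage of CDR positions showing the class.
Contact-preference log-odds use a symmetric pseudocount α (default 1):
P_n(x,y) = log₂ of the α-smoothed observed frequency over the α-smoothed
null frequency, for contact groups 1 (carbon–carbon pairs), 2 (direct
bonds) and 3 (water bridges). The NNK background enumerates the 32 codons
N∈{A,C,G,T} × N × K∈{G,T}, drops the single stop (TAG) and normalizes
over the 31 sense codons, giving p_i ∈ {1, 2, 3}/31. LOGO heights are
signed per-letter relative-entropy contributions d_ji = q_ji·log₂(q_ji /
p_i) for q_ji > 0 (zero otherwise); negative heights mark depletion, and
column sums equal the KL divergence from the background when all letters
are observed. Profile comparisons use Pearson r with the two-sided
Student's-t P for r = 0 on n − 2 degrees of freedom; when two profile
matrices are compared they are flattened row-major with entries that are
zero in both dropped. No multiple-testing correction is applied.

## Dataset curation and decoys

The selection filter applies, in order: antigen length ≥ 35 residues; CDR
completeness; CDR lengths (13, 10, 11, 8, 9) for H1, H2, L1, L2, L3;
a conformational epitope (contact-derived epitope residues split into
segments wherever the residue-number gap exceeds 2 — the tolerance
admits short unresolved stretches inside one segment); and greedy
heavy-chain clustering at 95% identity (best ungapped sliding-offset
matches over the longer length), keeping the first representative per
cluster in input order. Canonical-structure class membership is declared
in configuration, not computed.

The decoy sampler replaces an external docking program as the null
model: the antibody is rotated so its native paratope faces a random
non-epitope patch of the antigen (random spin about the approach axis,
tilt up to 25°), slid into contact in 0.4 Å steps, and accepted when no
heavy-atom pair is closer than 0.7 × the vdW sum, the decoy epitope
shares no residue with the native epitope, and the transformed paratope
centroid lies within 8 Å of the contact centroid (the paratope-centering
criterion). Survivors are ranked by cross-partition contact count — the
geometric-complementarity score — and the top n returned. All sampling
is driven by a single integer seed.

## Synthetic data

`make_toy_complex` plants features at exact detector geometry (hydrogen
bond at 2.9 Å/180°; water bridge aligned to orientation index 0 with the
acceptor at 2.85 Å and the donor at 2.90 Å; aromatic and C–C contacts
0.2 Å inside threshold), 10 Å apart so features cannot interact, with
residue numbering striding between features so multi-feature epitopes are
conformational. Gaussian coordinate noise σ degrades features
progressively. `make_hydrated_interface` builds two facing oxygen walls
(6 Å lattice, 5.8 Å separation) whose kernel-peak hydration sites, 2.8 Å
above the interior antibody-side oxygens, sit inside the interfacial
space; it is the substrate for the guided-versus-random placement
comparison. Problem sizes in the test and acceptance runs — 100 benchmark
fixtures, 50 detector-oracle complexes, 20 bridge seeds, 20 hydrated
interfaces × 3 random seeds — were chosen as the smallest sets at which
the compared quantities stabilize.

These generators are chemically simplified: poly-glycine/alanine
fragments, no backbone continuity, no rotamers, no energetics. Passing
tests therefore demonstrate the *geometric correctness* of the detectors
and the placement loop, not predictive accuracy on real antibody–protein
complexes; on the synthetic hydrated interfaces the guided-over-random
recall margin is narrower than on real structures because a saturated
random packing of a thin, ideal interfacial slab is itself a strong
baseline.

## Known limitations

* The PDM kernel is a stand-in construction, not a trained probability
  model; absolute placement accuracy on real surfaces is untested.
* Water-as-acceptor geometry ignores lone-pair directionality.
* His tautomer and protonation states are fixed, not predicted.
* mmCIF, nucleic acids and ligand chemistry are out of scope; unknown
  atoms fall back to element-default radii with all role flags off.
* The identity-clustering stand-in is ungapped; indel-containing
  near-duplicates may escape clustering.
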