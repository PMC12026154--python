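# Methods

This note records the models, parameter choices and numerical conventions
behind lipoflex, in the spirit of a package's own methods documentation:
what is computed, what is assumed, and what the synthetic tests do and do
not demonstrate about real structures.

## Structures, bonds and hydrogens

Structures are plain ATOM-record PDB files; trajectories are multi-model
PDB (MODEL/ENDMDL), kept as the canonical format so fixtures stay text and
diffable. Waters and non-protein HETATM records are dropped on read, the
first alternate location is kept, insertion codes are rejected, and input
hydrogens are discarded (the scorer rebuilds its own set). Covalent bonds
come from internal topology templates for the 20 standard residues plus
sequence-consecutive peptide bonds (gated at C–N ≤ 1.8 Å so chain breaks
are honoured) and SG–SG disulfides auto-detected at ≤ 2.5 Å; CONECT records
are never needed. Once a model is built its bond graph is carried along —
downstream stages never re-derive topology from perturbed coordinates.

Hydrogen augmentation produces only the semi-essential set used by
hydropathic scoring: hydrogens on N/O/S, on unsaturated (sp2/aromatic)
carbons, and on carbons alpha to a heteroatom. Counts follow element
valences against the realised bond graph with neutral-pH overrides (His
neutral ε-tautomer with H on NE2; Lys ammonium with three H; Asp/Glu and
the C-terminal carboxylate deprotonated; disulfide cysteines lose the
thiol H automatically because the SG degree is 2). Placement is ideal
internal geometry: N–H 1.01 Å, O–H 0.96 Å, S–H 1.34 Å, C–H 1.09 Å;
sp3 completion by the negative neighbour-vector sum, in-plane bisectors for
sp2, anti (trans) dihedrals for hydroxyls/thiols, staggered triples for
methyl-like and ammonium groups. Hydrogen names are systematic
(`H` + parent suffix + index: HZ1–HZ3 on Lys NZ, HH11/HH12 on Arg NH1), and
the parameter table is generated with the same rule so lookups never miss.

## Hydropathic scoring

The intramolecular score sums micro-interactions over all atom pairs that
are neither covalently coupled (bond-graph distance ≤ 3, i.e. 1-2/1-3/1-4
excluded, standard non-bonded practice) nor beyond a 9 Å cutoff (the
conventional MD non-bonded cutoff, reused for consistency):

    b_ij = S_i a_i S_j a_j R(r_ij),    R(r) = exp(-r / 1 Å),   B = Σ b_ij.

* **S_i** is the atom's solvent-accessible surface area computed on the
  whole protein and frozen during pairwise scoring, so buried atoms score
  near zero — the solvent-modulated design of hydropathic scoring.
* **a_i** is the hydrophobic atom constant. No published per-atom set
  exists for this engine, so the shipped table is authored from residue
  chemistry with octanol/water logP fragment reasoning: aliphatic carbons
  +0.5 (+0.1 when bonded to a heteroatom, the alpha positions), aromatic
  carbons +0.3 (+0.1 with polar substitution), carbonyl/carboxamide/
  guanidinium carbons −0.3, backbone N/O −0.6/−0.8, hydroxyls −0.7,
  carboxylates −1.1 (acid class), Lys/Arg nitrogens −1.2/−1.0 (base
  class), His ring nitrogens −0.5 (amphoteric), thioether S +0.3, thiol S
  −0.2; polar hydrogens −0.1, nonpolar hydrogens +0.1. The engine is
  therefore "HINT-style": the architecture and formula are standard, the
  constants are this package's own, and every numeric assertion in the
  tests is made within this parameter set. The table ships as TSV
  (`lipoflex/data/hint_params.tsv`) and any compatible table can be
  supplied instead.
* **Classification.** A pair is a hydrogen bond when a donor/acceptor role
  pair passes the geometry test (polar H within 2.5 Å of the acceptor and
  donor–H–acceptor angle ≥ 120°, a deliberate simplification of lone-pair
  directionality vectors; both the heavy-pair and the H–acceptor pair are
  classed as hydrogen bond). Otherwise acid+base pairs are
  electrostatic-favorable; acid–acid and base–base pairs are
  electrostatic-unfavorable and their score is forced negative (repulsive
  Coulombic — the raw product of two negative constants would be positive,
  so the class semantics, not the raw sign, decide favorability for
  like-charged pairs); two positive-a atoms are hydrophobic; mixed
  hydrophobic/polar products (< 0) are desolvation; remaining polar–polar
  pairs count as electrostatic-favorable. Components sum to the total
  exactly by construction, and per-residue totals attribute each b_ij half
  to each partner.
* Scoring operates on a single structure by default; an across-frames mode
  (mean ± SD per component) is available for trajectory error bars.
* Water-mediated contacts are out of reach of a waterless model, so
  bridged hydrogen bonds (e.g. via crystallographic waters) are absent by
  design.

SASA is Shrake–Rupley with a deterministic golden-spiral lattice (256
points, probe 1.4 Å; van der Waals radii C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20 Å). The lattice is expressed in a molecule-fixed frame (principal
axes with a skewness-based, rotation-equivariant sign rule), which makes
areas — and therefore scores — invariant under rigid motion of the whole
molecule to ~1e-9 relative. For pathologically symmetric point sets with
zero coordinate skewness the frame falls back to a fixed convention and
exact invariance is no longer guaranteed; proteins are never in that
regime.

## Mutagenesis

Mutations are restricted to targets whose side chain is an atom subset of
the source after defined element swaps, so results are deterministic and
rotamer-free; this covers Y→F, Y→A, C→S, C→A and any X→A/X→G, i.e. the
truncation mutations this workflow needs. Reproducibility was preferred
over generality: anything requiring a rotamer choice is refused with a
pointer to external tools. For C→S the SG atom is renamed OG, its element
set to O, and the CB–OG distance rescaled to 1.41 Å (standard C–O single
bond) along the existing CB→SG direction. Atoms that are neither deleted
nor rescaled are copied bit-identically. Mutants are scored as mutated,
without a minimization step in between; with minimization the scores would
shift by the local relaxation, which is outside this package's scope.

## Trajectory metrics

Superposition is weighted Kabsch (proper rotation enforced; collinear
references rejected). RMSD superposes every frame on a reference frame.
RMSF fits frames to the time-average structure (one refinement pass —
average, fit, re-average, fit — the convention of standard MD tooling;
`fit=False` gives raw fluctuations) and reports per-residue values on a
configurable atom selection (default Cα). Radius of gyration is
mass-weighted by default. SASA series re-run Shrake–Rupley per frame in
the whole-protein context; a stride parameter trades resolution for time.

The helix–barrel interface distance is the mean (or min) over an explicit
Cα pair list per frame, summarised as D_max and D_ave ± SD. The pairing is
configuration: when only residue ranges are known, a default pairing maps
each barrel-interface residue to its nearest helix Cα in the reference
frame — a replication choice that should be stated alongside any numbers
it produces. Tail averages (e.g. Rg over the equilibrated end of a run)
default to the last 40% of frames, configurable.

Essential-dynamics PCA superposes frames on their average, eigendecomposes
the 3N coordinate covariance (via SVD; divisor n−1), and reports
eigenvalues, PC1/PC2 projections, per-component ranges and explained
variance fractions, in Å by default with an nm toggle for comparison with
nm-reported essential subspaces.

Flexibility differencing flags residues whose RMSF changes by at least
0.7 Å — inclusive, so exactly +0.70 Å counts; a mutated position is matched
by residue number despite its name change. Wild-type RMSF ≥ 2.5 Å marks
intrinsically mobile residues. The shipped epitope annotation is the
published Discotope prediction for the allergen (13 residues in three
conformational epitopes); annotation entries absent from a profile warn
rather than fail, since truncated constructs are common.

## Synthetic ground truth

The toy protein emulates the lipocalin topology at reduced scale: 8
strands × 8 residues traced antiparallel on an 8 Å cylinder plus a
10-residue ideal α-helix (φ=−57°, ψ=−47°; strands φ=−139°, ψ=+135°), built
by natural-extension-reference-frame chain growth with ideal bond
geometry, poly-Leu bodies with Ala segment caps, side chains truncated at
CB so residue-level ground truth stays exact, and a fixed helix phase
chosen once so the default fold packs without steric clashes (minimum
interatomic distance 1.3 Å; anything under 1.0 Å raises). The helix Cα
centroid rests at `helix_offset` (default 4.25 Å) from the facing strand's
centroid. Full-side-chain ideal peptides (for the scorer's tests) graft
side chains from the chemical component dictionary's ideal residue
geometries onto the generated backbone.

The harmonic generator displaces each residue rigidly by iid Gaussian
noise (per-coordinate σ, per residue), making the per-residue RMSF ground
truth exactly σ√3. The breathing generator displaces the helix rigidly
along the barrel normal; because the helical trace wobbles perpendicular
to that normal, a fixed translation amplitude would not modulate the mean
Cα pair distance as a pure sine, so the per-frame displacement magnitude
is instead solved by 1-D root finding until the mean matched-pair distance
equals d₀ + A·sin(2πt/T) exactly, after which small Gaussian jitter
(default 0.02 Å) is added. Matched pairs are those whose connecting vector
tracks the breathing normal (perpendicular offset ≤ 2 Å). Defaults follow
the contrast the workflow is built to resolve: d₀ = 4.25 Å (the compact
mutant's average interface distance) with amplitude 1.65 Å, so the peaks
reach the ≈5.9 Å excursions of the flexible proteins; 500 frames at period
100 sample whole periods, making the time-average equal d₀ up to jitter.

What the synthetic tests demonstrate: the estimators recover known
fluctuation amplitudes, collective modes and interface-distance statistics
to their stated tolerances, and the scorer agrees with an independent
brute-force sum to ~1e-14. What they do not demonstrate: force-field
realism, rotamer dynamics, solvent effects, or that the authored
hydropathy constants reproduce any proprietary parameter set — comparisons
across proteins are meaningful within this table, not against other
engines.

## Numerical conventions and limitations

* Tolerances: scorer vs brute force 1e-10 relative (observed ~1e-14);
  PDB round trips limited by the 3-decimal fixed-column format (1e-3 Å);
  rigid-motion invariance 1e-9 (scores) / 1e-6 (metrics).
* RMSF recovery uses 2000 frames (observed worst-case error ≈2.6%,
  specified band 5%); breathing recovery uses 500 frames (D_ave error
  ~1e-4 Å against a 3·SEM band of ≈0.16 Å; D_max within the sine sampling
  step, jitter contributing ≈0.02 Å). Problem sizes were chosen so the
  whole suite runs in about a minute on one core.
* Ties and degeneracies: identical-eigenvalue PCA components have
  arbitrary but deterministic orientation; the SASA molecule frame falls
  back to a fixed convention for skewness-free point sets; single-atom
  systems skip neighbour occlusion entirely.
* The pipeline writes byte-identical outputs for identical configurations
  (stable column order, fixed float format, no timestamps); the run log
  records a hash of the scientific configuration (output paths and log
  verbosity excluded).
* Known limitations: no mmCIF, no hetero-ligand chemistry, no explicit
  water or ions, no pKa calculation, no rotamer repacking, no MD. Mutants
  are scored unminimized. The default interface pairing is a stated
  replication choice, not a recovered quantity.
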