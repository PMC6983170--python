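# Methods

## Geometry model

A halogen bond between a ligand C–X group (X ∈ {Cl, Br, I}; fluorine's
σ-hole is too weak and F is excluded throughout) and an acceptor atom A is
described per frame by the distance d = |X···A| (Å) and the σ-hole angle
θ = ∠(C–X···A) (degrees, vertex at the halogen). θ is computed as the
arccos of the normalized dot product of the X→C and X→A vectors; a
zero-length vector raises a degenerate-geometry error rather than
returning a value.

The (d, θ) plane is split by two cutoffs, `d_cut = 4.0 Å` and
`theta_cut = 140°`, into four regions: primary (d < d_cut and
θ > theta_cut), secondary_short (d < d_cut only), secondary_long
(θ > theta_cut only) and none. The favourable inequalities are strict, so
points exactly on a boundary fall in the less favourable region; because
the boundaries have measure zero this convention cannot move any occupancy
statistic. No outer distance bound is applied: a tracked contact is
measured in every frame, however far it drifts.

Acceptors are classified **c** (backbone carbonyl O, atom name `O`) or
**s** (side-chain O/N: Ser OG, Thr OG1, Tyr OH, His ND1/NE2, Asn/Gln
O/N-amide, Asp/Glu carboxylates, Lys NZ, Arg NE/NH1/NH2, Trp NE1). For
histidine both ring nitrogens are tracked as candidate acceptors; the
report keeps the one with the higher primary occupancy and records which
was used, since which nitrogen accepts is structure-dependent and should
not be hard-coded. Covalent C–X bonds are inferred from a 1.6–2.2 Å
distance window instead of CONECT records, which are often absent.

## Statistics

* **Occupancy** is the fraction of frames whose region label is `primary`;
  per-region fractions always sum to 1.
* **Mean ± SD** uses the population SD (ddof = 0): the trajectory is the
  entire population being described, not a sample from a larger one.
* **Interval medians and boxplots** slice time into half-open windows
  `[k·L, (k+1)·L)` anchored at the first frame time, with the final frame
  joining the last window, so a 60 ns run at the default L = 6 ns gives
  exactly 10 intervals. Quartiles use linear interpolation; whiskers are
  the most extreme points within 1.5·IQR of the quartiles. Empty windows
  are reported as NaN, not errors.
* **Ligand RMSD**: each frame's binding pocket (Cα of receptor residues
  with any atom within 6 Å of the ligand in the reference frame) is
  least-squares (Kabsch) superposed onto the reference, then the ligand
  heavy-atom RMSD is taken without re-fitting the ligand — the statistic
  measures binding-mode drift in the pocket frame.
* **Clustering**: average-linkage hierarchical clustering of the pairwise
  ligand-RMSD matrix (after pocket superposition), cut at k = 10 clusters
  by default. The representative frame is the member of the most populated
  cluster minimizing the summed RMSD to its cluster members; every tie
  (cluster size, representative) breaks deterministically by frame order.
  When the distance structure is degenerate and the linkage cut yields
  fewer than k clusters, trailing frames are peeled into singletons in
  frame order so exactly k clusters are always returned.
* **Replicate selection** scores each replicate by CV(d) + CV(θ)
  (CV = population SD / mean) and returns the argmin, ties to the lowest
  index — the replicate with the most stable XB geometry.

## XSAR and chemotypes

An XSAR set pairs a non-halogenated parent with every derivative whose
graph, after replacing its aryl-bound Cl/Br/I with H and canonicalizing
(RDKit), equals the parent's canonical graph; multi-substitution is
allowed and aliphatic halogens are ignored by default. The Xeffect is the
exact activity ratio parent/derivative on a lower-is-better nM scale, so
it obeys ratio algebra (identity 1, transitivity) exactly; inputs in pKi
must be converted by the caller.

The PI–AR distance embeds 20 conformers (ETKDGv3, fixed seed), relaxes
them with MMFF94, and takes the median distance from the basic nitrogen
(PI: non-aromatic amine, aryl-conjugated and amide nitrogens excluded,
ring amines preferred) to the centroid of the halogenated — or, for a
parent, candidate-halogenation — aromatic ring (AR). The ensemble median
is robust to occasional poor embeddings and deterministic under the seed.
The class threshold 4.75 Å is the midpoint of the two reference class
distances (5.6 Å arylpiperazine, 3.9 Å benzylpiperidine); the short-class
representative used in tests and in the acceptance script is
1-benzylpiperidine, whose N–CH₂–aryl geometry (~3.8 Å from the basic N to
the ring centroid) matches the short class value, whereas a 4-benzyl
isomer would sit near 6.3 Å.

## Synthetic trajectories

The generator emulates the one statistical feature the analysis relies
on: a contact switching between a bound state (crystal-like geometry,
primary region) and a broken state. Per frame a state is chosen — i.i.d.
by mixture weights, or by a symmetric 2-state Markov chain with a given
stay probability — and (d, θ) are drawn from that state's Gaussians,
truncated by redraw to d > 2.5 Å and θ ∈ [0, 180]. The default spec is a
60 ns trajectory (2000 frames at 30 ps) with a 0.6/0.4 bound/broken split
at (3.8 ± 0.3 Å, 163 ± 8°) vs (5.2 ± 0.5 Å, 115 ± 15°), the occupancy
scale seen for strong D4-pocket halogen bonds.

Coordinates realize each draw exactly: the acceptor O is placed at
distance d from the halogen on a cone about the C–Cl axis whose opening
reproduces θ, with a random azimuth. This decouples the statistical tests
from coordinate noise — measured (d, θ) equal the planted values to
machine precision, so any discrepancy downstream is a pipeline defect,
not sampling error. The topology is minimal (a 4-heavy-atom chloro
ligand, a valine-like acceptor residue riding on its carbonyl O, four
static pocket Cα for superposition). What the generator does **not**
emulate: force-field physics, solvent/membrane, correlated receptor
motions, multiple simultaneous contacts, or realistic ligand flexibility.
Passing tests therefore demonstrate the correctness of the measurement
and statistics pipeline, not the realism of any MD protocol.

Note one deliberate property: because per-state (d, θ) distributions can
straddle the region cutoffs, planted *state* weights and measured
*region* occupancies coincide only when the states are well separated;
the statistical recovery tests use well-separated states (5σ from each
cutoff) so the planted weight is the ground-truth occupancy up to
binomial sampling error (tested at 3·sqrt(p(1−p)/n)).

## I/O and numerics

PDB parsing/writing and DCD/XTC reading go through MDAnalysis; multi-model
PDBs map to frames, B-factors and HETATM flags are preserved, altloc 'A'
or blank is kept, and ligand atoms default to non-water/ion HETATMs.
Coordinates are Å, times ns, angles degrees; PDB output carries 3-decimal
coordinates, so round trips are exact only to that precision. Generic
residue numbering is a user-supplied TSV lookup (`chain residue_seq
label`); no alignment is computed. Clustering distances, quartiles and
superpositions use scipy/numpy throughout; hierarchical clustering seeds
nothing (it is deterministic), and every stochastic routine (conformer
embedding, synthetic generator) takes an explicit integer seed.

## Problem sizes

The test suite works at 1000–5000 frames for statistical checks, 100
random instances per numerical-oracle comparison (tolerance 1e-8), 10,000
points for the region-partition sweep, and 20-conformer ensembles for
pharmacophore distances — sizes at which the binomial and SE bounds used
in the assertions are already tight while the whole suite runs in
seconds.

## Known limitations

* Donor perception assumes each halogen has exactly one covalent carbon
  within 1.6–2.2 Å; exotic bonding raises a perception error.
* Acceptor perception is name-based (wwPDB atom nomenclature); renamed
  atoms in non-standard force-field PDBs will not be recognized.
* The c/s acceptor table covers O/N side-chain acceptors only; π-systems
  and sulfur acceptors are out of scope.
* Element inference for PDBs lacking the element column is heuristic
  (two-letter halogen/metal names recognized for HETATMs).
* The Xeffect is a raw activity ratio; no error propagation from assay
  noise is attempted.
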