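# Methods

## Gate-closure coordination numbers

Closure of each side of an alternating-access transporter is quantified by
a smooth coordination number between two residue groups flanking the gate:

    C = Σ_{i∈group1} Σ_{j∈group2} [1 − (r_ij/R)^6] / [1 − (r_ij/R)^12]

with r_ij the distance between non-hydrogen atoms and switching radius
R = 4.5 Å. The rational has a removable singularity at r = R; it is
evaluated through the algebraically identical form 1/(1+(r/R)^6), which is
finite everywhere and equals 0.5 exactly at r = R. Tests keep the printed
form (in extended precision) as the oracle. All cross pairs are summed
exactly; the optional neighbor-list path uses a lossless cutoff placed
where a single pair contributes less than 1e-12 (≈ 100·R), so the two
paths agree to well below 1e-9. Group disjointness is enforced because
self-pairs are undefined in a cross-group sum. Default residue groups for
the MPC1/MPC1L/MPC2 protomers are built in; chains, residues and R are
configurable.

A value of ~100 on a gate means on the order of a hundred cross-gate atom
pairs in contact — a closed pathway; values near zero mean an open one.

## Quality filtering and k-medoids landscape clustering

Models are retained when their interface-quality score is strictly greater
than the threshold (default 0.4); missing scores are an error unless a
drop-and-log flag is set. Retained models are clustered in (C_N, C_C)
space with PAM k-medoids: k-medoids++ (D²-weighted) seeding, alternation
of nearest-medoid assignment and within-cluster medoid updates, followed
by greedy single-swap refinement until no medoid/non-medoid exchange
lowers the cost — the result is locally optimal under single swaps.
Defaults: k = 9, Euclidean distance on raw coordinates (z-scoring
available as a flag), maximum distance-matrix dimension 5000; larger
inputs are subsampled uniformly at random (seeded) for the medoid search
and all points are then assigned to the nearest medoid. Everything is
deterministic given the seed; ties break to the smallest index /
lexicographically smallest model id.

Each cluster's representative is the member minimizing the mean Euclidean
distance to all members of the cluster in metric space (for a fully
enumerated cluster, the medoid). Representative tightness — the mean
superposed RMSD between a representative and the other members over a
caller-chosen atom selection — is reported alongside, since metric-space
centrality does not by itself certify structural homogeneity.

## State classification

States are anchored to two endpoint reference structures: the
outward-open endpoint defines the open reference for the N-gate and the
closed reference for the C-gate; the inward-open endpoint the reverse. A
gate counts as closed when its coordination number is within a margin of
the closed reference (or beyond), open when within the margin of the open
reference. N open with C closed is outward-open, N closed with C open is
inward-open, both closed occluded, anything else (including overlapping
margins) intermediate. The default margin is 0.3 of the reference span
per gate. A 10%-of-span margin would be usable only if the mid-path
models held ≥ 90% of the closed-reference coordination on both gates
simultaneously; no smooth one-parameter path between the two endpoint
structures can do that (see the generator section), so the wider default
was chosen and is recorded in each label's rule record.

## Rigid-body rotation analysis

The bundle rotation between two states is a fixed-selection analysis, not
an automatic domain decomposition: state B is superposed onto state A on
a caller-chosen fixed selection (Kabsch least squares; the residual is
reported), then the rigid transform best mapping B's mobile selection
onto A's is fitted and decomposed into the rotation angle
(arccos((trace−1)/2), argument clamped to [−1, 1]), the rotation axis
(from the skew part, or the symmetric eigenvector at 0°/180°), and the
screw translation along the axis. The residual of the second fit says how
rigid the motion really was. The hinge report lists per-residue Cα
displacements after the fixed alignment and flags the window with the
steepest mean absolute displacement gradient along the sequence as the
candidate hinge/bending region, ties to the earliest window; identical
states flag nothing. This detector localizes the static-to-mobile
transition; when a rotation axis passes through the interior of the
mobile bundle, the displacement minimum at the axis is not what it flags.

## Interaction typing and pose analysis

Ligand chemistry is declared (donors, acceptors, signed charged groups,
planar rings, apolar carbons) rather than perceived from connectivity;
protein chemistry comes from a built-in standard-residue dictionary, with
backbone N (except proline) as donor and carbonyl O as acceptor, and an
optional protonated-histidine flag that adds an imidazolium positive
charge. Default geometric criteria: hydrogen bond, donor–acceptor heavy
distance ≤ 3.5 Å (≤ 3.6 Å with a D–H…A angle ≥ 100° when hydrogens are
present — the angle is recorded only in that mode); ionic,
opposite-charge group-centroid distance ≤ 5.5 Å; π-parallel, ring-centroid
distance ≤ 5.5 Å with interplanar angle ≤ 30° and lateral offset ≤ 2.0 Å;
π-perpendicular, centroid distance ≤ 6.0 Å with angle 60–90°; hydrophobic,
apolar C…C ≤ 4.0 Å collapsed to one record (closest pair) per residue.
All cutoffs are config-overridable; every emitted record carries the
distances/angles it was accepted on.

A pose's fingerprint is the canonical set of (interaction kind, protein
residue) tokens. The modal fingerprint of a pose set is the most frequent
one (ties: more tokens, then lexicographic), and the convergence fraction
counts poses whose fingerprint contains the modal one.

Pose clustering follows the "without fitting" convention: the pairwise
distance is the unaligned RMSD over the ligand's non-hydrogen atoms plus
the binding-site atoms, agglomerated with average linkage. The Kelley
penalty at each level is the average of the mean within-cluster pairwise
distance over multi-member clusters, normalized across levels to
[1, n−1], plus the cluster count k; the reported k minimizes the penalty,
ties to the smallest k. When every level's spread is (near-)equal — e.g.
duplicated poses — the normalization collapses, the penalty reduces to
1 + k, the tie rule yields k = 2, and the result is flagged degenerate.
The criterion locates the knee where merging distinct groups would
inflate the spread; for data whose true group count is 2 it therefore
relies on the k = 2 level having near-zero spread, which is why the
ground-truth recovery tests use tight (duplicated) groups.

## Structure I/O and surface areas

PDB (multi-model) and mmCIF are read through gemmi into a flat atom
record list; residue numbers are author numbering, insertion codes are
rejected, altloc groups collapse to the highest-occupancy conformer
(ties: first in file), and repeated atom names without altloc codes are
duplicate-atom errors. PDB output is hand-formatted fixed-width text, so
identical inputs give byte-identical files. Buried interface area between
two chains is (SASA_A + SASA_B − SASA_AB)/2 by Shrake–Rupley sampling on
a deterministic Fibonacci sphere lattice (default 960 points, no RNG),
Bondi van der Waals radii keyed by element (unknown elements are errors),
probe 1.4 Å; all-heavy-atom and Cα-only modes are exposed, heavy-atom
default.

## The synthetic rocker-switch generator

The generator emulates the data regime of a large predicted-structure
ensemble of a two-protomer transporter with known ground truth. The
template is an idealized heterodimer: chains A and B, three straight
α-helical backbones each (N, CA, C, O per residue on co-axial helices
with fixed radius/phase/rise offsets; 1.5 Å rise, 100° twist per
residue), arranged around a pseudo-twofold axis along the
membrane normal, with residue numbering matching the MPC1L/MPC2 gate
definitions. The H2–H3 bundle of each chain rotates rigidly about an
axis through a designated hinge residue's Cα, perpendicular to the
membrane normal, by 16.5° (chain A) and 19.0° (chain B) between the
outward-open (t = 0) and inward-open (t = 1) endpoints. Backbone-only
models keep the generator honest and fast: the coordination metric needs
only non-hydrogen atoms, and each gate residue contributes four.

Two design points matter for what the tests do and do not show:

- **Phase-staggered schedules.** The chain-A rotation (long lever arms to
  the N-gate band, hinge adjacent to the C-gate band) completes early in
  t, and the chain-B rotation (the mirror arrangement) late:
  f_A(t) = 0.95·(1−(1−t)^γ) + 0.05·t and f_B(t) = 0.95·t^γ + 0.05·t with
  γ = 7 by default. A synchronized linear schedule would make the
  mid-path model half-open on both gates — a channel, which an
  alternating-access transporter never forms; the staggered schedule
  produces a genuinely occluded intermediate (both gates ≥ ~75% of their
  closed-reference coordination at t = 0.5) while every pair distance
  remains strictly monotone in t, so C_N strictly rises and C_C strictly
  falls along the path. γ = 1 recovers the synchronized linear motion.
- **Protomer stagger.** Chain B is offset 2.6 Å along y so that closing
  gates saturate against a ~2.6 Å closest-approach floor instead of
  interpenetrating without bound; this caps the closed-state contact
  count and keeps the landscape arc shaped like a rocker switch.

The occluded plateau necessarily flattens C_N near the closed end, which
trades against rank correlation under coordinate noise: Spearman
ρ(t, C_N) at n = 500 is ≥ 0.99 for σ = 0.1 Å, ≈ 0.97 at the default
σ = 0.2 Å, and ≈ 0.95 at σ = 0.3 Å. Cluster representatives average this
noise away, so the pipeline-level rank correlation between representative
C_N and ground-truth progress is ≈ 1.0 at the default conditions.

Pseudo-quality scores default to clip(1 − |N(0, 0.15)|, 0, 1),
independent of t so filtering is unbiased; a biased mode penalizes
mid-path models to exercise filter/landscape interplay. Progress values
draw from uniform (default), two-mode Beta mixtures, or Beta(a, b); the
real density of predicted models across a landscape is unknown, so this
is a knob, not a claim. One seeded RNG drives everything; identical
parameters and seed give byte-identical PDB output.

Pose sets place a pyruvate-like ligand in a hand-built binding-site
scaffold (K49-, N100-, L96-, Y64- and F68-analog residues). Modal poses
satisfy a designated fingerprint — ionic + hydrogen bond to the lysine
analog, hydrogen bond to the asparagine-analog amide, hydrophobic contact
to the leucine analog — with margin-safe jitter (σ = 0.05 Å against
≥ 0.4 Å cutoff margins); the remainder are displaced until the ionic
contact is broken by ≥ 0.5 Å beyond its cutoff, so interaction typing
recovers the labels exactly and an n-pose set at modal fraction f
converges at exactly round(n·f)/n.

What the synthetic data does **not** emulate: side chains and packing,
membrane environment, sterics (closed gates approach closer than van der
Waals contact would allow), predicted-model confidence fields, and any
realistic density of models along the path. Passing tests certify the
pipeline's arithmetic and its recovery of known ground truth, not
biological conclusions about any particular transporter.

## Problem sizes

The test suite and acceptance script run ensembles of up to 2000 models
(~650 atoms each), 500-model correlation checks, 80-pose docking sets and
10,000-score filter checks; these sizes give stable statistics for every
quantity measured while keeping a full run in the low minutes on one CPU.

## Known limitations

- Insertion codes and multi-character chain ids beyond PDB conventions
  are rejected rather than handled.
- Interaction typing has no water-mediated contacts, no metal
  coordination, and no pKa/partial-charge model; histidine protonation is
  a global flag, not per-residue.
- The hinge detector assumes a single contiguous bending region per
  comparison.
- Kelley-criterion group-count recovery for k = 2 depends on the
  degenerate-spread tie rule (see above).
- SASA uses a fixed element-keyed radius table; exotic elements must be
  added before use.
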