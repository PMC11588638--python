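# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Region annotation

The repertoire unit is the V domain, FR1→FR4, with any hinge sequence kept
as separate metadata.  Coordinates are 0-based half-open internally; AIRR
columns are converted from the 1-based closed convention on read and back on
write.

The built-in annotator is a deliberately simple anchor heuristic aimed at
well-formed VHHs: the first cysteine within the first 30 residues is taken
as IMGT 23 (FR1 then extends three residues further); the first tryptophan
6–14 residues past FR1, preferring a `W[x]RQ` context, is IMGT 41, which
pins FR2 as the 17 positions IMGT 39–55 with fixed offsets (so hallmark
positions 42/49/50/52 become addressable); the last `[WR]G.G` match near the
C terminus starts FR4 (IMGT 118; the scan is overlap-aware so a CDR3 ending
in `RG` cannot shadow the true motif); the last `YYC` context before FR4
locates the conserved cysteine IMGT 104, and FR3 is taken as the 39
positions ending there (no IMGT gaps assumed).  CDR3 is whatever lies
between 104 and 118.  Sequences where an anchor fails are dropped with a
logged reason, mirroring repertoire QC, not raised as pipeline errors.

This heuristic is not a general antibody numbering tool.  Annotation is
pluggable: AIRR input carries externally computed regions, and boundaries
can also be transferred from an annotated reference through a global
pairwise alignment.

## Germline assignment and hypermutation score

Queries are aligned to every germline with a glocal pairwise nucleotide
alignment (match +1, mismatch −1, gap open −4, extend −1); end gaps on the
germline side are free because the expressed sequence continues through
CDR3/FR4 past the end of a V gene.  The best hit is the highest-scoring
germline, ties broken by fewer mismatches and then lexicographic gene name.
Mismatches are counted over aligned columns only — insertions and deletions
are not mismatches — so the score

    mismatch_score = 100 × mismatches / alignment_length

is a per-100-bp substitution rate, the standard proxy for somatic
hypermutation load.  When only amino acids are available the same scoring
runs on residues; the resulting per-100-residue score is flagged
(`aa_based`) and is not comparable to the nucleotide score.

## Classification

Classical: F/Y at IMGT 42 AND E/Q at 49 AND R at 50, OR best germline on the
VHH whitelist.  The hallmark at position 52 is not tested (it is the most
variable of the four, and at least one VHH germline carries W there).  The
hallmark residues are read from the expressed sequence, not the germline.
Cysteines are counted over the full V region, FR1→FR4, hinge excluded.

Type assignment: classical (Y, 2 Cys) → `Y_C2`, (F, 2) → `F_C2`, (F, 4) →
`F_C4`, anything else → `UNASSIGNED` (3-cysteine sequences are the typical
case); non-classical by best-germline family, IGHV3 → `N_V3`, IGHV4 →
`N_V4`, IGHV1 or no hit → `UNASSIGNED` (IGHV1 non-classicals are a sub-0.2%
minority in alpaca repertoires).  These invariants are enforced on the
`TypeAssignment` type itself.

The whitelist and the 2B/2C hinge motifs are configuration, not code.  The
shipped whitelist is a placeholder with only publicly well-known alpaca VHH
gene names; the shipped hinge motifs are synthetic stand-ins used by the
generator.  Real analyses must substitute curated lists.

## Sequence features

* Net charge at pH 7.4 uses the fixed scheme D −1, E −1, R +1, K +1,
  H +0.1, all other residues 0, termini ignored.  This is intentionally not
  a Henderson–Hasselbalch evaluation; the two models coexist (the fixed
  scheme for region charges, Henderson–Hasselbalch only inside the pI
  solver).
* Hydropathy is the arithmetic mean of Kyte–Doolittle values (range −4.5 for
  Arg to +4.5 for Ile).
* pI solves charge(pH) = 0 by bisection on [0, 14] to 1e−4 pH units; the
  charge model sums Henderson–Hasselbalch terms for the termini and the
  D/E/C/Y/H/K/R side chains with a configurable pKa set (default
  `IPC_protein`; `EMBOSS` also shipped).  Every term is strictly decreasing
  in pH, so the root is unique.  Absolute pI values shift by a few tenths of
  a pH unit between pKa sets; the set used is recorded in the table
  metadata.
* The aggregate region `CDRs` is the concatenation CDR1+CDR2+CDR3; `VHH` is
  the full V region (hinge excluded).  Regions containing `X` yield missing
  values and are excluded from statistics — a conservative choice.

## Structure analyses

Parsing keeps the first MODEL, heavy atoms only, resolves altlocs to the
highest-occupancy conformer (ties prefer `A`), and discards HETATM and
waters.  Contacts use all heavy atoms with a strict `< 4 Å` criterion;
epitope = contacting antigen residues, paratope = contacting antibody
residues.  Complexes with epitopes under 8 residues are removed as likely
crystal-contact artifacts.  A paratope is `FR2_involving` iff at least one
paratope residue maps to FR2; paratope residues outside CDR1/2/3 and FR2
count as `other`.

Residue–residue distances use the unweighted heavy-atom centroid as the
residue's central coordinate (a Cα mode exists for sensitivity checks).  The
CDR3 conformation metric is the minimum centroid distance between the IMGT 42
residue and any CDR3 residue after trimming 2 residues from each CDR3 end;
the trimmed termini sit at the loop base and would otherwise dominate the
minimum regardless of conformation.  Values around 6 Å indicate a loop bent
down over FR2, values above roughly 12 Å an extended loop.

The FR2×CDR3 interaction map reports, per FR2 position (IMGT 39, 40, 42, 50,
55) and CDR3 position, the fraction of structures with any heavy-atom pair
under the cutoff.  Variable-length CDR3s are aligned at both termini using
IMGT-style labels (105… from the left, …117 from the right, insertion codes
at 111/112 for loops longer than 13); the exact middle-of-loop convention is
a package choice.

SASA uses a deterministic Shrake–Rupley integrator: a fixed golden-spiral
point sphere (default 960 points) per atom at radius r_vdW + probe (probe
1.4 Å, standard van der Waals radii shipped in code); a point is accessible
iff outside every other inflated atom.  Buried surface area is monomer SASA
minus in-complex SASA, reported for the antigen (epitope side) and the
antibody (paratope side), clipped at 0.  Accuracy: an isolated sphere is
integrated to ≲0.2%; for packed atoms the discretization leaves on the order
of 0.3% variation of total area under rotation and up to ~1 Å² per residue
at 960 points (quartering with 3840 points halves it).  Absolute SASA/BSA
values are therefore integrator-dependent at the percent level and should be
compared within one integrator only.

## Statistics

Two-group comparisons use the two-tailed Mann–Whitney U test: for pooled
sizes ≤ 20 the null distribution is enumerated exactly over all group
assignments of the pooled observations (rank sums are precomputed, so ties
are handled natively); larger samples use the tie-corrected normal
approximation with continuity correction.  Correlations are Pearson r with
the t-based two-sided test; per-animal aggregates are compared with a paired
t test (all-zero differences → t = 0, P = 1; constant nonzero differences →
infinite t, P = 0).  Stars: `ns` P > 0.05, `*` 0.01 ≤ P ≤ 0.05, `**`
0.001 ≤ P < 0.01, `***` 0.0001 ≤ P < 0.001, `****` P < 0.0001 — a total
function; the boundary values 0.05/0.01/0.001/0.0001 are assigned to the
weaker annotation.  No multiple-testing correction is applied; tables carry
raw P-values (noted in the report footer).  Standard errors are sample
SD/√n.  Type order in all tables is Y_C2, F_C2, F_C4, N_V3, N_V4.

In the hinge-usage and top-3-FR2 tables, per-animal percentages sum to 100
by construction and position ties are broken toward the lower IMGT position.

## Synthetic data

The generator exists so that every pipeline stage is testable against known
ground truth without external downloads.  It emulates:

* five types in configurable proportions (defaults: Y_C2 0.331, F_C2 0.227,
  F_C4 0.240, N_V3 0.055, N_V4 0.034, UNASSIGNED 0.113 — the composition of
  a real adult alpaca repertoire);
* type-specific CDR3 length laws (shifted Poisson, means ordered
  Y_C2 12.3 < N_V3 ≈ N_V4 14.0 < F_C2 16.0 < F_C4 18.8) and CDR3
  composition biases (acidic CDR3s for F_C4, basic for non-classicals);
* uniform per-base somatic hypermutation at a configurable rate (default
  0.03), FR4 W→R replacement (rates 0.027 classical / 0.112 non-classical,
  codon mix CGG 0.689 / AGG 0.255 / CGT 0.056), a 2B/2C hinge mix
  (0.56/0.44), geometric read counts (p = 0.15, so roughly half the records
  survive the count ≥ 5 filter) and 22 animals across three age groups.

Scaffold "germlines" are invented sequences with IMGT-style names — one per
type, classical scaffolds whitelisted — not real IMGT entries.  So that
ground-truth labels remain well defined under mutation, hypermutation never
touches the label-defining and anchor codons (IMGT 23, 41, 42, 49, 50, 52,
the 102–104 YYC block, any planted cysteine, FR4 start) and never creates a
cysteine, tryptophan, stop codon, or a tyrosine within two residues upstream
of a cysteine.  The per-record mutation count is drawn Binomial(L, rate)
over the full germline-covered span and then placed on eligible positions,
so the expected mismatch score is exactly 100 × rate even though some codons
are protected.  CDR3 and FR4 are never mutated (they are not covered by the
germline alignment, so mutations there would not register in the score).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: SHM hot/cold spots and indels, IMGT insertions/
deletions in framework regions, allelic germline variation, clonal lineage
structure, sequencing error, and any correlation between type and animal.
The annotator's 100% boundary recovery on synthetic records reflects that
generated sequences respect the anchor architecture by construction; real
repertoires contain sequences that violate it and are dropped by QC.

Toy complexes are two-chain structures with one pseudo-atom (carbon radius)
per residue: a 15-residue antibody scaffold on a line at 8 Å spacing with a
5-residue FR2 (IMGT 39/40/42/50/55), a CDR3 pseudo-loop hanging below the
42 residue at 6 Å spacing realizing a requested extended (14 Å) or bent
(6 Å) minimum-distance regime, and antigen residues offset perpendicular to
the antibody plane.  Planted pairs sit at their requested distances
(3.2–3.9 Å); every other cross-chain pair exceeds 6 Å, verified at
generation time.  Single-atom residues make SASA closed forms available for
testing.  The labeled complex-set generator mirrors the qualitative
per-type trends (Y_C2/N_V3 more FR2-involving, Y_C2 extended vs F_C2/F_C4
bent CDR3, no N_V4, epitopes topped up to pass the ≥ 8 filter); it makes no
claim of geometric realism.

## Problem sizes

Default analysis sizes: repertoire simulation and typing at n = 2000
(pipeline default; the typing-recovery property is exercised at n = 5000),
SHM-score recovery at n = 2000, 40–60 toy complexes per structure set, SASA
at 960 points for accuracy-sensitive checks and 240 points inside bulk
per-complex summaries.

## Known limitations

* The anchor annotator assumes gap-free IMGT architecture in FR2/FR3 and
  fails (by design, with a named anchor) on sequences that deviate.
* Only PDB input is supported for structures (no mmCIF).
* pI values are model pI, not measured; comparable only within one pKa set.
* BSA is integrator-dependent at the percent level (see above).
* The Mann–Whitney exact path enumerates C(n, n_a) assignments and is
  intended for pooled sizes ≤ 20.
* The shipped whitelist and hinge motifs are placeholders; real analyses
  must supply curated configuration.
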