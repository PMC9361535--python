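# Methods

This note documents the models behind each analysis stage, the tunable
parameters and their defaults, the numerical choices made where the
procedure was genuinely open, what the synthetic generators do and do not
emulate, and the known limitations.

## 1. Structure-based mutation triage

### Structure model

PDB text is parsed with Bio.PDB into a flat array-backed model: heavy
atoms only, waters and non-protein heteroatoms dropped, one alternate
location per atom (highest occupancy; ties resolve to the first-listed,
i.e. lexicographically first, altloc).  Residues are keyed by
`(chain, number, insertion code)`; mutation positions use protein
numbering on the first (or configured) chain, with the menin default
protein length of 610 residues as the validity range.

### Rotamer instability criterion

For a candidate mutant residue type, every rotamer of the library is
rebuilt on the fixed backbone and tested for steric clash; the stability
call is: 0 % clashing rotamers → *stable*, 100 % → *unstable*, anything
between → *potentially stable*.

*Side-chain construction.* Internal coordinates (bond lengths, angles,
torsion offsets) are measured once per residue type from the ideal
Chemical Component Dictionary templates bundled with biotite and rebuilt
by natural-extension (NeRF) placement anchored on the target N/CA/C.
Reconstruction of the templates themselves is exact to machine precision,
and χ angles re-measured from built coordinates match the requested values
within well under 1°.

*Rotamer library.* The default library is combinatorial over per-bond
candidate angles: sp3–sp3 bonds at the three staggered positions
(−60°, 60°, 180°), terminal planar groups at a per-chemistry set
(symmetric carboxylates/rings at {0°, 90°}, asymmetric amides/imidazole/
indole at {−90°, 0°, 90°}, arginine's guanidinium bond at
{−90°, 90°, 180°}).  This gives e.g. 3 serine, 9 leucine and 81 lysine
rotamers.  It is deliberately a *coverage* library (does the structure
admit any conformation of this residue type?) rather than a
survey-frequency library; any mapping residue → χ-tuples can be passed in
its place.  Glycine and alanine have no χ angles; since the all-rotamers-
clash criterion cannot fire for them, their clash fraction is defined
as 0.  Proline is built at its ring template geometry as a single
conformer.

*Clash rule.* A rotamer clashes when any side-chain heavy atom lies closer
than `vdW_i + vdW_j − tolerance` to any atom of another residue, with
heavy-atom vdW radii (C 1.70 Å, N 1.55 Å, O 1.52 Å, S 1.80 Å) and a
default tolerance of 0.4 Å.  Hydrogens are ignored.  The mutated residue's
own atoms are excluded, as are the backbone C/O of the preceding and the
backbone N of the following residue: those sit in 1-3/1-4 covalent
geometry with CB and would register a spurious "clash" for every residue
in any chain.  Detection is verified in the tests against an exhaustive
all-pairs distance oracle.

### Polar-contact losses

Side-chain hydrogen bonds are called by distance only (donor–acceptor
heavy atoms ≤ 3.5 Å) with donor/acceptor typing from residue chemistry;
salt bridges pair opposite-charge side-chain group atoms at ≤ 4.0 Å.
Backbone N/O of the two bonded neighbour residues are excluded as
partners (near-covalent geometry).  A wild-type contact counts as *lost*
when the mutant residue type lacks the role (donor, acceptor, positive,
negative) the wild-type side chain played in it.  An angle criterion is
available in principle but off by default — the distance-only rule is
deliberately permissive and symmetric across residue types.

### Interfaces and surface exposure

Relative accessibility is Shrake–Rupley sphere-point SASA (196 points per
atom by default; deterministic, refinable) normalized by the Tien et al.
(2013) theoretical Gly-X-Gly maxima, capped at 1.2; "surface" means
relative SASA ≥ 0.2.  An interface zone is every menin residue with an
atom within the contact radius (default 5 Å) of any partner-chain atom in
a complex structure.  A mutation in a zone is *disrupting* when it is
surface-exposed, the wild type can hydrogen-bond, and the mutation removes
a polar/charge capability; it is a *possible gain* when it adds one.  No
energies are computed — the call is purely qualitative.

### Categories

Each mutation receives one label by precedence:
`unstable` (all rotamers clash) → `hbond_loss_unstable` (≥ 1 lost polar
contact) → `interface_altering` → `pathogenic_unknown` (position not
resolved in the monomer) → `no_predicted_effect`.  Counts are reported
both per input row and per unique `(wt, position, mutant)` change, since
mutation lists compiled from databases contain the same change observed in
multiple tumors.

## 2. AP-MS interactome quantification

### Preprocessing

Protein-group tables use the MaxQuant `proteinGroups.txt` dialect; zero
intensities are treated as missing.  Filtering removes flagged
contaminant/reverse/identified-by-site rows, groups with no unique
peptides, and groups with fewer than 2 peptides (applied across all
samples of the experiment).  LFQ intensities are log2-transformed and
missing values imputed per sample column from
`Normal(μ − 1.8 σ, (0.3 σ)²)` with μ, σ the column's observed mean and SD
— the standard downshifted-normal model for left-censored (MNAR)
pull-down data.  Observed values are left bit-identical; the imputation is
reproducible given the seed.

### Significance: moderated t with permutation FDR

Per protein, `d = (mean_pulldown − mean_control) / (se + s0)` where `se`
is the pooled (Student) two-sample standard error and `s0 = 2` damps
low-variance proteins.  The variance model is configurable but pooled by
default, matching the classic SAM construction.  Significance is a global
two-sided cutoff on |d|: all distinct group-label assignments are
enumerated when there are ≤ `n_perm` of them (20 for 3 vs 3), otherwise
`n_perm = 250` seeded random draws are used; the estimated FDR at a cutoff
is the *median* permuted positive count divided by the observed positive
count, and the smallest cutoff with estimated FDR ≤ target (default 0.01)
is chosen.  The raw two-tailed p reported alongside comes from the
unmoderated t statistic.  On fully null simulations the procedure calls
≈ 0.1 % of proteins, comfortably below the nominal budget.

### iBAQ stoichiometry and complex recovery

Per protein and pull-down replicate, the mean control iBAQ is subtracted
and negative values clamp to 0 (undetected background cannot contribute
negative molarity); stoichiometry is mean adjusted iBAQ over the bait's,
so the bait is exactly 1.  The dispersion reported is the SD of
replicate-wise ratios, not propagated error.  Mutant complex recovery is
the mean over complex members of mutant/WT stoichiometry, with members
absent from the mutant counted as 0; the default member sets are the
MLL1/MLL2 COMPASS-like subunits (DPY30, KMT2A, KMT2B, WDR5, ASH2L, RBBP5,
HCFC1, HCFC2, PSIP1) and the JunD/AP-1 set (JUND, ATF7, FOS).

## 3. Genome-occupancy analysis

### Spike-in normalization

With exogenous chromatin spiked at a constant ratio, the spike-per-target
read ratio measures inverse recovery.  The control track's factor is
`f = (spike_exp/target_exp) / (spike_ctrl/target_ctrl)`; equal ratios give
f = 1, and f is linear in the experiment's spike reads.  The direction of
the ratio is configurable (the convention is stated here rather than
inferred, since either orientation is dimensionally valid); the default
multiplies the *control* track so it becomes comparable to the experiment.

### Classification and motifs

Overlap is ≥ 1 bp intersection with the merged partner set — the common
default of interval-intersection tools.  The three booleans (MLL1, JunD,
H3K4me3) form codes 0–7; the default display grouping maps the six
MLL1⁺-or-JunD⁺ categories to clusters c1–c6 and reports the two
MLL1⁻/JunD⁻ categories separately, and is fully configurable.  Motif
annotation scans the two fixed consensus motifs on both strands (both are
their own reverse complement as patterns, so a forward scan suffices);
for disjoint pie-style proportions the precedence is ATF > AP-1 because
the ATF/CRE consensus embeds a half-site of the degenerate AP-1 pattern.

### Differential retention

Peak coverage is the sum of per-base normalized signal over the peak
(sum, not mean, is robust for narrow peaks).  With pseudocount 1, the
fold change is directional WT/mutant — the question is loss of binding —
and the p-value is a two-sided Poisson rate comparison of the rounded
normalized counts, computed exactly via the conditional binomial test
(given the total count, the WT share is Binomial(n, ½) under equal
rates).  A peak is *lost* only when FC > 4 **and** p < 0.001; everything
else is retained.  Retention is therefore monotone in both cutoffs, which
the tests check.  Equal sequencing depth between genotypes is the caller's
responsibility (subsample upstream when depths differ).

### Correlation and heatmaps

Tracks are re-binned to 10 kb (signal-weighted mean), bins with zero
signal in all tracks are dropped, and Pearson correlations computed;
constant tracks yield missing values, never 0.  Tornado matrices are
peak × bin means centered on peak midpoints, rows ordered by total signal.

## 4. Synthetic generators: what they emulate, and what they do not

The generators exist so that every stage can be verified against known
ground truth without any external download.

* **Structures** — ideal-geometry polypeptides (NeRF backbone at fixed
  φ/ψ, CCD template side chains).  Clash plants place a blocker atom in
  van-der-Waals overlap with the CB position, which every rotamer of every
  non-Gly type shares, so "all rotamers clash" holds by construction.
  H-bond plants orient a free Asp so its OD1 sits at 2.8 Å from a planted
  Ser OG; interface plants put a partner-chain alanine CB ~4 Å from a
  designated CA.  These toys have none of the packing density, loop
  irregularity or crystallographic noise of real structures, so passing
  tests demonstrate the *logic* (geometry, counting, precedence), not
  calibration of thresholds against real proteins.

* **Interactomes** — triplicate pull-down vs control tables with
  log-normal intensities, configurable replicate SD on the log2 scale
  (default 0.3), planted interactors enriched by a configurable Δlog2
  (default 6; the recovery benchmarks use 4), iBAQ proportional to
  stoichiometry × bait abundance with 10 % CV, logistic MNAR censoring of
  low intensities, and flagged contaminant/decoy rows.  Peptide-level
  effects (shared peptides, match-between-runs artifacts) are not
  modeled.  With 3 replicates and 10 % iBAQ noise the stoichiometry-ratio
  SD is ≈ 8 %, so individual estimates occasionally miss a true value by
  slightly more than 20 % — that is the sampling variance of the design,
  not an estimator defect.

* **Landscapes** — non-overlapping menin peaks realizing the configured
  8-category mixture exactly after rounding; partner peaks jittered over
  their menin peak; a uniform-ACGT genome *scrubbed* of accidental AP-1/
  ATF matches before motifs are injected, making motif truth exact up to
  rare insertion-boundary rematches (< 2 %); Poisson per-bin read counts
  over a piecewise-constant rate (background 0.05 reads/bp, +3 reads/bp in
  peaks); mutant tracks share the WT truth with designated lost peaks
  scaled to a residual fraction (default benchmarks: 30 % of the JunD-only
  cluster and up to 60 % of the MLL1/H3K4me3 cluster at 5 % residual);
  spike-in counts exact by construction.  Real fragment-length
  distributions, chromatin sequence composition, mappability and
  peak-caller behaviour are out of scope — peak files are inputs to the
  real pipeline, not something it produces.

Default problem sizes (300–10,000 peaks, 500-protein tables, 20-seed null
studies, ~20-residue toys) were chosen so the whole verification suite
runs in well under a minute while keeping sampling error far from the
assertion margins.

## 5. Known limitations

* The rotamer criterion depends on the library and the clash tolerance;
  counts on real structures shift with either.  Both are exposed as
  configuration, and cross-library calibration on the published mutation
  tables is left to users with those inputs.
* Hydrogen-bond calls are distance-only; no angular or energetic term.
* The triage cannot distinguish "disrupts the MLL1 complex" from
  "disrupts the MLL1–LEDGF complex only" — it reports per-complex
  interface flags and leaves the interpretation to the user.
* The permutation FDR uses a global |d| cutoff; asymmetric up/down cutoff
  pairs are not scanned.
* Resolved positions with no predicted effect are labelled
  `no_predicted_effect` even when the source annotation is pathogenic;
  only unresolved positions fall into `pathogenic_unknown`.
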