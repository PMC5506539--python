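# Methods

`coevonet` quantifies the relationship between residue coevolution and
evolutionary conservation in protein families. This note documents the
models and conventions the package implements, the synthetic data it is
validated on, and the numerical choices that matter.

## Covariation scoring

Four per-family scorers produce symmetric L×L matrices over alignment
columns; all are standardised to Z-scores per family (mean 0, population
SD 1 over the valid upper triangle) before pairs with Z ≥ 4 and sequence
separation |i−j| ≥ 6 are selected.

**MIp.** Plug-in mutual information in bits from (optionally
sequence-weighted) joint frequencies, computed pairwise-complete: sequences
with a gap or ambiguous residue at either column are dropped for that pair,
and pairs with fewer than 20 usable sequences (configurable) are masked.
The average-product correction MIp(i,j) = MI(i,j) − MI(i,·)MI(j,·)/⟨MI⟩
removes the rank-one background that shared entropy and phylogeny impose.
Gaps are excluded from the MI alphabet because treating them as a 21st
state inflates the shared-gap signal.

**McBASC.** For column i the similarity table S_i(k,l) = M(a_ki, a_li)
(McLachlan matrix by default; BLOSUM62 and identity selectable) is built
over all ordered sequence pairs; score(i,j) is the Pearson correlation of
S_i and S_j over entries where both columns carry standard residues for
both sequences. Fully conserved columns have zero variance and score 0 by
convention. Scores live in [−1, 1].

**Mean-field DCA.** A 21-state Potts model (20 residues + gap; unknowns
count as gaps) is inferred by inverting the pseudocount-regularised
connected-correlation matrix: reweighted frequencies (inverse cluster
size at 80% identity), pseudocount mixing f ← (1−λ)f + λ/q with λ = 0.5,
one state dropped per column, couplings e_ij = exp(−(C⁻¹)_ij). Direct
information is the KL divergence (bits) between the two-site direct model
— with single-site terms fixed by self-consistency to reproduce the
marginals — and the product of marginals.

**PSICOV-style.** Columns are one-hot encoded over the 20 standard
residues, sequence-reweighted, and the 20L×20L covariance is shrunk
toward its diagonal (base fraction 0.3, doubled until positive definite).
Zero-variance coordinates are dropped first — their precision rows are
exactly diagonal, so pair scores are unchanged while the problem shrinks.
A sparse precision matrix is estimated by graphical lasso and each column
pair scored by the L1 norm of its 20×20 block, then APC-corrected.

Two PSICOV numerical choices deserve comment. The solver is capped at 15
iterations (tol 5e-3): block L1 scores and their ranking stabilise within
a few iterations, long before the dual gap closes (validated against a
50-iteration run: score correlation > 0.9999999, identical top ranks, an
order of magnitude faster). The penalty default is 0.003 with shrinkage
0.3. Stronger penalties look safer but behave worse on both ends: they
thin the precision matrix until the score distribution is nearly all
zeros, so the few surviving entries standardise to arbitrarily large
Z-scores on signal-free alignments (a calibration failure of the Z ≥ 4
rule), and they suppress genuine couplings at moderate alignment depth.
The weaker penalty with heavier diagonal shrinkage keeps the null score
distribution dense and well-behaved and retains sensitivity; calibration
was verified on coupling-free alignments (false-positive fraction at
Z ≥ 4 below 10⁻³).

## Conservation index

Per-column conservation is a weighted sum-of-pairs score
raw(c) = Σ_{k<l} w_k w_l M(a_kc, a_lc) / Σ_{k<l} w_k w_l over sequence
pairs with standard residues at c, with BLOSUM62 by default and
independent-count weights (inverse cluster size at 80% identity,
normalised to sum 1). Columns with more than 50% gaps, or fewer than two
scoreable residues, are masked. Raw scores are z-normalised over unmasked
columns (population SD), giving the conservation index (CI): 0 is a
column of average conservation within its family, positive values are
more conserved. Family-level conservation is the mean CI over gapless
columns only — the conserved core — which is what lets family averages
differ from zero despite the per-family normalisation. The exact
independent-count estimator of the original AL2CO program is not
reproduced; inverse-cluster-size counting is the standard effective-count
scheme and numeric agreement with AL2CO output is not claimed.

## Structure context

One chain of one PDB model is read (highest-occupancy altloc, MSE as MET,
waters and other heteroatoms dropped). Alignment columns map to residues
through the ungapped representative row, globally aligned to the
structure sequence; aligned-identity below 95% is treated as a wrong
pairing. Pair distances default to the minimum heavy-atom distance (CA
and CB modes selectable); the contact filter keeps pairs at ≤ 10 Å
(inclusive). Null ("non-coevolved") pairs are drawn strictly below 10 Å
and strictly more than 6 positions apart, from anchors that touch no
significant pair, 10 independent draws.

Solvent accessibility is an in-repo Shrake–Rupley implementation:
deterministic golden-spiral sampling (960 points per atom), radii C 1.70,
N 1.55, O 1.52, S 1.80 Å (1.80 with a warning for unknown elements),
probe 1.4 Å; relative accessibility divides by Tien et al. theoretical
Gly-X-Gly maxima, and residues below 7% (strict) are buried. A single
isolated atom reproduces the closed-form sphere area to better than 1%.

Backbone hydrogen bonds use the Kabsch–Sander electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a bond
below −0.5; amide hydrogens are rebuilt on the bisector of C(i−1)→N and
CA→N (1.01 Å), and never for proline, chain starts, or across chain
breaks (N to preceding C further than 2 Å). Secondary structure is
three-class: helix from two consecutive i→i+4 turns, strand from the
parallel/antiparallel bridge patterns, coil otherwise; CA–CA gaps above
4.5 Å bound all patterns. Side-chain bonds use donor/acceptor heavy-atom
tables with a 3.5 Å cutoff. These replace the PSA/SSTRUC/HBOND programs
with documented formulas; only the 3-class/2-class labels feed the
analysis, so residual differences from those programs are immaterial
here.

## Connectivity statistics

A site's degree is its number of significant, spatially filtered
partners; sites with no partner do not enter site-level analyses.
Degrees are binned (left-closed integer bins starting at 1; widths 1 and
5 at site level, 40 at family level — scaled to 5 for the 24-family
synthetic cohort), and ordinary least squares is fit to the bin means,
unweighted by default (`by_n` optional). HCC/LCC splits at more than 3
connections. Environment contrasts classify pairs as both-accessible,
both-buried, or mixed (likewise for hydrogen bonding and helix/strand)
and report the HCC−LCC mean-CI difference per class, pooled across
families (per-family aggregation available).

The real-versus-null control uses **unbinned** site-level fits on both
sides: with the handful of pairs that survive Z ≥ 4 in a typical family,
degrees occupy two or three values, and a binned regression over two
occupied bins has R² = 1 identically for real and null alike — only the
scatter fit can discriminate. Binned null fits are still computed and
attached for completeness.

## Synthetic data

The generator produces what the analysis assumes: families with tunable
per-column conservation, sparse couplings between spatially close sites,
and a representative sequence matching an (idealised) structure.

*Geometry.* Each family's structure is a compact self-avoiding bead chain
(3.8 Å steps, radius ≈ 3.4·L^⅓) with a protein-like contact density;
couplings are planted on actual contacts (≤ 10 Å, |i−j| > 6). The
`plant_structure` optimiser solves the inverse problem for explicit
sparse pair sets (staged penalised least squares: exact bonds, planted
pairs at 4–9 Å, other pairs pushed beyond 12 Å); idealised helices,
strands and an antiparallel sheet serve the geometry tests.

*Sequences.* Alignments are Gibbs-sampled from a 20-state Potts model —
N independent chains, 150 sweeps, no phylogeny, matching the independence
assumption of all four scorers. Coupling-free models are sampled directly
from the single-site Boltzmann law. Fields put weight on one preferred
letter per column. Couplings are deviation-only, similarity-coherent
permutations: each non-consensus letter of one column is rewarded with
one non-consensus letter of the other (similar letters mapping to similar
letters, which is what a substitution-matrix method can see), and the
consensus states carry no coupling term. While a site sits at its
consensus the partner's marginals are untouched — couplings do not leak
conservation into coupled columns — but every excursion is a compensated,
detectable excursion, so the observable covariation scales with how often
the coupled sites are free to move. A mean-field compensation term
(log(1 + (e^s−1)/19) per edge, added to the consensus field) keeps a
column's conservation at the level its own field encodes regardless of
its coupling degree.

*Cohort.* 24 families, L = 60, N = 300 by default. Core field scale runs
0.5 → 2.2 across families while planted couplings run 20 → 6 (per-edge
strength 2.5 × U(0.9, 1.25)), encoding the family-level hypothesis
(variable families acquire more connections). A small minority of sites
(two per family, the highest-contact-degree core positions) are hubs:
they receive 95% of coupling endpoints and strong fields,
3.8·(0.55 + 0.30·scale) — hubs stiffen with their family's overall
conservation, so in conserved families even hubs are frozen and their
couplings are barely observable; this, at a fixed Z cutoff, is what
produces fewer detected connections in conserved families. The
mean-field compensation is applied to hubs only: non-hub partners absorb
the coupling pressure and drift toward variability, as coupling-rich
columns should. 25% of columns are variable flanks with 30% gaps
(representative kept gap-free); the gapless core therefore sits above
the family mean by an amount that tracks the family's conservation, as
in real curated alignments.

What the generator does **not** emulate: phylogenetic relatedness (all
chains are independent, so the reweighting machinery is exercised but not
stressed), indels beyond column-wise gap injection, real side-chain
packing (cohort structures are CA beads; backbone-dependent annotations
are validated on idealised backbones instead), and the broad length/depth
spread of real family collections. Passing the recovery tests therefore
shows the estimators and the statistical pipeline are correct and
calibrated on data satisfying their assumptions — not that real,
phylogenetically structured families will show effects of the same size.

## Benchmarks and problem sizes

The packaged benchmarks (`coevonet.benchmarks`) use: 20 coupling-free
replicates at L = 30, N = 500 for Z-cutoff calibration; 20 replicates
with 15 uniformly placed planted contacts (L = 30, N = 500) for ranked
recovery; and the default 24-family cohort for both trend recoveries and
the null control. These sizes keep a full run in minutes on one CPU while
leaving the per-check sampling error well below the effect sizes being
demonstrated. Hub-biased placement is a cohort-trend feature and is
disabled in the recovery benchmark.

## Degenerate inputs and conventions

Columns are 0-based internally, 1-based in every file written. Fully
conserved columns: McBASC 0 by convention, CI defined, MI 0. All scores
equal: Z-standardisation returns zeros with a no-variance flag and no
pair can be significant. Flat y in a regression: slope 0, R² 0. Ties in
ranked outputs break by descending Z then (i, j). Glycine has no CB; CB
distance mode falls back to CA. B-factors written as CI clamped to
[−9.99, 99.99]; unmapped residues 0.00.

## Known limitations

- Mean-field DCA and the capped graphical lasso are approximate inference
  schemes; their scores are useful for ranking and thresholding, not as
  calibrated coupling estimates.
- The per-family Z ≥ 4 rule is scale-free: it keeps roughly the strongest
  handful of pairs per family regardless of how many true couplings
  exist, which compresses differences in detected counts between
  coupling-rich and coupling-poor families.
- Exact numeric agreement with the original AL2CO / PSA / SSTRUC / HBOND
  / McBASC / DCA / PSICOV binaries is not claimed anywhere; conventions
  are documented here instead.
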