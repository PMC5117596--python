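# Methods

## Scope and data model

`holoquant` implements the post-search half of a spectral-counting
metaproteomics workflow for a two-taxon system: a host animal and its
bacterial symbionts measured together in whole-organism proteome runs.
Spectrum-to-peptide matching itself (the search engine) is out of scope;
the pipeline starts from PSM tables that carry, per spectrum, the matched
peptide, a score (higher = better) and a target/decoy label, and from the
protein database those matches were searched against.

## Target–decoy q-values

The decoy database is the target database with every sequence reversed
(ids prefixed `rev_`). At any score threshold the FDR among accepted PSMs
is estimated as D/max(1, T), with D and T the decoy and target counts at
or above the threshold; the estimator is the plain ratio, not the
(2D)/(T+D) variant — a deliberate, documented choice since the upstream
tooling this mirrors does not publish its internal formula. q-values are
the running minimum of the FDR from the worst score upward, so they are
monotone in score; tied scores are processed as one block that shares the
FDR computed through the block's end. The PSM filter keeps q ≤ 0.02.

At desk scale the *protein-level* FDR report behaves differently from a
full-size study: roughly 2% of accepted PSMs are decoys, and with only a
few hundred mirror decoy groups to absorb them nearly every decoy group
passes the group filters, so the reported protein FDR is high and the
> 3% flag fires on synthetic fixtures. This is a property of small
databases, not a defect of the estimator; with realistically sparse
databases (10^5–10^6 entries) the same report lands in the few-percent
range.

## Grouping, uniqueness, balancing

Pairwise identity is computed from a global Needleman–Wunsch alignment
(BLOSUM62, gap open 10 / extend 1) as identical aligned residues divided
by the length of the *shorter* sequence — the centroid-clustering
convention, under which a fragment contained in a longer protein is 100%
identical to it. `X` (ambiguous translation) never counts as identical.
Clustering is greedy: records sorted by length descending (ties by id)
either join the first seed at ≥ 90% identity, in seed founding order, or
found a new group; the seed is therefore always the longest member. A
unit-cost edit-distance bound (via edlib) is used only to skip alignments
that provably cannot reach the threshold; it never changes the result.

Peptide uniqueness is re-assessed at the group level by substring search
against all member sequences: a peptide is unique if every protein
containing it lies in one group. I and L are distinct residues in this
matching. Balancing runs per sample independently: each group first
receives its unique-peptide spectra U_g; each shared peptide's count is
then split among its sharing groups proportionally to U_g, with an equal
split when all sharing groups have U_g = 0 (the degenerate case has no
published convention; symmetry is the only defensible default). The
"proportion of unique evidence" is counted in spectra by default —
`weight_by="peptides"` switches to unique peptide species, the main
interpretive alternative. Per-sample totals are conserved to 1e-9
relative tolerance by construction, and the test suite asserts it on
randomized sharing structures.

## Filters

A retained group needs, after the q-value cut: ≥ 2 spectra, ≥ 2 distinct
peptides, ≥ 1 peptide unique to the group. The protein-level
distinct-peptide requirement is kept at 1 (so that short or fragmented
sequences can be identified at all) and the stricter two-peptide rule is
enforced at the group level; applying both at the group stage after
clustering retains the same set as applying them at separate stages,
since group evidence only aggregates member evidence.

## nSpC

SAF_i = SpC_i / L_i with L_i the seed (longest member) length by default;
`length_mode="mean"` uses the mean member length instead. nSpC divides by
the SAF total over a normalization universe: `all` (the holobiont —
used for host/symbiont fractions), `host` (reproduces the published
host-table convention in which host nSpC values sum to 10,000 per sample
on the per-10000 scale; symbiont rows are reported on the same scale
factor), or `per_taxon`. Samples with zero total SAF in the universe get
zeros and a warning rather than NaNs. Symbiont fractions are computed on
the holobiont universe with contaminant groups excluded from both
numerator and denominator.

## Condition comparison

The pooled-variance two-sample Student's t-test, two-tailed, applied to
the per-sample symbiont fraction (or any per-sample column): pooled
variance s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2), df = n₁+n₂−2. The
pooled form with two tails reproduces the published comparison of
symbiont nSpC content between fresh and starved animals (means
3050.30/1869.77, sds 421.88/122.47, n = 3/3 → p = 0.00963) exactly from
the summary statistics, which is what fixed both choices. Welch's form is
available behind `welch=True`. Computing from replicates and from their
summary statistics agrees to 1e-12. With zero pooled variance the test
degenerates: p = 1 for equal means, p = 0 with a warning otherwise.

## Synthetic holobiont generator

The generator emulates the statistical structure the analysis assumes,
with defaults set to the study design: two conditions, *fresh* at 29.5%
and *starved* at 18.7% symbiont share of spectra, three biological
replicates each, 50,000 spectra per sample, and multiplicative Gaussian
replicate noise (sd 0.03) on the symbiont fraction, clamped to [0, 1].
The database holds 120 host and 80 symbiont base proteins (uniform random
sequences, lengths uniform in 150–450 residues) plus 12 variant families
at 95% point-substitution identity, which must co-cluster at the 0.9
threshold. Protein abundance weights are log-normal within taxon
(log-sd 0.8); a spectrum draws its taxon from the sample's realized
symbiont fraction, a protein within taxon proportionally to
weight × length — longer proteins yield more spectra, which is exactly
the premise the NSAF length correction undoes — and then one of the
protein's fully-tryptic peptides (≤ 2 missed cleavages, ≥ 5 residues)
uniformly. Decoy matches are appended at 5% of all matches with reversed
peptides and scores Normal(μ_t − 2σ, σ) against targets' Normal(μ_t, σ),
which yields monotone q-values with a realistic overlap.

Ground truth records, per sample, the realized symbiont spectral fraction
and the abundance-level symbiont fraction (selection probability divided
by length, renormalized — the quantity nSpC estimates without bias under
this model). Everything is deterministic given `rng_seed`, with
independent substreams for the database and each sample.

What the generator does *not* emulate: peptide detectability and
ionization efficiency differences, shared peptides across taxa arising
from homology (shared peptides here arise only within variant families
and by rare chance), dynamic range of real abundance distributions,
technical-replicate structure, or any spectrum-level physics (m/z,
retention time). Passing recovery tests therefore demonstrates the
*arithmetic* of the pipeline — grouping, balancing, normalization,
inference — not robustness to instrument- or biology-driven biases.

## Residue screening

The screen aligns each query globally to an annotated reference
(BLOSUM62, gap open 10 / extend 1) and reads off the query residues at
annotated positions. Calls: *amidase* is "active" only if every
active-site position maps and matches its expected residue set, "inactive"
on any mapped mismatch (a single lost catalytic residue abolishes
activity), and "indeterminate" whenever an annotated position is unmapped
(deleted in the query) — unmapped dominates mismatch, since absence of
evidence is not a mutation call. The binding-groove call (DAP-type vs
other) works identically. A "free cysteine" requires C at the annotated
sulfide-binding position, at a query position not claimed by a
conserved-disulfide annotation. Annotated positions and expected residue
sets are user-supplied TSV data: published evidence for them lives in
figure alignments that are not machine-readable, so the package treats
them as inputs and ships only synthetic examples in its tests. Alignment
ties resolve to the aligner's first reported alignment, which is
deterministic for fixed inputs.

## ORF extraction

Six-frame, stop-to-stop (every maximal stop-free stretch), standard
genetic code, default minimum 40 residues — matching classic ORF-finder
behavior; an initiator-methionine mode is available behind
`require_start`. Codons containing N translate to X. Reverse-frame
coordinates are reported 1-based inclusive on the forward strand, so the
same ORF found on a sequence and on its reverse complement occupies the
same interval.

## Problem sizes and numerical choices

The validation suite runs the recovery analysis at the full design depth
(50,000 spectra/sample) across a 100-seed panel for power, and the
type-I-error calibration across a 1,000-seed panel at 4,000
spectra/sample — test size under the null does not depend on spectral
depth, so the smaller tables only reduce compute. Oracle-equivalence
checks compare the greedy clusterer against a brute-force assignment
oracle on 200 random instances of ≤ 20 sequences, and the q-value routine
against exhaustive threshold enumeration on 200 random PSM lists of ≤ 50
entries with forced score ties. Conservation and normalization identities
are asserted at 1e-9 relative tolerance; TSV round-trips write floats
with `%.17g` and parse with round-trip precision so fixtures reproduce
in-memory objects bit-exactly.

## Known limitations

- Grouping is greedy and order-dependent (by design, mirroring centroid
  clustering); it is not a globally optimal clustering.
- The protein-level FDR report is meaningful only for databases large
  enough that decoy PSMs scatter thinly (see above).
- Quantification is spectral-count based; intensity-based quantification
  and parsimony protein inference beyond the stated grouping are
  non-goals.
- The t-test carries the usual normality assumption; at n = 3 per
  condition it is a convention of the field rather than a robust choice,
  and the type-I calibration panel shows it holds at the generator's
  noise model.
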