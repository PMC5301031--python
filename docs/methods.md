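# Methods

## Scientific setting

Nodal T-cell lymphomas with a T follicular helper (TFH) phenotype —
angioimmunoblastic T-cell lymphoma (AITL) and its relatives — carry a
characteristic mutation spectrum: epigenetic regulators (*TET2*,
*DNMT3A*) mutated across blood lineages, and hotspot mutations (G17V
*RHOA*, *IDH2* R172) confined to the tumor T cells. Because the tumor
sits in a dense microenvironment of reactive B cells, bulk sequencing
cannot tell which cell population carries which mutation. The
analytical chain implemented here resolves that by (1) screening
targeted-sequencing pileups for somatic candidates, (2) re-measuring
each candidate by amplicon deep sequencing in laser-microdissected
PD1+ (tumor-enriched) and CD20+ (B-cell) compartments and classifying
it by its detection pattern, (3) assessing infiltrating-B-cell
clonality from subcloned IgH VDJ colony sequences, and (4) aggregating
per-case calls into subtype-stratified frequency tables.

## Variant screening (`clonarch.screen`)

A pileup site carries stranded alt/total read counts plus two input
annotations (coding effect; known-SNP membership) that stand in for
external annotation databases. The cascade retains a site iff, in
order:

1. VAF > 0.02 (strict);
2. alt reads ≥ 7 and total depth ≥ 11 — a literal strict reading of
   "more than 6 reads of more than 10";
3. ≥ 1 alt read on each strand (the minimal reading of "appears on
   both strands");
4. nonsynonymous;
5. not a known SNP;
6. VAF outside the inclusive germline window [0.45, 0.55]. With no
   matched normal, heterozygous-looking VAFs are presumed germline;
   the window applies only at discovery, never to amplicon validation.

Each removed site records the *first* failing rule, making the screen
auditable and a strict partition of its input. The cascade is
verified against an independent one-expression restatement of the six
rules on 10 000 random sites plus all boundary cases.

## Lineage assignment (`clonarch.compartments`)

Detection in a compartment requires depth ≥ `min_depth` (default 100;
below it the compartment is *indeterminate*, mirroring "not examined"
entries in real data), VAF ≥ `min_vaf` (0.02) and alt reads ≥
`min_alt` (5). The defaults are calibrated so that a 0.1% per-base
error at deep amplicon coverage essentially never triggers a
detection, while true VAFs of a few percent are detected reliably.
The (PD1+, CD20+) detection pair maps to multilineal / T-specific /
B-specific / undetected; whole-tumor measurements feed only the
enrichment ratio PD1+ VAF / whole-tumor VAF, flagged "enriched" at a
factor ≥ 1.5 (an interpretive default operationalizing "substantially
higher" — enrichment failure is reported, never used to change a
call). Gene-level aggregation marks a gene multilineal in a sample iff
at least one of its mutations is multilineal.

## IgH clonality (`clonarch.igh`)

Colonies are grouped by exact (V, D, J, junction amino-acid) identity;
a group of ≥ 2 of the ≥ 12 colonies is an expanded clone (2/12
identical colonies count as clonal expansion). A missing D assignment
is its own grouping value. Clonality: monoclonal when direct Sanger
sequencing was already clean (subcloning not applicable); otherwise
oligoclonal if any expanded clone exists, else polyclonal.

Germline identity is computed by global pairwise alignment
(Biopython's `PairwiseAligner`; match +1, mismatch −1, linear gap −2)
of the rearranged V segment against every reference, taking the
best-scoring pair; identity = 100 × matches / aligned columns, gap
columns included in the denominator (a conservative, documented
choice — IMGT's exact computation is not reproducible bit-exactly, so
the threshold behavior is additionally pinned on gap-free constructed
cases). Identity < 98.0% strictly means somatically hypermutated;
exactly 98.0% is unmutated.

The packaged germline V references are synthetic sequences (labelled
as such in the FASTA) so that no network download is needed; they
share nothing but length scale with real IGHV alleles, which is
irrelevant to every property tested (grouping, alignment arithmetic,
thresholding).

## Cohort summary (`clonarch.cohort`)

Frequency tables count mutated cases per gene, per subtype (AITL,
nodal PTCL with TFH phenotype, PTCL-NOS/TFH) and overall, optionally
restricted to the laser-microdissected subcohort. Percentages are
rounded **half-up** to one decimal (3/48 → 6.3; banker's rounding
would print 6.2) and rendered without a trailing ".0", matching how
such tables are conventionally printed. "Recurrent" means mutated in
≥ 2 cases outside the four established drivers.

`demo_cohort()` builds an 87-case matrix (48 AITL, 5 TFH, 34
PTCL-NOS/TFH; 19 microdissected) whose per-subtype gene counts equal
the published cohort's, both overall and in the LMD subcohort. The
published data identify counts, not a public per-case matrix, so the
gene-to-case layout is the package's own: established drivers fill
the first cases of each subgroup and the 13 novel recurrent genes
cycle through fixed windows sized so that their 34 mutation
occurrences spread over 24 distinct cases. Only the counts are
acceptance surface; the layout is arbitrary by construction.

## Synthetic cohort simulator (`clonarch.simulate`)

The generator *is* the study-condition model, not a tuning knob. Its
clone tree has three nodes: an ancestral clone carrying two *TET2*
mutations, one *DNMT3A* mutation and one synonymous passenger; a
T-lineage subclone adding G17V *RHOA* and *IDH2*; and an optional
B-lineage subclone adding *NOTCH1*. All somatic mutations are
heterozygous. Default per-compartment carrier fractions:

| clone      | whole_tumor | PD1pos | CD20pos |
|------------|------------:|-------:|--------:|
| ancestral  | 0.60        | 0.80   | 0.40    |
| T subclone | 0.35        | 0.75   | 0.00    |
| B subclone | 0.10        | 0.00   | 0.30    |

These respect the nesting invariants (child ≤ parent; disjoint
siblings sum ≤ parent per compartment) and encode what microdissection
does: PD1+ selection concentrates the tumor subclone, CD20+ selection
removes it and concentrates B cells. No quantitative purity was
published (PD1+ selection even failed in a few real cases), so purity
is a free parameter; the defaults place every carried mutation's
expected VAF ≥ 0.05, the regime in which the recovery properties are
stated. Expected VAF = carrier fraction × dosage (0.5 het, 1.0 hom).

Counts: total depth ~ Poisson(mean) (targeted default 200×, amplicon
default 2000×), alt reads ~ Binomial(depth, v′) with
v′ = v(1−e) + (1−v)e/3 (substitution errors hit the specific alt base
a third of the time; default e = 10⁻³), strands split binomially at
p = 0.5 separately for alt and reference reads so strand invariants
hold by construction. Heterozygous known-SNP sites (v = 0.5) and
error-only sites (v = 0) are emitted as screening controls.
Deliberately absent: overdispersion, indel errors, copy-number
change, read-level (FASTQ) simulation and alignment — so passing
tests demonstrate the logic of the chain under clean binomial
counting, not robustness to real library artifacts.

IgH simulation plants each requested clone as round(fraction × n)
colonies sharing one rearrangement, junction and hypermutated V
sequence; the background is colonies with guaranteed-distinct
junctions. V segments are substitution-mutated away from a germline
reference at rate (100 − target_identity)/100, every hit changing the
base, so realized alignment identity tracks the target (it can sit a
point or so above it when the aligner recovers matches through gaps
at high divergence).

## Numerical and design notes

- Determinism: every stochastic routine takes a seed or
  `numpy.random.Generator`; the pipeline derives per-case seeds from
  one master seed and writes a SHA-256 manifest, so identical
  config + seed gives identical files.
- Problem sizes in the test suite (e.g. ~1000 simulated mutations for
  recovery, 200 seeds for the IgH round trip, 10 000 sites for the
  screen oracle) are the sizes at which the stated properties are
  sharp while the whole suite stays interactive.
- Zero depth makes VAF undefined and raises; the screen never divides
  by zero because simulated depth is floored at 1 and real pileups
  with zero depth are rejected at parse time.
- Whether ">6 of >10 reads" means strict or non-strict inequalities is
  ambiguous in plain language; the strict reading (≥7 of ≥11) is
  adopted and the boundary is tested explicitly on both sides.
- The classification deliberately performs no statistical test of VAF
  differences between compartments and no phylogenetic reconstruction;
  the detection-pattern logic is the method.

## Known limitations

- Compartment purities, detection thresholds and the enrichment factor
  are simulator/interpretation parameters, not values calibrated to
  patient data.
- The synthetic germline V set means absolute identity values are not
  comparable to IMGT output; only the alignment arithmetic and the
  98% threshold logic carry over.
- `percent` half-up rounding matches printed tables; re-deriving
  percentages from text that itself contains arithmetic slips will
  disagree with those slips by design (the arithmetic wins).
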