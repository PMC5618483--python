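# Methods

This note documents the models, conventions and numerical choices behind
`snrkfam`, stage by stage, together with what the synthetic-data generator
does and does not emulate.

## Identification

Candidates are the translated annotated gene models; queries are the
labelled reference SnRK2 peptides of two reference species. We align
protein-vs-protein rather than protein-vs-six-frame-genome: the original
workflow immediately re-maps genomic hits onto annotated models, and
working from the models preserves the E-value threshold and
reciprocal-best-hit (RBH) logic at desk scale. Spliced-alignment
refinement of gene models is **not** implemented; gene models are trusted
as annotated. This is a deliberate simplification.

Local alignment is Smith–Waterman–Gotoh (optimal local score under
BLOSUM62 with affine gaps, a gap of length *k* costing `open + k·extend`;
defaults 11/1), executed by Biopython's C `PairwiseAligner` behind the
module surface; an unknown residue `X` scores 0 against everything.
Statistical significance uses Karlin–Altschul statistics with the
published gapped-BLOSUM62 constants λ = 0.267 nats, K = 0.041
(configurable): bit score S′ = (λS − ln K)/ln 2 and E = m·n·2^(−S′).
The screen uses a database-style search space (query length × summed
candidate lengths), the RBH step a pairwise one. The threshold E ≤ 10⁻⁵
is the study's screening cutoff.

RBH retains a candidate only if its best raw-score hit within **each**
reference proteome (family and non-family proteins together) is a labelled
SnRK2; ties break toward the lexicographically smallest reference id. The
original text does not say whether "both species" or "either species" was
required; "each" is the default and "any" is a switch
(`reciprocal_best_hit(..., mode=...)`).

Domain confirmation matches two PROSITE-syntax signatures (ATP-binding
region, Ser/Thr-kinase active site). The matcher supports literals, `x`,
`[...]`, `{...}`, `(n)`/`(n,m)` and the `<`/`>` anchors; ranged
repetitions are non-greedy, so the reported 1-based inclusive span is the
leftmost-shortest match. The wildcard and exclusion classes accept `X`;
inclusion classes do not.

## Gene structure

Coordinates are GFF3 1-based closed throughout; segment lists inside a
`GeneModel` are ordered in transcript orientation (5′→3′ of the mRNA).
Intron phase is the cumulative CDS length upstream of the intron, mod 3.
Introns that do not interrupt the CDS (entirely within a UTR) carry no
phase and are flagged non-coding rather than given a guessed value. A CDS
whose summed length is not divisible by 3 sets a validation flag on the
model instead of failing the parse; overlapping exons are a hard error.
One mRNA per gene is assumed; alternative isoforms are out of scope.

## Protein properties

Molecular weight sums average residue masses (Expasy table) plus one water
(18.0153 Da), reported in kDa to two decimals. The isoelectric point
solves Henderson–Hasselbalch net charge = 0 by bisection on pH ∈ [0, 14];
net charge is strictly decreasing in pH, so the root is unique. The pKa
set is the Bjellqvist/ProtParam one, including the residue-dependent
N-/C-terminal values — chosen because the study's printed values came from
ProtParam, and the cross-check tolerance (±0.1 pH) absorbs residual
differences. Because the terminal pKa depend on the end residues, pI is
invariant under reversal of the peptide's interior but not under full
reversal; the test suite checks the composition-invariance form. The
bisection iterates to 10⁻⁷ in pH so the residual charge at the returned pH
is far below 10⁻³.

GRAVY is the mean Kyte–Doolittle hydropathy; the aliphatic index follows
Ikai, AI = X(Ala) + 2.9·X(Val) + 3.9·(X(Ile)+X(Leu)) with X in mole
percent (the printed table omits AI values, so only the formula is
testable). The C-terminal classification computes Asp/Glu mole fractions
over the residues after a given domain end (default: the last 50 residues
when no domain end is supplied): E-rich if f(E) ≥ τ and f(E) > f(D),
D-rich symmetrically, else neither; τ defaults to 0.12, chosen so that the
family's documented group semantics (Group 1 Glu-rich, Groups 2–3
Asp-rich, Group 4 neither) are reproduced with margin while a typical
background fraction (~0.05 per residue) stays "neither".

## Promoter scanning

The promoter is the 2000-bp window on the gene's coding strand whose 3′
end abuts the transcription start site (+1); windows truncate at
chromosome edges with a warning, and a gene with zero upstream sequence is
an error. Display coordinates follow the PlantCARE convention: a hit at
1-based window index N is printed as −N bp. A minus-strand hit means the
forward window holds the pattern's reverse complement, and it is reported
at the leftmost forward-strand index of its span. This convention is the
only one consistent with the published placement table's internal
evidence: the nested ABRE triple of GmSnRK2.21 (CCTACGTGGC/−1349 contains
TACGTG/−1351 and ACGTGGC/−1352 at exactly those offsets) and the
mirrored CGTCA/TGACG rows at identical positions on opposite strands.

All overlapping and nested occurrences are reported (the published table
counts the GmSnRK2.21 nested triple as three ABREs). Palindromic patterns
(CACGTG) are deduplicated to a single forward-strand hit per site, since
the table counts such sites once. IUPAC ambiguity codes are allowed in
patterns; `N` in the window never matches. The catalog is data, not code:
the bundled TSV holds exactly the published element/pattern/function rows,
and users may load larger PlantCARE-style catalogs.

Known inconsistencies of the published table are recorded, not "fixed":
the GmSnRK2.9 CGTCA row lacking its mirrored TGACG row, the implied
forward CACGTG inside GmSnRK2.13's minus-strand ABRE, the implied
minus-strand TACGTG inside GmSnRK2.17's, and — found during
reconstruction — the GmSnRK2.7 TGA-element at −836(−) whose planted bases
conflict with the CGTCA/TGACG pair at −834. The generator's conflict
policy (`on_conflict`) defaults to raising; the bundled reconstruction
uses `skip`, which drops the later conflicting row and records it in the
truth table. Scanning a reconstructed promoter therefore reproduces every
planted placement exactly, with extra hits only of three kinds: mirror
pairs, nested catalog patterns inside planted bases, and palindrome
strand flips.

## Phylogeny

The multiple alignment is progressive: a UPGMA guide tree from pairwise
global-alignment identities (free end gaps), then profile–profile merges
by Needleman–Wunsch–Gotoh on column-frequency profiles (column score
f_Aᵀ·S·f_B with gap frequencies scoring 0; end gaps penalised; no
double-gap state transitions). This replaces the original MUSCLE step so
the pipeline has no binary dependency; the real-data mean-identity figure
is therefore aligner-dependent and not asserted.

Distances are p-distances with pairwise deletion of gap-containing
columns (the simplest model consistent with common protein-NJ defaults;
the distance model is configurable in principle via `DistanceMatrix`).
Neighbor joining follows Saitou–Nei with the Studier–Keppler criterion
Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k); ties break toward the
smallest (i,j) pair in the current working order; branch lengths use the
standard formulas, with negative lengths clamped to zero and flagged
(display convention of common tree software). On additive inputs the
tree's path metric reproduces the matrix to 10⁻⁹, verified against an
exhaustive least-squares oracle over all 105 six-taxon topologies.

Bootstrap supports resample alignment columns with replacement, rebuild
the NJ tree per replicate, and report the percentage of replicates
containing each original internal bipartition; rows are sorted by taxon id
before resampling so supports are invariant to input order. The study's
replicate count (B = 1000) is the default.

Group assignment anchors each non-reference leaf to the group of its
nearest reference leaf by patristic distance. A consistency flag marks
leaves whose smallest reference-containing clade (bipartition side of the
unrooted tree) holds references of a different group.

## Expression and qRT-PCR

FPKM = 10⁹·C/(N·L); Z-scores standardise each gene across samples with
the sample (ddof = 1) standard deviation, constant genes becoming all-zero
rows with a flag. ΔΔCt quantification pairs each replicate's target Ct
with the reference-gene Ct from the same sample (ΔCt), takes the
untreated control at the same time point as calibrator, and reports
FC = 2^(−ΔΔCt). Significance is a two-sided Student's t-test on the
replicate ΔCt values (equal-variance by default, Welch via a flag) —
applied to ΔCt rather than fold-change replicates, the standard practice
where the original text says only "Student's t-test". Amplification
efficiency is fixed at 100% and p-values are reported raw, without
multiple-testing correction, matching the per-gene star annotations of
the source workflow. Degenerate replicate sets (all values identical)
return p = 1 when the means agree and p = 0 otherwise. The induction rule
is boundary-inclusive exactly as printed: FC ≥ 2 and p ≤ 0.05 at one or
more time points, per treatment.

## Networks

Edges use the t transform t = r·√((n−2)/(1−r²)) on n−2 degrees of
freedom, two-sided. Boundary semantics follow the printed thresholds
literally: p ≤ 0.05 inclusive; r strictly > 0.5 / > 0.8 / < −0.5. Strong
positives are a subclass of positives. Pairs involving a constant profile
have undefined correlation and are skipped with a log message. Tissue
networks correlate FPKM profiles across samples; treatment networks
correlate per-gene fold-change series across time points (the same engine
with different profile extractors — which expression values fed the
original networks is unstated, so both extractors are exposed). No
multiple-testing correction, as in the source workflow. Note that the
treatment networks rest on n = 4 time points, where p ≤ 0.05 requires
|r| ≳ 0.95 and spurious edges at the nominal rate are expected; the
tissue networks (n = 28) are the statistically meaningful ones.

## The synthetic-data generator

Defaults mirror the study design: a 22-member family split 6/4/8/4 over
four groups; nine exons / eight introns per gene except one designated
shorter analog (the GmSnRK2.6 stand-in, 8 exons); 2-kb promoters; 28
tissues; three biological replicates; treatments NaCl / ABA / rac-GR24
sampled at 0/8/16/24 h.

Proteins are built on a 340-residue scaffold: the two signature instances
planted at residues 10–33 and 119–131 (N-terminal half, as in the real
family), a conserved core, and a 50-residue group tail (30% Glu for Group
1, 30% Asp for Groups 2–3, Asp/Glu-free background for Group 4). Sequences
descend through a two-level hierarchy (family ancestor → group ancestors →
genes/references) with per-site substitution rates 0.10/0.05 (0.08 for
references), signature windows protected. The reference panel mirrors the
study's: ten family peptides in one species spanning Groups 1–3 only, ten
in the other including the sole Group-4 anchor, plus two non-family
kinases per species so RBH has real discriminating work. Decoys are two
near-kinases (ancestor-derived, ATP signature intact, active site
destroyed — they survive screen and RBH and fail the domain check) and
three unrelated random proteins (they fail the screen; random 330-mers sit
tens of σ below the E ≤ 10⁻⁵ score threshold).

DNA is reverse-translated with uniformly random synonymous codons and cut
into exons realising a fixed, conserved phase pattern; introns are
GT…AG with sizes drawn from 78–600 bp (the study's real introns reach
4.6 kb; the range is shortened to keep the toy genome small, and the
lower bound is the study's own minimum). UTRs are 120/150 bp. Promoter
background is i.i.d. at configurable GC (default 0.35), resampled
position-wise until no catalog match touches a background base — a
guarantee of zero spurious hits, not a claim about real soybean promoter
composition (the original background model is unknown).

Expression counts are lognormal: genes in a block share a latent
standard-normal tissue profile mixed at √ρ (default target ρ = 0.9,
three blocks of four genes), exponentiated around a per-gene base level
and converted to integer counts through gene length and library size.
The correlation target applies on the log scale; the count-scale Pearson
correlation is attenuated slightly by the exponential transform (≈0.88
for a 0.9 target), which the tests account for. Ct tables put the
reference gene at Ct 20 and targets at gene-specific baselines of 24–27,
shifting treated samples by −log₂(FC); replicate noise is Gaussian with
σ = 0.2 cycles, a typical qPCR replicate scatter, at which the t-test
keeps its nominal size and the all-flat null yields an empty induced set
in ≫95% of simulations. The default true-effect table includes ~13- and
~18-fold salt inductions at 8 h, rising/falling hormone responses and an
SL-repressed gene, emulating the salient published responses.

What the generator does **not** emulate: sequencing reads (counts are
drawn directly), library-size biases beyond a scalar, codon-usage
realism, indels or domain rearrangements between family members,
paralogous gene pairs with correlated histories, and real promoter
composition. Passing the planted-truth tests therefore demonstrates that
the pipeline's logic is correct under the stated generative model — not
that it would meet the same accuracy on real genomes, where gene-model
quality and alignment ambiguity dominate.

## Problem sizes and tolerances used in the test suite

The suites run at desk scale by design: the default genome carries 27
gene models (~170 kb over five chromosomes); phylogeny is 42 taxa × ~360
columns; NJ exactness uses 200 random additive 6-taxon instances against
the exhaustive 105-topology least-squares oracle; scanner equivalence
uses 500 random 150-bp windows against a naive matcher; pI bisection is
checked against a 0.001-step grid scan within 0.002; correlation
p-values are checked against 10,000-draw resampling oracles (the
unconditional null simulation within 3 Monte-Carlo standard errors — the
t p-value's exact estimand — and the data-conditional permutation test
within a documented ~0.03 small-sample allowance at n = 8); and the null
calibrations of the induction rule and network edges use 1000 simulated
datasets each, requiring an empirical type-I fraction inside [0.04, 0.06]
at α = 0.05.

## Known limitations

* Gene models are trusted; there is no spliced-alignment refinement or ab
  initio prediction.
* Heuristic alignment seeding is absent — every comparison is an exact DP,
  which is fine at desk scale and slow at genome scale.
* The progressive aligner has no iterative refinement; deep alignments
  will be worse than MUSCLE/MAFFT, and identity-dependent figures shift
  accordingly.
* Distance-based phylogeny only; no ML/Bayesian inference, no duplication
  dating.
* Real-data figures that require the original accession or author data
  (per-protein MW/pI of the published loci, the 66.7% mean identity, the
  26-edge/16-node and 7-edge/10-node networks, printed fold changes) are
  outside what the synthetic testbed can verify; the suites verify the
  computational machinery instead.
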