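# Methods

This note records the models implemented in `genefam`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Family identification

Profile-HMM domain search is replaced by a deterministic two-signature
scan for the SBP-domain zinc fingers: Zn-1 = `C-x(2,4)-C-x(10,20)-
C-x(2,4)-H` followed, within a combined span of 60–90 residues
(bracketing the ~76-aa domain consensus), by Zn-2 = `C-x(2,4)-
C-x(10,20)-H-x(2,4)-C`. Matches are minimal (non-greedy) per start
position; each Zn-1 is paired with the earliest in-bounds Zn-2, and
overlapping candidate hits resolve to the leftmost. The spacing bounds
and span window are an operationalization of the two published
zinc-binding arrangements, not a calibrated profile; they are exposed in
`ScanConfig` and should be re-tuned for families whose finger spacings
differ. On the package's own fixtures the scan has 100% recall on
planted domains, and its empirical false-positive rate on random
background proteins is bounded in the test suite (≤5% per 150-aa random
protein); a profile HMM would do better on real proteomes and is the
natural upgrade path.

Deduplication collapses identical protein sequences and isoforms of one
source gene (longest isoform kept), then orders survivors by chromosome
and start coordinate and renames them `<prefix>1..N`, the convention
used for naming family members along chromosomes.

Protein statistics use Expasy-style average residue masses (MW = Σ
residue masses + one water) and a Bjellqvist-style pKa set (N-terminus
7.5, C-terminus 3.55; side chains D 4.05, E 4.45, C 9.0, Y 10.0,
H 5.98, K 10.0, R 12.0) with the pI solved by bisection on the
Henderson–Hasselbalch net charge over pH 0–14. The residue `X`
contributes 110 Da and no charge. Different published pKa tables shift
pI by a few tenths of a unit; the table is fixed so results are
reproducible, and the tests assert the defining property (net charge at
the reported pI is zero) rather than table-specific values.

## Ka/Ks (NG86) and dating

Codon alignments are built by globally aligning the two translations
(BLOSUM62, gap open −10, extend −0.5) and expanding protein gaps to
codon gaps, so gap runs always respect codon boundaries and removing
gaps recovers the inputs. Codon columns containing a gap, an ambiguous
base, or a stop codon in either sequence are excluded from counting
(complete deletion within the pair, the common practice of desktop
Ka/Ks tools). A terminal stop codon is stripped before alignment.

Sites follow the equal-weight mutation-opportunity definition: each of
the nine single-nucleotide mutants of a codon contributes 1/3 of a site,
synonymous or nonsynonymous by the standard genetic code, with mutations
to stop codons counted as nonsynonymous; s + n = 3 exactly per codon.
Differences are averaged over all k! mutational pathways between two
codons with equal weight; pathways whose intermediate states are stop
codons are excluded, and if every pathway is excluded all are kept.
Proportions are corrected with the Jukes–Cantor formula
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 raises a saturation error at the
pair level and marks the window undefined at the window level. Ks = 0
leaves the ratio undefined (flagged, not an error).

Selection classes: purifying (< 1), neutral (within 1e-3 of 1),
positive (> 1). The neutral band is deliberately narrow: published
duplication tables treat a ratio of 0.997 as purifying and only an
exact printed 1.000 as the neutral boundary case, so a wider band would
misclassify real table rows. In report tables the binary
"purifying" column is strictly `ratio < 1`.

Dating uses T = Ks/(2λ)·10⁻⁶ Mya with λ = 6.5×10⁻⁹ synonymous
substitutions per site per year, the standard grass-lineage clock;
λ is a parameter everywhere it appears. Report tables round Ka, Ks and
the ratio to 3 decimals and dates to 2, matching the print convention of
published tables.

Sliding windows are anchored on alignment coordinates: window size and
step must be divisible by 3 (defaults 150 bp / 9 bp), a length-L
alignment yields ⌊(L−W)/step⌋+1 windows starting at 1, 1+step, …, and
each window is scored by the same estimator restricted to its columns
(gaps occupy span but contribute no counts).

## Codon-pair simulator

The generator diverges two copies of a random ancestor (uniform sense
codons — no codon-usage bias is modeled) by placing substitution events
one at a time. Every non-stop single-nucleotide change of the current
sequences is a candidate; synonymous candidates carry weight 1 and
nonsynonymous candidates weight ω, so instantaneous rates stand in the
ratio 1 : ω per site. The expected event count is calibrated so
synonymous events per synonymous site equal the requested Ks. The
realized truth (event counts over the final pair's NG86 site counts) is
returned with the sequences, and the truth satisfies
syn + nonsyn events = total placed, exactly.

Two intentional properties of this design matter for interpretation.
First, because stop-creating mutations are never placed while the NG86
nonsynonymous site count includes them as opportunities, the realized
dN/dS sits a few percent below nominal ω (visible at ω = 1, where the
recovered mean ratio is ~0.92–0.95 rather than 1.00). Second, the
equal-weight pathway averaging of the estimator undercounts
nonsynonymous and overcounts synonymous differences once many codons
carry multiple hits; at Ka ≳ 0.6 the estimate is compressed toward 1.
Recovery checks are therefore run at moderate divergence — Ks ≈ 0.4 for
the ω = 0.3 recovery (mean over 100 pairs of 500 codons within ±0.08)
and Ks = 0.2 for the sign-recovery sweep over ω ∈ {0.2, 1, 2} — the
regime counting estimators are designed for. Likelihood codon models
would be needed beyond it.

## Phylogeny

The multiple alignment is progressive (guide-tree based, BLOSUM62,
affine gaps), delegated to biotite's aligner. Distances use pairwise
gap deletion (robust to ragged termini); the Poisson correction
d = −ln(1−p) is available and flags p → 1 as saturated (infinite), but
the pipeline default is the p-distance because deeply diverged family
members that share only the domain routinely saturate the correction.
Neighbor joining follows the Saitou–Nei Q-criterion with deterministic
tie-breaking (lowest index pair); negative branch lengths are clamped
to zero with the deficit moved to the sibling edge, preserving path
lengths. On additive matrices NJ provably recovers the generating tree;
the tests verify this up to n = 8 and cross-check against exhaustive
OLS minimum-evolution search at n = 6.

Bootstrap resamples alignment columns with replacement; the support of
each internal edge of the full-data tree is the percentage of replicate
trees containing the same bipartition, reproducible bit-exactly given
the seed. Subfamilies are the maximal clades (≥2 leaves) whose
subtending edge support exceeds the threshold (default 50), found by
DFS from the tree's top-level trifurcation; remaining leaves are
"ungrouped". Midpoint rooting is provided for display only. Note that
well-supported *super*-clades absorb their sub-clades by construction:
with six clades radiating from a common ancestor the six groups are
recovered, but any supported structure between clades takes precedence,
as it should.

## Synteny and duplication

Anchors are unordered gene pairs whose global protein alignment score,
normalized by the smaller self-score, reaches a cutoff (default 0.5).
The normalized score stands in for a BLAST E-value cutoff: it is a
database-size-free significance proxy that is 1 for identical proteins
and ≈0 for unrelated ones, and the empirical null (shuffled fixtures)
produces no anchors at the default. Chaining works in gene-rank
coordinates (ordinal position along the chromosome), the MCScan
convention, with a longest-chain DP per chromosome pair and orientation:
ranks strictly monotone on both chromosomes (increasing, or decreasing
on the second for inverted blocks), consecutive rank gaps ≤ 25, chains
of ≥ 5 anchors kept, anchors assigned to at most one block, and the DP
verified against exhaustive search on small instances. min_anchors = 5
and max_gap = 25 are MCScan-family defaults; the tandem criterion
(same chromosome, ≤ 10 intervening gene ranks, not in a block) is the
common convention — none of the three is dictated by the analysis being
reproduced, and all are config-exposed.

Classification is a partition: segmental (pair inside a block), tandem,
dispersed. The summary percentage is
100 × |distinct genes in segmental pairs| / |family|, one decimal —
e.g. 24 genes of a 31-member family → 77.4%.

## miRNA target scanning

Scanning is ungapped (published target alignments for this miRNA family
are gapless; target bulges would add unconstrained parameters). Each
transcript window of miRNA length is scored positionally against the
miRNA's reverse complement: Watson–Crick 0, G:U wobble 0.5, mismatch 1,
doubled within the seed (miRNA positions 2–13 from the 5′ end), summed
into the expectation; defaults mirror the psRNATarget scheme and the
reporting cutoff is expectation ≤ 3. Overlapping sites resolve to the
best-scoring (ties leftmost); the region label (CDS vs 3′ UTR) comes
from the window midpoint. T and U are equivalent on the target side.
The three-line alignment rendering uses `|`/`o`/space, and recomputing
the expectation from the symbols reproduces the score.

## Expression

The atlas transform is entrywise log2(FPKM+1). Breadth classes use an
"expressed" threshold of FPKM ≥ 1 (a standard convention — the choice
is not dictated by the data and is a parameter): silent if no tissue
reaches it, constitutive if ≥90% of tissues do, restricted otherwise.
ΔΔCt follows Livak: per-replicate ΔCt = Ct_target − Ct_reference
(replicates paired within sample), calibrator baseline = mean calibrator
ΔCt, relative expression 2^(−ΔΔCt) with mean ± SE over replicates.
Technical replicates are combined at the ΔCt level, the standard
practice. The method is invariant to sample-wide Ct shifts, and a
noise-free simulated 4-fold induction is recovered exactly.

## Synthetic genomes: what they emulate and what they do not

`simulate_genomes` produces multi-chromosome gene orders with planted
collinear blocks (anchor pairs at monotone positions, either
orientation) and tandem arrays, recorded in truth tables. Planted
family genes carry the two-zinc-finger signature with randomized
spacers — so family members share the motif architecture but not
sequence, as in real domain families — and anchor/array partners are
near-identical copies (default 5 point substitutions). Background
genes are random CDS. Gene ranks, not base-pair positions, carry the
collinearity signal, matching the chaining model.

Passing the planted-recovery checks therefore shows that detection and
chaining are correct under the stated model; it does not show
robustness to the features real genomes add: gene loss inside blocks,
nested or overlapping duplications, transposed duplicates, tandem
arrays of diverged members, fractionated polyploidy remnants, or
annotation noise. Likewise the expression generator produces clean
class structure (constitutive / tissue-specific / silent with lognormal
noise) without batch effects or length biases, and the Ct generator has
ideal amplification efficiency. Fixture sizes in the tests (3
chromosomes × 24–30 genes, 100-codon genes, 20–200 bootstrap
replicates, 50–100 Monte-Carlo replicates) were chosen as the smallest
sizes at which every recovery statement is stable across seeds.

## Numerical choices

- Q-matrix ties in NJ break to the lowest taxon-index pair; chain-DP
  ties prefer the earliest anchor; overlapping scan hits and target
  sites resolve leftmost. All outputs are pure functions of inputs,
  parameters and seed; pipeline reruns are byte-identical.
- Saturation: JC correction raises at p ≥ 3/4; Poisson distances flag
  p → 1 as infinite and NJ refuses infinite inputs rather than
  guessing.
- Degenerate inputs: empty families, matrices with no shared columns,
  transcripts shorter than the miRNA, and CDS with internal stops are
  rejected with explicit errors (or skipped with a warning where the
  contract says so).
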