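# Methods

## Scope and model of the analysis

The package re-creates, on synthetic data with planted ground truth, a
four-part in-silico study of bifunctional CPD/(6-4) photolyases: (1) a
residue-conservation screen that separates true bifunctional homologs from
other cryptochrome/photolyase family (CPF) members, (2) parsimony analysis
of DNA-repair-activity evolution on the CPF clade tree under alternative
rootings, (3) feature annotation of a compact two-gene photolyase operon,
and (4) RT-qPCR relative expression of the operon genes under UV-B.

All coordinates anywhere in the package are 1-based inclusive on the
forward strand, with orientation carried by an explicit strand field
(GenBank convention).

## Residue-conservation screen

BLAST tabular hits pass when E-value < 10⁻³ **and** percent identity > 30,
both strict; filtering is idempotent and order-preserving. Partial
sequences are those covering < 0.7 of the reference by optimal global
alignment (the threshold is configurable; no canonical value exists).
Redundancy clustering is greedy and incremental in descending length order
at > 85% identity to a cluster representative — the scheme CD-HIT uses,
without its word-filter heuristics, so clusters are equivalent in spirit
but not guaranteed bit-identical to CD-HIT's.

Percent identity comes from one optimal global alignment (BLOSUM62, gap
open 10, extension 0.5) with the *aligned-columns* denominator (positions
where neither sequence is gapped) by default; shorter-sequence and
full-alignment-length denominators are available because published
identity figures rarely state their convention. The input pair is ordered
canonically before aligning so the function is exactly symmetric even when
co-optimal alignments disagree in identity count. Tests check the engine's
optimal score against an independent quadratic Gotoh dynamic program.

The rule screen maps the twelve PhrSph98-numbered functional positions
onto alignment columns via the reference row's gap structure and requires
the allowed residue at every column: electron transfer
Y389/W369/W390/F376/W381, FAD binding N412/D413, lesion binding
W314/A430/M388, lesion stabilization E310/N384. Two rules are residue
*classes* rather than single residues: F376 admits any aromatic (F/W/Y),
matching the substitutions observed inside homolog clades, and A430 admits
Trp, the replacement characteristic of class II CPD photolyases. A gap at
a ruled column fails the rule — a deleted catalytic residue cannot
function. A sequence is a true homolog iff all twelve rules pass, which
makes the classification monotone: adding rules can only shrink the
homolog set.

Logo information content per column is R = log₂20 − H with H the Shannon
entropy of residue frequencies, gaps excluded; the approximate small-sample
correction e(n) = 19/(2·ln2·n) can be subtracted (clipped at 0). The
BMGE-like trimmer instead counts the gap as a 21st symbol for its entropy,
matching each tool's intent: a logo describes residues present, a trimmer
judges column reliability. Columns survive trimming iff gap fraction ≤ 0.2
and entropy ≤ threshold; the trimmed 259-column length of the original
curated alignment is tool-heuristic-dependent and is not reproduced.

## Activity parsimony

Each collapsed CPF clade carries a state in {CPD, SIX4, DUAL, CRY_NONE},
decomposed into two binary traits (CPD repair, 6-4 repair). Minimum change
counts use Hartigan's generalization of Fitch parsimony, correct on
polytomies; tests verify it against exhaustive enumeration over internal
labelings. Ancestral states come from Hartigan most-parsimonious-
reconstruction (MPR) state sets resolved top-down, taking the parent's
state whenever it lies in the node's MPR set. The MPR sets matter: the
first-pass Fitch sets alone would force a single 6-4 gain onto the stem of
the prokaryotic clade followed by a loss in class II CPD photolyases,
whereas the equally parsimonious reconstruction the MPR sets expose places
independent gains on the FeS-BCP, eukaryotic 6-4 and bifunctional branches
— three independent origins of 6-4 repair, two of which (FeS-BCPs and
eukaryotic 6-4 photolyases) also lost CPD repair. The number of
*independent gains* of a trait is the number of branches carrying a 0→1
flip, each of which starts a maximal trait-bearing subtree. Per-trait flip
totals always equal the Fitch minimum (asserted by tests).

Because unordered parsimony scores are invariant under rerooting, "the
rooting with fewest changes" is only decidable under an asymmetric model.
Candidate rootings are scored by Sankoff parsimony with gain cost 2 and
loss cost 1 per trait — gaining a complex repair capability is the
expensive move (converting a 6-4 photolyase to CPD activity takes ~3
mutations, the reverse ~11). Two design points were genuinely open and are
resolved as follows:

- The derived 6-4 trait is anchored *absent* at an implicit origin above
  the root, so a rooting that places the root inside a 6-4 clade pays for
  the trait's own origin. Without this anchor such rootings always score
  lower by simply inheriting the trait, and with *both* traits anchored
  absent the comparison ties (a rooting at FeS-BCP can buy CPD repair with
  one stem gain instead of ancestral presence plus losses).
- The CPD trait's root state is left free, so CPD-ancestrality is an
  *inference*, not an assumption — and indeed the minimal (SPL) rooting
  reconstructs CPD repair as ancestral.

Under this model the SPL rooting scores 8 versus 9 for the FeS-BCP and
bifunctional rootings and is uniquely minimal. The conclusion is
model-dependent (costs 2:1 and the origin anchor are choices); the scoring
table is always emitted so other settings can be compared.

The collapsed clade topology is encoded from its textual description —
bifunctional sister to class II CPD photolyases, those sister to FeS-BCPs,
the three an all-prokaryote clade sister to the remaining CPF clades, SPL
outermost. The internal arrangement of the remaining clades is not fixed
by the description and is a configurable argument; the reported event
counts do not depend on it. A desk-scale distance pipeline (p-distance +
neighbor joining, exact on additive matrices) stands in for likelihood
tree inference, which is out of scope.

## Operon annotation

ORFs run start codon through in-frame stop, inclusive; the scanner reports,
per stop, the longest ORF (first start after the previous in-frame stop).
Start codons default to ATG with GTG/TTG available as options; stops are
TAA/TAG/TGA. Overlap records are produced for consecutive same-strand
features with negative intergenic distance and carry the junction
substring in gene orientation and a different-frames flag; an 11-nt
overlap necessarily changes frame (11 ≢ 0 mod 3). Shine-Dalgarno motifs
(AGGAGG/AGGAG/GGAG, longest preferred at equal position) are searched in
gene-strand space with spacer — nucleotides strictly between motif end and
start codon — in a 4..13 window, so intragenic SDs inside an upstream
overlapping gene are found naturally. Promoter box pairs are scored by
consensus match counts against TTGACA/TATAAT with 15–19 nt spacing; this
is plain consensus matching, not a trained promoter classifier — planted
box strings are sequence-level ground truth to re-find, and the default
acceptance threshold (8 of 12 positions) admits occasional random pairs,
which ranking by score tolerates. Transcription-factor sites (CRP
TCACAATT, IHF ACAGACAA) are matched on both strands with a mismatch
budget. Operon grouping chains same-strand genes with intergenic gap ≤ 50
nt, each strand independently, so an opposite-strand ORF lying between
co-directional genes does not break their operon. In-silico PCR counts the
amplicon from the forward primer's 5′ end to the reverse primer's 5′ end
inclusive — both primer footprints count, which is how gel-verified
product sizes are quoted.

## qPCR

Relative expression is 2^(−ΔCt), ΔCt = Ct_target − geometric mean of the
reference-gene Cts, references paired with targets by condition and
replicate. The geometric mean is taken on the Ct scale by default (the
source formulation); a linearized alternative (geometric mean of 2^(−Ct),
i.e. arithmetic mean on the Ct scale) is available via a flag. The
"add a constant to every Ct" invariance is exact under the linearized
convention and holds to within the tiny gmean-vs-mean discrepancy under
the Ct-scale convention. Fold change defaults to the ratio of mean
relative expressions (treated/control), with mean-of-ratios as the
alternative reducer; the two coincide at zero noise. Primer-efficiency
correction and significance testing are out of scope.

## Synthetic data generator

The generator's defaults are the study conditions. The protein family
mirrors the published screen size: 55 homologs and 94 decoys (149
screened) diverged from a 460-residue synthetic reference that carries the
twelve functional residues at their PhrSph98-numbered positions. The
reference is a package constant (fixed internal seed) and is a labelled
synthetic stand-in — only ruled positions and length matter to the
analyses. Divergence is i.i.d. per-site substitution (rate 0.05) outside
ruled positions; decoys additionally replace ≥ 1 ruled position with a
non-allowed, non-aromatic residue, mirroring the Thr/Leu replacements seen
in non-homolog clades. There is no indel model, rate variation or
phylogenetic correlation, so passing tests demonstrate correctness of the
rule screen, not robustness to realistic alignment error.

The operon generator lays out promoter (CRP and IHF sites, TTGAAG −35 and
TGCTATACA −10 boxes 14 nt apart), a 240-nt upstream gene ending in the
11-nt junction ATGTCAGTTGA (upstream TGA stop, downstream ATG start,
frames differing), the AGGAG SD motif ending 7 nt before that ATG, and a
231-nt downstream gene — desk-scale lengths standing in for the ~1.5-kb
real genes. Assembly is validated and re-drawn (seeded, deterministic)
until the plus-strand ORF scan recovers exactly the two planted genes and
the leading gene has no accidental SD hit; an in-frame stop is planted
immediately upstream of gene 1 so promoter-region starts cannot extend it.
Reverse-strand designs are exact coordinate mirrors. Random padding can
still contain chance ORFs on the opposite strand and chance promoter-like
box pairs; recovery is therefore asserted at planted coordinates rather
than by uniqueness.

Ct tables plant fold changes as Ct shifts of −log₂(fold) from per-gene
baselines, with optional Gaussian Ct noise; reference genes (PPC, RNPB)
are constrained to fold 1. The planted folds are the published inductions:
3.5 (PHR), 2 (bifunctional PHR-like), 3 (intergenic amplicon) at 15 min of
UV-B, back to 1 at 30 min; 3 replicates. At zero noise recovery is exact;
at noise 0.2 Ct the recovered fold is within 3 s.e.m. across replicated
simulations (the ratio-of-means estimator has O(Var/n) bias, negligible at
these settings).

Tree designs validate that the planted event count equals the Fitch
minimum on the planted topology before emitting.

All generators are byte-deterministic given a seed.

## Numerical and degenerate-input choices

Ties in greedy clustering order break by input position; promoter hits
sort by score then position; ambiguous ancestral states prefer the parent,
then the lexicographically first MPR state at the root. All-gap logo
columns are reported missing rather than 0. Trimming everything raises
(naming both thresholds) rather than returning an empty alignment. Empty
hit lists and empty record lists are empty outputs, not errors. Problem
sizes in tests and the acceptance script (149-sequence families, 630-nt
operons, ≤ 300-aa alignment oracles, 200-tree enumeration checks) were
chosen as the smallest sizes that exercise every code path at the study's
published proportions.

## Known limitations

- No BLAST/MAFFT/PhyML execution: the package consumes their standard
  output formats or uses its internal desk-scale substitutes.
- CD-HIT clusters and BMGE column counts are not reproduced exactly
  (heuristic-dependent); the 250→149 reduction of the original screen is
  therefore mirrored by construction in the synthetic family, not
  re-derived.
- The SPL-minimal rooting result depends on the asymmetric cost model and
  origin anchoring described above.
- Promoter scanning is consensus counting, not a statistical model of
  σ⁷⁰ promoters; terminator prediction and 3D structure analysis are out
  of scope.
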