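# Methods

`mitoplasmid` re-creates, as tested library code, a comparative-genomics
analysis of DNA exchange between fungal mitochondrial genomes and their
linear ("invertron") plasmids: structural plasmid detection in assembled
contigs, plasmid–mtDNA homology mapping, detection of tRNA-gene capture
by plasmids and of subsequent mitochondrial tRNA loss, parsimony
counting of independent transfer events on a plasmid phylogeny, and
codon-family usage ranking. This note records the models, parameter
choices, numerical conventions, and what the synthetic test bed does and
does not demonstrate.

## Structural plasmid detection

Invertron-like linear plasmids are 5–15 kb molecules encoding a DNA and
an RNA polymerase in inverted orientation, capped by terminal inverted
repeats (TIRs) with covalently bound terminal proteins. The screen
follows that definition operationally:

1. **Size window.** Only contigs of 5 000–15 000 nt are considered as
   whole-plasmid candidates (all known invertron plasmids fall in this
   range). Both bounds inclusive.
2. **ORF pair.** ORFs are called as maximal stop-to-stop stretches in
   all six frames under the mold mitochondrial genetic code (NCBI
   table 4, TGA = Trp); no initiator codon is required (a
   `require_start` flag exists but is off — size is the published
   criterion and start-codon usage in fungal mitochondria is
   ambiguous). The "1 kb+" ORF floor is read in nucleotides
   (`min_orf_nt = 1000`). The two longest non-overlapping qualifying
   ORFs decide the class: opposite strands → invertron (both divergent
   and convergent arrangements accepted and recorded); same strand with
   TIRs → non-invertron linear (the pCGr/pCC2-like architecture);
   anything else → no call. TIRs are *not* required for the invertron
   call itself; they feed the autonomy judgement.
3. **TIR search.** Seed-and-extend between the outermost 2 000 nt of
   each end and the reverse complement of the other end, exact 12-mer
   seeds, reporting the best pairing of length ≥ 20 nt at ≥ 0.8
   identity (known invertron TIRs range from tens to hundreds of nt; on
   random 10 kb sequence this null fires in < 1 % of seeds). Ties
   prefer the longer, then more leftward repeat.
4. **Polymerase verification.** Each ORF's translation is locally
   aligned (BLOSUM62, gap open 11 / extend 1 — classical protein-search
   costs) against a user-supplied panel of known plasmid polymerases.
   In strict mode a candidate whose ORFs both score below 100 is
   demoted; the library default is permissive so the screen runs
   without a curated panel. The analysis scripts enable strict mode
   whenever a panel is supplied: chance contigs carrying two ≥ 1 kb
   ORFs in inverted orientation do occur in large assemblies, and
   polymerase identity is what separates them from plasmids.
5. **Autonomy.** Sequence outside the TIRs (outside the ORF span when
   no TIR was found) is the evidence: flanks shorter than 100 nt on
   both sides → autonomous; a flank with a significant homology segment
   against any supplied mitochondrial genome → inserted (a recent,
   still-intact insertion); long flanks matching nothing → ambiguous.
6. **Rescue pass.** Contigs of any size are re-screened by nucleotide
   homology against known plasmids and accepted calls, to surface
   plasmids split across contigs. A fragment record requires ≥ 200 nt
   of significant homology *overlapping a polymerase ORF* of the
   reference — without that restriction, a mitochondrial contig sharing
   only a captured tRNA locus with a plasmid would be flagged. Fragment
   records are never full calls.

## Alignment engine and significance

Two engines sit behind `local_align`:

* **seed** — exact 11-mer word seeds (a megablast-like preset with word
  28 and +1/−2 scores is also provided) locate candidate diagonals; on
  each diagonal the optimal ungapped segment(s) are extracted exactly as
  best-scoring subarrays of the per-position +2/−3 profile. This is the
  scalable path and is exact for ungapped homology, which is the only
  kind the v1 generator plants.
* **dp** — full affine-gap Smith–Waterman (numba kernels). Linear-memory
  forward and reverse passes locate each optimal segment's end and
  start; a full-pointer pass over the bounding window recovers the
  path. Further segments come from masking previous ones and re-running.
  Automatic below 4×10⁶ cells (e.g. a tRNA against a contig), available
  on request far beyond that.

Segment non-overlap is enforced greedily by score, ties by leftmost
query start. Both query strands are always searched; minus-strand
segments are reported in forward coordinates with `strand = '-'`.

Raw scores convert to E-values as E = K·m·n·e^(−λS). λ solves the
Karlin–Altschul identity Σ pᵢpⱼe^(λsᵢⱼ) = 1 numerically (Brent plus a
Newton polish; residual ≤ 1e−9 enforced by test). K uses the classical
ungapped series on the score lattice,
C = exp(−2 Σₖ k⁻¹[E(e^{λSₖ}; Sₖ<0) + P(Sₖ ≥ 0)]), with
K = C·d / (A·(1−e^{−λd})), A the conjugate mean step. For +2/−3, +1/−2,
+1/−1 and +4/−5 the computed (λ, K) agree with NCBI BLAST's printed
ungapped constants to three decimals (frozen as test oracles). Gapped
alignments reuse the ungapped λ/K — the standard approximation; absolute
E-values for gapped chance hits are therefore mildly optimistic, which
is why significance decisions are only trusted on clear cases.

The analysis-wide significance rule is strict on both sides: a segment
counts only if its length **exceeds 50 bp** and its E-value is
**below 0.001**. Cumulative homology between a plasmid and an mtDNA is
the union length (overlaps merged) of surviving segments projected onto
plasmid coordinates, searched in both query directions with duplicates
merged.

## tRNA capture, loss, and dependency

A **capture** is a reference mitochondrial tRNA gene found on a plasmid
at ≥ 0.9 identity over ≥ 90 % of the gene (mutation count = mismatches
plus indel columns). A **loss** call searches the whole host assembly
(plasmid contigs excluded) with the significance filter plus a much
looser acceptance — ≥ 0.7 identity over ≥ 50 % of the gene — so that
"lost" is hard to claim: any plausible mitochondrial remnant counts as
present. The thresholds are deliberately asymmetric; both are this
package's choices, biased against the headline dependency claim. Note
that for a ~72 nt tRNA the > 50 bp significance rule is the binding
constraint on the loss search; it also suppresses short gapped chance
hits in unrelated contigs, which the E-value approximation alone would
occasionally admit. A capture whose host lost its mitochondrial copy is
classed `adopted_lost` (red in the report; the host now depends on the
plasmid for that anticodon), otherwise `retained` (blue); with no host
assembly the status is `unknown` and excluded from tallies.

The **flank profile** excises the captured gene ± 300 nt from the
plasmid and measures, against each comparison mtDNA, how far significant
homology extends beyond the gene boundaries. The donor lineage of the
capture shows extents near the full flank; other genomes match only the
(conserved) tRNA itself; a host that deleted the locus matches nothing.

## Transfer events on the plasmid tree

Each tRNA type's presence across plasmid leaves is mapped onto a rooted
(possibly multifurcating — polytomies are treated as hard) tree, and the
minimum number of independent origins is computed by unit-cost Sankoff
parsimony: gains (0→1) and losses (1→0) cost one each, and a root
reconstructed as "present" counts as one gain, so any non-empty pattern
has ≥ 1 origin. Among minimum-cost labelings the one with fewest gains
is reported (the DP minimises (cost, gains) lexicographically, which is
exact because total cost is minimised per child); ties in the backtrack
prefer absence, in preorder. Per-origin leaf sets attach each captured
leaf to its nearest gain. The counter is verified against exhaustive
enumeration of ancestral labelings on 200 random trees. Two boundary
facts worth knowing: on an n-leaf star, k scattered captures are k
origins only while k ≤ (n+1)/2 (beyond that one root origin plus losses
is cheaper), and the gain count is *not* monotone in the presence
pattern (adding a capture can tip the optimum to a root origin with
fewer gains) — the tests pin both behaviours.

The tree itself is an input: an externally inferred maximum-likelihood
newick with bootstrap supports is the intended source (supports below
95 are collapsed into polytomies, strictly; missing supports default to
100, configurable; a collapsed edge's length is redistributed to its
children, preserving root-to-leaf depths — collapsing a positive branch
cannot preserve all pairwise paths). Re-implementing ML inference would
be out of proportion, so the pipeline ships a stand-in: neighbor joining
(deterministic lexicographic tie-breaks; exact on additive matrices) on
Poisson-corrected p-distances over the concatenated polymerase
translations, midpoint-rooted (the midpoint halves the tree diameter,
which provably minimises the maximum root-to-leaf depth). The stand-in
assumes equal-length polymerase ORFs (no indels); with real, unequal
sequences it refuses and asks for an external tree rather than guess an
alignment.

## Codon-family usage

Codons are tallied in frame 0 over the 14 principal mitochondrial genes
(atp6, atp8, atp9, cob, cox1–3, nad1–6, nad4L), terminal stops excluded,
internal stops counted but flagged. Families follow the shipped
anticodon map (`data/trna_families.tsv`): 24 tRNAs partitioning the 62
mold-mito sense codons using organellar wobble conventions — single
U34 tRNAs read whole four-codon boxes ("superwobble"), G34 reads NNY,
U34 reads NNR, with Ile(TAT) for ATA and Met(CAT) for ATG. The map is
data, not code, and the loader validates the partition, so a curated
annotation can replace it; per-amino-acid (rather than per-tRNA) pooling
is available by editing that file. Cross-genome averaging is the
unweighted mean of per-genome fractions (long genomes should not
dominate; pooled counts are a flag away). Ranking is ascending
(1 = rarest), ties sharing the smaller rank.

## The synthetic test bed

The generator (`mitoplasmid.simulate`) is the study's ground truth
factory: identical config + seed give byte-identical FASTA and a JSON
manifest in which every planted feature is locatable at its recorded
coordinates. Default study conditions: 20 hosts; ~24 kb mitochondrial
genomes carrying the 14 principal genes (codons drawn from configured
family weights; the defaults give Arg-TCG and Cys the two smallest
weights, as observed in real fungal mtDNA) and a shared 24-tRNA gene
set (~72 nt each, anticodon planted at offset 33); 50 decoy contigs per
host, 20 % of them length-matched into the 5–15 kb window to stress the
size filter; and 12 planted plasmids — nine autonomous invertrons, two
same-strand non-invertron linear plasmids, three near-intact insertions
emitted as separate contigs with 1 kb mtDNA-derived flanks (emulating an
assembler splitting at the insertion boundary), with 300 nt TIRs,
900/800-aa polymerases and ~150 nt pads. One-base "collars" just inside
each TIR are set to A on both sides so they cannot pair, pinning the
detected repeat to the planted coordinates.

Polymerases evolve along a known plasmid tree (default: three quartets
off the root; per-edge amino-acid substitution 1.5–3 %, root 8 % from
the panel), then are back-translated with uniformly chosen sense codons,
so relatives are similar at the protein level but nucleotide-divergent.
Six captures are planted — Arg-TCG ×3, Cys ×2, Trp ×1 — each on a leaf
whose sister carries no capture, so the designed minimum is six
independent events; two captures (one Arg, one Cys) coincide with
deletion of the host's gene ± 300 nt, the two-loss configuration of the
real data. Capture blocks copy the donor mtDNA's gene ± 300 nt with 5 %
flank divergence (transition:transversion 2:1) and an exact gene by
default. Capturable tRNAs get ≥ 450 nt tRNA-free spacers so a capture
flank never swallows a neighbouring gene; insertion sites are reserved
in wide inter-gene spacers for the same reason; planted homology blocks
sample tRNA-free mtDNA. Degradation of insertions applies substitutions
(ORF-internal stops repaired and boundary stops restored for
"near-intact" plants), or forces n stop codons per polymerase placed one
per bin across the ORF (n ≥ 5 guarantees no surviving 1 kb frame), and
can fragment the copy.

**What passing these tests shows — and does not.** The synthetic data
have no indels, no repeats, no assembly artifacts, no sequencing error,
and mitochondrial genomes that are unrelated across hosts except at
tRNA genes and planted blocks; intergenic sequence is uniform-random.
Perfect precision/recall under these conditions validates the logic and
the coordinate arithmetic of every step, and the threshold behaviour at
the planted divergences — not performance on real assemblies, where
diverged repeats, nuclear mitochondrial insertions and fragmented
assemblies would raise both error rates.

## Design choices in the open

* Detection thresholds, the 50 bp / 0.001 filter, the 5–15 kb window and
  the support-95 collapse are the published settings; capture (0.9/0.9)
  and loss (0.7/0.5) thresholds, TIR defaults, `flank_min` = 100 nt and
  the 100-point polymerase floor are this package's, chosen once and
  recorded here.
* The pipeline does not cache stage outputs: it is deterministic and
  desk-scale (the full default analysis runs in well under a minute), so
  content-hash caching would add state and failure modes for no saved
  time. Reruns are byte-identical, which the tests assert directly.
* Problem sizes in the tests and the acceptance run — 20 hosts, 50
  decoys/host, 50 capture/loss scenarios, 200 random trees and 200
  random alignment pairs — are the package's desk-scale study
  conditions; they complete in a few minutes on one CPU.
* Wet-lab steps, read assembly, the NCBI BLAST web service, MAFFT/
  Gblocks/IQ-TREE and tRNA-Scan secondary-structure validation are out
  of scope; external alignments and trees are accepted as inputs at the
  module boundaries. An optional anticodon-position sanity check stands
  in for structure validation of captured tRNAs.
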