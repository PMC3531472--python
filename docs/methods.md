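# Methods

This note records the models, conventions and numerical choices behind
`cicermark`, and what the synthetic-data experiments do and do not
demonstrate.

## SSR mining

A locus is a maximal perfect tandem repeat of a primitive unit of
2–6 nt. Internally, for each unit size k the scanner finds maximal
period-k regions — runs where every base equals the base k positions
earlier — and reports the leading complete-unit run of each region;
partial trailing units are never counted, and `N` terminates a region.
Minimum tract lengths are 12 nt for k = 2 and 15 nt for k = 3–6, which
translate to minimum unit counts 6/5/4/3/3; mononucleotide runs are
excluded by the primitivity requirement.

Tracts of different unit sizes can overlap (a dinucleotide run can
continue in phase into a trinucleotide run). We resolve overlaps
greedily: longer tracts win, ties prefer the smaller unit size, then
the leftmost start. This subsumes the simpler "drop contained loci"
rule and guarantees the output is non-overlapping, which downstream
compound grouping relies on. One consequence is that exact
reverse-complement mirror symmetry holds for isolated tracts but not at
junctions between adjacent repeat regions, where the partial-unit
remainder is orientation-dependent; no complete-unit reporting
convention avoids this.

Motif classes are canonicalized as the lexicographic minimum over all
rotations of the motif and its reverse complement, reported as
`canonical/revcomp` (e.g. `AAG/CTT`). Compound repeats group
consecutive loci separated by ≤ 100 nt (configurable).

Primer pairs are picked by scanning each flank outward from the tract
for the first window of 18–24 nt with GC 40–60 %, Tm 55–62 °C and no
mononucleotide run of 5+. Tm uses the simplified formula
`Tm = 64.9 + 41·(GC_count − 16.4)/length`, a deterministic stand-in for
full nearest-neighbor thermodynamics; loci with < 100 bp of flank on
either side are ineligible. Under this Tm formula the joint GC/Tm
window is narrow (for a 20-mer only GC-count 12 satisfies both), which
is why primer lengths are allowed to vary across the full 18–24 range,
including for the allele-specific primer below.

## Polymorphic SSRs

Matching is anchored on ortholog pairs rather than all-vs-all flank
search: in gene families flank matching alone is ambiguous, while RBH
pairs compare the same gene. Within an ortholog pair, loci of the same
canonical class match when the 20 nt immediately left (right-aligned at
the tract edge) and right (left-aligned) of both tracts agree at ≥ 90 %
ungapped identity; both knobs are configurable. Each locus matches at
most once — best mean flank identity wins, ties to the leftmost locus.
Matches with equal unit counts are retained as matches but excluded
from the polymorphic set; summary cuts count unit differences ≥ 3
(≥ 6 nt of length difference) and ≥ 10, both inclusive. Positional
distributions use the tract midpoint over ten equal relative-position
bins, with midpoint 1.0 assigned to the last bin.

## Fixed-difference SNP calling

Each pileup column carries per-genotype read bases and Phred
qualities. For genotype g and candidate fixed allele x the likelihood
is `L_g(x) = Π_i (1−e_i)` over matching reads times `Π e_i/3` over
mismatching reads, with `e_i = 10^(−q_i/10)` capped at 3/4 so that a
quality-0 base is exactly uninformative. With a uniform prior over the
16 ordered allele pairs, the reported posterior is the total
probability of the 12 differing pairs; the called alleles are the
argmax pair. Likelihoods are evaluated in log space and renormalized by
the maximum, so deep columns cannot underflow. `N` bases are dropped
before anything is counted.

The filter chain applies, in order: posterior ≥ 0.95; per-genotype mean
Phred at the site ≥ 30; per-genotype depth ≥ 3; consensus base ratio
exactly 1 in both genotypes; then removal of every candidate lying in
any 10 bp window holding ≥ 3 surviving candidates (the window rule
removes all members, it does not keep one); then removal of candidates
within 3 bp of any column with indel evidence in either genotype. Each
reject carries its first failing flag and per-filter attrition is
logged. The order is fixed because attrition bookkeeping depends on it;
the cluster rule deliberately operates on candidates that survived the
per-site filters.

## Orthology, Ka/Ks and divergence dating

RBH uses best hits by lowest E-value, then highest bitscore, then
lexicographic subject id; a pair is kept when both directions are
mutual best hits with E ≤ 1e-20 and best-hit alignment length ≥ 300 nt.
For small or simulated inputs the hit tables are computed by calling
the `blastn` executable; production inputs supply precomputed tables.

Codon alignment fixes the frame of the first sequence as the one (of
six) with the longest stop-free codon run; the second sequence's frame
is whichever of its six translations aligns best (global protein
alignment, BLOSUM62, gap open −10 / extend −0.5). The protein alignment
is threaded back onto codons and every column containing a gap, stop or
ambiguous codon in either sequence is dropped pairwise; pairs with
< 100 aligned codons are skipped with a logged reason.

Ka/Ks follows Nei–Gojobori (1986): per-codon synonymous site fractions
from the single-base mutation fates under the standard code (changes to
stop codons count as nonsynonymous), site counts averaged over the two
sequences, multi-hit codons resolved by averaging over minimal
mutational pathways with stop-passing pathways excluded (falling back
to all pathways only when every pathway is blocked), and Jukes–Cantor
correction `d = −(3/4)·ln(1 − 4p/3)`, undefined at p ≥ 3/4
(saturation). This is a deterministic desk-scale stand-in for
maximum-likelihood codon models; its values differ from ML estimates,
so published real-data means are not comparison targets. Our site
counts agree exactly with Biopython's NG86 implementation; difference
counts agree wherever no mutational pathway passes through a stop
codon (Biopython averages over stop-passing pathways instead of
excluding them).

The Ks peak is the highest-count bin of the Ks histogram with values
assigned to the nearest multiple of the bin width (0.002 by default,
chosen to resolve a 0.006–0.008 peak region); exact zeros — pairs with
non-detectable divergence — are excluded, and ties take the smaller
Ks. Divergence time defaults to T = Ks/r with
r = 1.5×10⁻⁸ synonymous substitutions/site/year; the textbook
T = Ks/(2r) convention is available as `time_convention = ks_over_2r`,
since the two conventions are both in circulation and differ by the
factor attributing divergence to one or both lineages. Selection
summaries average ω = Ka/Ks over pairs with 0 < Ks ≤ 2 and defined ω;
mean-of-ratios is upward-biased at low divergence (small Nd, Sd), so
the recovered mean ω slightly exceeds the simulator's target.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
two haploid descendant transcriptomes of a common codon-structured
ancestor. Defaults are the study conditions: GC 38 %, transcript
lengths 600–1500 nt (mean ≈ 1 kb), pairwise synonymous divergence
0.008, ω = 0.3, κ = 3.8 (transition fraction κ/(κ+2) ≈ 0.655, i.e. a
~1.9 transition/transversion count ratio), read depth Poisson(10),
base quality normal(37, 2) clipped to [2, 60], sequencing error 10⁻³.
Everything is deterministic under the seed.

Substitutions are placed by acceptance resampling: candidate sites are
drawn uniformly, the alternative base transition-weighted by κ, the
change classified synonymous/nonsynonymous against the current codon,
and accepted while the per-lineage quota for its class (synonymous
target d/2 over NG86 synonymous sites; nonsynonymous target ω·d/2 over
nonsynonymous sites) is unfilled; changes creating stops are rejected
and each nucleotide site is hit at most once across both lineages, so
every substitution is a fixed difference. Exact quotas hit the target
divergence precisely but condition the accepted Ts/Tv mix on the
synonymous/nonsynonymous split, so the realized transition fraction
deviates from κ/(κ+2) by a percent or two; the unconstrained SNP
planter realizes it exactly.

Planted SSRs insert the same motif at the same ancestral offset in
both genotypes with per-genotype unit counts; the single bases adjacent
to the insert are set (identically in both genotypes) to break the
repeat period, so the mined tract is exactly the planted one.
Transcripts carrying SSR inserts are excluded from SNP planting and
pileup simulation because unequal insert lengths shift homologous
coordinates. Heterozygous pileup sites emit an exact 50/50 allele split
per column — the even-sampling idealization of a diploid site — so
their rejection by the consensus-ratio filter is a property of the
filter, not of sampling luck. Error bases are uniform over the three
alternatives and qualities are independent of error status; both are
simplifications adequate for filter testing but not models of real
sequencer error.

What passing recovery tests shows: the implementation applies its
stated rules correctly at realistic depths, qualities and divergences.
What it does not show: robustness to misassembly, paralog collapse,
alignment error, indel-rich divergence, or non-uniform error models —
none of which the generator emulates.

## Validation experiment sizes

The seeded recovery suite (also run by `scripts/acceptance.py`) uses:
1000 planted fixed SNPs plus 100 heterozygous sites and 50 indel
columns across 200 transcripts of 600–900 nt at depth 10 / Phred 37
(observed recall ≈ 96–98 %, zero false or heterozygous acceptances);
200 planted SSR loci (unit differences cycling 0–4, 160 polymorphic)
across 210 transcripts anchored via blastn RBH (recall 100 %, zero
false pairs); and 2000 ortholog pairs of 2.1–3.0 kb evolved at
synonymous divergence 0.008 (peak recovered at 0.008, giving 0.53 My
at r = 1.5×10⁻⁸). The 2.1–3.0 kb length for the Ks experiment is
deliberate: each pair's Ks takes values in steps of one substitution
per ~500–700 synonymous sites, and shorter transcripts cannot resolve
the 0.002 histogram bin.

## Known limitations

* Orthology is pairwise RBH only; paralog-aware methods (trees,
  synteny) are out of scope.
* Ka/Ks is NG86, not ML; saturated pairs are reported as undefined
  rather than estimated.
* The primer rules cover composition constraints only (no hairpin or
  dimer thermodynamics).
* SNP calling requires the externally supplied pileup dialect; read
  mapping and indel calling are out of scope.
* Within-genotype heterozygote genotyping is not attempted: a
  heterozygous site is evidence against a fixed difference and is
  filtered, nothing more.
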