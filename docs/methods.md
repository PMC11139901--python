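# Methods

This note documents the models, defaults and numerical choices behind
`lariatkit`, and what the simulated study conditions do and do not show
about real data.

## Coordinates and strand conventions

All coordinates are 0-based, half-open, on the reference strand (BED
convention); a branchpoint is reported as the 0-based genomic position of
the branch nucleotide. All intron-relative logic (5'SS windows, branch
offsets, tail windows, lariat topology) operates on the strand-corrected
(transcript-orientation) sequence; minus-strand positions are mirrored
through `end - 1 - offset`. Sequence windows attached to annotations — the
first 20 nt of each intron (the 5'SS anchor) and the last 250 nt (the
branch-bearing tail) — are stored strand-corrected.

## Synthetic genomes and annotations

`make_genome` builds contigs of intergenic spacer and single-transcript
genes on both strands, each gene holding `introns_per_gene` introns
(default 2, so same-gene contrasts and U2-vs-U12 comparisons are
exercised). Introns are 300–600 nt by default, start GT and end AG (U12
introns carry a distinct `GTATCCTT` 5'SS motif), and each carries one
planted branch nucleotide:

* branch base drawn from 78% A / 10% G / 6% C / 6% T (configurable); the
  78% mirrors the qualitative A-dominance of branchpoints recovered in
  debranching-deficient cells, not a literature estimate;
* embedded in a YTNAY-like context (pyrimidine, T, any, branch,
  pyrimidine) followed by an ~85%-pyrimidine tract to the 3'SS;
* placed 22–70 nt from the 3' terminus, always within the intron's last
  100 nt.

Intron 5'SS 20-mers are drawn until unique across the annotation, so the
splice-site mapper's uniqueness requirement is satisfiable by construction.
`make_genome` returns `(genome, introns, gene_models)`; the gene models
(exon intervals) feed the read simulator and the spliced/unspliced
classifier.

## Debranching kinetics

`DebranchKinetics` models lariat survival under the debranching enzyme.
The reference substrate (A branchpoint, no 5'SS modifier) survives with
fraction `base_survival` (default 0.05, i.e. a 20-fold knockout/wildtype
enrichment). Other substrates survive as

```
survival = base_survival ** (rate(branch base) × motif modifier)
```

so a relative debranching rate below 1 (a slower substrate) yields a higher
survival fraction — the exponential form corresponds to first-order decay
over a fixed exposure. The 5'SS modifier multiplies the rate when the
intron carries G at configurable 1-based positions (default 2 and 4);
`u12_rate_factor` scales the rate of U12 introns. In the debranching-null
condition survival is identically 1. With flat rates the expected
null/active count ratio is exactly `1/base_survival` before Poisson
sampling; all acceptance-style fold-change checks build on that identity.

## Read simulation

Lariat reads are constructed as
`[intron sequence ending at the branch nucleotide][intron sequence from
position 0]`, with the junction uniform along the read subject to both
blocks >= `min_block` nt (default 1; the mapper-validation conditions use
20 so that both algorithms can recover every read). Intron circles join
the intron 3' terminus to position 0; linear mRNA and pre-mRNA reads are
uniform substrings of the spliced and unspliced transcripts.

Reverse-transcriptase branch readthrough is modelled as a single
substitution at the branch nucleotide itself — tracing cDNA synthesis
around the lariat, the branch base is the first template base copied after
crossing the 2'-5' bond — with configurable probability (readthrough
fidelity is known to be poor and sequence-dependent but unquantified; one
knob suffices to test mapper tolerance). Per-base substitution/N/indel
noise is applied from a separate RNG stream so that noise settings never
perturb read placements at a fixed seed. Qualities are a constant Q30
placeholder; nothing downstream is quality-aware.

What the simulator does **not** emulate: repetitive sequence and paralogy
(alignment uniqueness is nearly guaranteed on random toy genomes), splice
isoform diversity, coverage biases, paired-end structure, and realistic
human intron length/composition distributions. Passing tests therefore
demonstrate algorithmic correctness on the assumed read structure, not
performance on real libraries.

## Alignment core

The aligner performs *fit* alignment: the whole query aligns, the
reference contributes a substring. The scoring scheme is fixed at match
+1, mismatch −2, gap −(3 + length) (open −3, extend −1); all downstream
filters are expressed in mismatch/indel counts, so the scheme only breaks
ties. N never matches. The search enumerates, vectorized over all
placements, every alignment with at most one internal indel of bounded
length — exhaustive within that budget, verified against a full
dynamic-programming oracle on kilobase instances. A full affine DP is kept
as a diagnostic fallback for reads whose best explanation needs two indels
or a longer one; the splice-site mapper uses it to attribute rejection
reasons. Linear classification (mapped iff the read fits end-to-end within
a 5%-of-length mismatch budget) is seeded by exact k-mers (k=12); this is
complete whenever the longest error-free stretch reaches k, which holds at
the default budget for simulated read lengths, and does not consider
indel-containing linear alignments. Spliced transcripts are indexed
alongside the genome so exon-junction mRNA reads count as linearly mapped
(the role a spliced aligner plays on real data).

## Branchpoint mapping

Both mappers run on linearly unmapped reads, try both read orientations,
and report the branch base from the genome (strand-corrected), never from
the read, since the read base at the branch is unreliable.

Split mapper: ">15 bp" segments are read strictly as >= 16 nt. The read's
3' part must match an intron prefix exactly and be the segment's unique
exact genomic occurrence; the read's 5' part must occur uniquely within the
same intron, ending at the branchpoint, in inverted order (branch offset at
or beyond the upstream block's end), with one tolerated mismatch at its
terminal (branch) base. Among valid bipartitions the highest total
alignment score wins; ties across distinct (intron, branchpoint) pairs are
discarded as ambiguous.

Splice-site mapper cascade, every rejection recorded with its reason:
(1) > 5% ambiguous characters; (2) linearly mapped; (3) no unique perfect
20-nt 5'SS hit (reads matching several 5'SSs are rejected even when the
hits are identical paralogous sequences); (4) trimmed 5' portion < 20 nt;
(5–6) alignment to same-gene 250-nt tail windows within <= 5 mismatches,
<= 10% mismatch rate, <= 1 indel of <= 3 nt; (7) inverted order (the
trimmed block must start 3' of the 20-nt 5'SS block); (8) score ties
discarded. Restricting the tail search to the 5'SS-matched gene up front
produces exactly the call set of an all-introns search followed by the
gene restriction, since only same-gene alignments can become calls; only
the reason recorded for out-of-gene-only alignments differs. When no
in-budget alignment exists, a relaxed enumeration and the DP fallback
compete (highest score wins) to name the violated filter —
mismatch budget, mismatch rate, indel count, or indel length.

Intron-circle filtering marks calls whose branchpoint lies within
`circle_tolerance` nt (default 2) of the intron 3' terminus; the tolerance
absorbs end-trimming ambiguity and is configurable down to 0 (exact
terminus only).

## Analytics

Recovery rate is exactly `lariat reads / mapped reads × 1e6`. Fold changes
divide per-million-normalized levels, with a 0.5-normalized-unit
pseudocount per intron (needed for introns absent from one condition);
set-level fold changes sum normalized levels before the ratio and use no
pseudocount. The positional G-enrichment test and the editing contrast use
a Pearson chi-square computed from the textbook Σ(O−E)²/E (optionally
Yates-corrected), checked against scipy; the eCLIP enrichment contrast
uses a hand-built Welch t on log2 per-intron fold changes, also checked
against scipy. Sequence logos stack strand-corrected windows per distinct
branchpoint (optionally only single-branchpoint introns) or per 5'SS of
the top-N introns by read support, ties broken by intron id for
determinism. Spliced/unspliced classification requires a 6-nt overhang on
each side of the junction/boundary and locates reads by exact substring
match against the transcript models — adequate for noise-free simulation,
deliberately not a general aligner. "Positions 2 and 4 downstream of the
5'SS" are interpreted as 1-based intron positions (position 1 = first
intron base) and are configurable, since position-origin conventions vary.

## Reporter assay (MPRA)

The library replaces the −3..+2 hexamer around the branch (branch at
hexamer offset 3 — the convention used for score tracks as well) with all
4096 hexamers × 4 barcode pairs. Barcode filtering drops 11-mers
containing TAA/TGA/TCA (potential cryptic branch sites) and keeps, for
each of five hexamer-based regulatory score tables, only barcodes at or
below the pool median of the sum of squared overlapping-hexamer scores
(ties at the boundary pass; a combined-sum mode is available). Requiring
the bottom half of all five tables independently retains only ~1.8% of the
4^11 barcode space, so the pool generator scans the entire space in one
deterministic vectorized pass. Published score tables are not shipped; a
seeded synthetic generator provides stand-in tables and user TSVs are
accepted. Intronic and exonic barcodes draw from the same filtered pool
(the two roles occupy different construct positions and are read
separately), each role using 16,384 distinct barcodes with no species
pairing a barcode with itself.

Splicing efficiency uses the pseudocounted, library-normalized ratio given
in the README; the input-weighted mean of SE is 1 by algebra and asserted
to 1e-12 on every computation. The functional score is log2 of the mean SE
over a hexamer's barcode pairs; when replicate tables are present the
per-replicate scores and their mean ± sd are reported alongside the pooled
score, since the within/across-replicate reduction order is a genuine
choice.

## RBP conditioning and motifs

A binding site belongs to an intron only if fully contained (a
partial-overlap mode exists); the control pool holds introns with no site
of any analyzed RBP. Site-to-branchpoint distance runs along the circular
lariat topology with the site summarized by its midpoint: in the loop the
distance is min(direct upstream path, path through the branch junction);
in the tail it is the linear offset. Motifs are built by ranking 5-mers by
log2 enrichment over a uniform expectation (pseudocount 1), greedily
aligning the top 10 to the top 5-mer at the maximal-agreement offset
(ties: smallest |offset|, then negative), and stacking with equal weight.
Scanning scores the log-odds (vs uniform, pseudocount 1e-3) at every
offset of the intron sequence and its reverse complement and flags
windows at >= 0.8 × the maximal attainable score by default — a
documented stand-in for an external PWM-scanning service's defaults, with
the threshold configurable.

## Auxiliary assays

The co-IP filter calls a hit when the 3-replicate control mean is < 3 and
the IP mean is > 10 (strict inequalities), substitutes 0.1 for zero-count
means in the fold change, and reports a two-sided Student t-test on the
triplets. Editing rates are exact proportions of edited adenosines;
correction subtracts the matched non-transfected rate and floors at zero
(a ratio mode is provided and labelled, as the correction's functional
form is a choice); the condition contrast is a Pearson chi-square on raw
edited/unedited counts, because the test needs counts, not corrected
rates.

## Study conditions and problem sizes

The validation suite and `scripts/acceptance.py` use desk-scale problem
sizes chosen to make the programmed parameters statistically recoverable:
a 20-fold regime at 1e4 expected knockout lariat reads (Poisson noise on
the global ratio ≈ ±1), mapper validation on 2000 noise-free lariat reads
with blocks >= 20 nt plus 2000 linear reads, composition contrasts at
~3000 called reads, a 4-fold reporter-efficiency ratio at depth 1e6
(recovered log2 difference within ±0.1), and editing contrasts at ~400
bases per condition with a 4% wildtype baseline and 10% knockout rate — a
2.5× fold within the 2–3× band such assays report, at a baseline where the
chi-square has ~90% power; the acceptance script averages the editing fold
over 20 replicate simulations for a stable summary. Recovery rates
computed at these depths are orders of magnitude above real-library values
because simulated lariat:linear ratios are high; each reported value
carries its problem size.

## Known limitations

Uniqueness checks rely on the near-absence of repeats in random toy
genomes; no duplicate-read collapsing; the linear classifier ignores
indels; the splice-site mapper cannot recover reads whose junction leaves
either the 20-nt 5'SS or the 20-nt trimmed portion incomplete (the split
mapper covers those down to 16-nt blocks); multiple-testing correction is
left to callers; and the simulator's independence assumptions (one
transcript per gene, uniform junction placement) are simplifications.
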