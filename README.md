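# lariatkit

Toolkit for studying intron lariat turnover with sequencing data: it
simulates lariat-bearing RNA-seq reads under a debranching-kinetics model,
calls branchpoints with two independent mapping algorithms, and computes the
downstream statistics used in debranching-enzyme (Dbr1) knockout studies —
lariat recovery rates, knockout/wildtype fold changes, branchpoint and
5' splice-site composition, splicing-reporter (MPRA) functional scores,
eCLIP-conditioned lariat enrichment, co-IP spectral-count filtering, and
ADAR-timestamp editing rates.

It is written for computational RNA biologists who want a small, fully
tested, self-contained reimplementation of this analysis stack that runs on
simulated data at desk scale — no reference genome or archive downloads —
while accepting user-supplied FASTA/FASTQ/BED/TSV inputs through the same
interfaces.

## The science in brief

Splicing excises each intron as a **lariat**: the intron's 5' end is joined
to the **branchpoint** (BP, usually an adenosine near the 3' end) through a
2'-5' bond. The debranching enzyme Dbr1 linearizes lariats; when it is
absent, lariats accumulate (~20-fold in knockout cells). Reverse
transcriptase occasionally reads through the branch, producing a read with
an inverted gapped structure:

```
read  = [ intron sequence ending at the BP ][ intron sequence from position 0 ]
```

Two mappers recover the branchpoint from such reads:

* **split mapper** — tries every bipartition of an unmapped read into two
  segments of >15 bp; a call requires one segment to align uniquely at the
  first nucleotide of an annotated intron and the other uniquely within the
  3' portion of the same intron. The end of the downstream segment is the
  branchpoint. Alignments ending at the intron's 3' terminus are **intron
  circles** and are filtered out.
* **splice-site mapper** — finds a unique, perfect 20-nt intron 5'SS match
  in the read, trims from the match to the read end, and aligns the
  remaining 5' portion (>= 20 nt) to the last 250 nt of introns of the same
  gene, keeping alignments with <= 5 mismatches, <= 10% mismatch rate and at
  most one indel of <= 3 nt; the highest-scoring survivor ends at the
  branchpoint.

Sample-level lariat load is the **recovery rate** (lariat reads per million
linearly mapped reads); knockout/wildtype contrasts are ratios of these
normalized levels. The **branchpoint functional score** of a hexamer h
(occupying -3..+2 around the branch) comes from a massively parallel
reporter assay: with input/output counts i_j, o_j per barcode-tagged
species,

```
SE_j   = ((o_j + 1) / (i_j + 1)) / (Σ_k (o_k + 1) / Σ_k (i_k + 1))
score(h) = log2( mean SE over h's four barcode pairs )
```

The input-weighted mean of SE over a library is exactly 1 by construction.

## Worked example

Run the end-to-end simulated knockout-vs-wildtype workflow (simulate →
classify → both mappers → circle filter → aggregation → statistics):

```python
from lariatkit.io import RunConfig
from lariatkit.pipeline import run_pipeline

cfg = RunConfig(seed=1, n_genes=20, lariat_reads_null=1000, linear_reads=800,
                pre_mrna_reads=200, circle_reads=40, out_dir="demo")
report = run_pipeline(cfg)
print(round(report["global_fold_change_split"], 2))   # 19.33
print(round(report["global_fold_change_ss"], 2))      # 19.89
print(report["concordance"]["fraction_agree"])        # 1.0
```

The config programs a lariat survival fraction of 0.05 in the
debranching-active (wildtype) condition, so the expected knockout/wildtype
fold change is 20; the two printed values (19.33 and 19.89 for the split and
splice-site mappers) recover it within Poisson noise at 1000 expected
knockout lariat reads. Every branchpoint called by both mappers agrees
(`fraction_agree` 1.0); the split mapper calls more reads (1005 vs 736 in
the knockout sample here) because the splice-site mapper additionally needs
the full 20-nt 5'SS *and* a >= 20-nt trimmed portion inside the read, which
reads with junctions near either end cannot provide. The knockout
branchpoint composition in the same report is 84.6% A / 9.0% G / 4.0% C /
2.5% T, reflecting the planted 78% A composition plus the A-biased sampling
of the abundance model.

The same workflow is available from the shell:

```
lariatkit run --seed 1 --out demo
lariatkit simulate reads --n-genes 10 --out sim
lariatkit map split --reads sim/reads_null.fastq --genome sim/genome.fa \
    --introns sim/introns.tsv --out calls.tsv
lariatkit mpra design --out library.tsv
```

## Layout

| module | contents |
| --- | --- |
| `lariatkit.synthetic` | toy genomes/annotations, debranching kinetics, read and count-table simulators with ground truth |
| `lariatkit.align` | k-mer index, exhaustive fit aligner, DP fallback, linear-read classifier |
| `lariatkit.mapping` | the two branchpoint callers, intron-circle filter, per-intron aggregation |
| `lariatkit.analytics` | recovery rates, fold changes, composition, logos, positional chi-square, spliced/unspliced ratios, U12 contrast, score annotation |
| `lariatkit.mpra` | reporter library design, barcode filters, splicing efficiency, functional scores, genomic score tracks |
| `lariatkit.rbp` | eCLIP interval conditioning, circular lariat distances, 5-mer motif building and scanning |
| `lariatkit.assays` | co-IP spectral-count hit filter, ADAR-timestamp editing statistics |
| `lariatkit.io` / `lariatkit.pipeline` / `lariatkit.cli` | formats, configuration, orchestration, command line |
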