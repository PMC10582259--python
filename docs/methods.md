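# Methods

## Model

clipqc treats assembly evaluation as a breakpoint-detection problem on the
alignments of the project's own reads. Every accepted alignment contributes
its aligned reference span to a per-position depth array and each soft/hard
clipped end contributes one *clip event* at a single coordinate: the first
aligned base for a left clip, one past the last aligned base for a right
clip. All coordinates are 0-based half-open; human-facing AGP output is
1-based inclusive per that standard.

At a clipped position the clipping ratio `r = clips / depth` is compared
against two thresholds. The model behind the bands is a diploid sample
sequenced without allele bias: at a locus where the assembly matches one
haplotype, the other haplotype's reads clip, so `r ≈ 0.5`; at a true
assembly defect neither haplotype's reads align through, so `r ≈ 1`, pulled
below 1 in practice by sequencing error and mapping noise. Positions are
labelled

* `het` for `h_low ≤ r ≤ h_high` (default 0.4–0.6, closed interval),
* `breakpoint` for `r ≥ f` (default 0.75; ≥ rather than > so the boundary
  case is deterministic),
* `ambiguous` in between — reported separately, never counted as error,
* `excluded` when depth < `m` (default 2) or depth > `M ×` mean depth
  (default 5; collapsed repeats attract pileups that cannot be interpreted).

The mean depth for the `M` filter is genome-wide per technology; a
per-contig option exists for assemblies with strong inter-contig coverage
differences.

Short-read (NGS) and long-read (SMS) evidence is then integrated per
junction, in priority order (structural evidence subsumes regional evidence
at the same junction, and a match consumes the evidence it used so one
junction yields one call):

1. SMS breakpoint + NGS breakpoint or NGS zero-coverage within ±100 bp
   (`cse_flank`) → **CSE**;
2. remaining NGS breakpoint with SMS depth ≥ `m` across the flank and no
   SMS breakpoint nearby → **CRE**;
3. remaining NGS gaps clear of existing calls, spanned by SMS → **CRE**
   anchored at the gap start (anchoring at the start is an arbitrary but
   deterministic choice);
4. NGS het with clean SMS spanning and no SMS het/breakpoint nearby →
   **CRH**;
5. SMS het corroborated by an NGS het, or by an NGS depth drop ≥ 40%
   relative to the surrounding flanks (approximating one missing
   haplotype) → **CSH**.

SMS-only breakpoints without any short-read corroboration are dropped: long
reads still carry enough residual error that an uncorroborated long-read
clip cluster is more often a mapping artifact than a misjoin.

Optional refinements: a coverage-discrepancy test for CREs (`-d`) compares
20-bp window means of SMS depth over ±200 bp of the NGS breakpoint and
requires `(max − min)/max ≥ d`; it defaults to **off** (`d = 0`) so that
spanning long reads alone validate a regional error — a non-zero default
would silently change recall on clean data. `--error-region` attaches the
enclosing NGS zero-coverage interval to each call, delimiting where the true
breakpoint lies when the junction neighbourhood is noisy.

## Filters and their defaults

| parameter | default | unit | role |
|---|---|---|---|
| `min_mapq` (q) | 20 | phred | drop ambiguous mappings |
| `exclude_flags` (F) | 1796 | bitmask | unmapped/secondary/QC-fail/duplicate |
| `h_low`–`h_high` | 0.4–0.6 | ratio | heterozygosity band |
| `f` | 0.75 | ratio | breakpoint cutoff |
| `min_cov` (m) | 2 | reads | minimum usable depth |
| `max_cov_mult` (M) | 5 | × mean | repeat-pileup exclusion |
| `sms_min_clip_frac` | 0.1 | of read length | SMS terminal-clip noise filter |
| `sms_cluster_radius` | 20 | bp | merge wobbling SMS clip coordinates |
| `cse_flank` | 100 | bp | NGS corroboration window for CSE |
| `cre_flank` / `cre_window` | 200 / 20 | bp | discrepancy test geometry |
| `window_frac` | 1e-4 | of assembly | normalization window width |

Supplementary alignments (flag 2048) are **kept** by default — they are not
in the 1796 mask and they carry the second half of split reads at real
junctions — with a flag to drop them. Hard clips count as clip evidence with
their CIGAR length even though the bases are absent from the record. Clip
events at contig termini (position 0 or contig length) are discarded: every
contig end clips trivially. Depth is computed from reference-consuming
operations only (`M/=/X/D`); clipped bases never add depth.

SMS calls are clustered (transitive merge within 20 bp, matching the
window granularity of the discrepancy test) because long-read clip
coordinates wobble by a few bases around one junction; the representative is
the position with the largest clip count (ties go left), merged counts are
summed, and the label is recomputed. Clustering is idempotent and conserves
total clip count. NGS breakpoints stay at single-base resolution.

## Scoring

Within non-overlapping windows of width `round(10⁻⁴ × assembly size)` the
raw error count `m` is damped to `Nw = Σ_{i=1..m} 1/i`. Tiling rather than a
literal sliding window is deliberate: tiling makes `Σ Nw` a well-defined
total (a sliding window would count each error up to `w` times), and a
window with 3 errors then contributes 1/1 + 1/2 + 1/3 = 1.83. Windows tile
each contig independently; the width derives from total assembly size.

`R-AQI = 100·e^(−0.1·N/L)` and `S-AQI = 100·e^(−0.1·10·N/L)` with `N` the
cumulative normalized CRE (resp. CSE) count and `L` in Mb. The tenfold
structural rate encodes that one misjoin corrupts downstream scaffolding in
a way many local indels do not. Per-fragment scores use the fragment's own
length (which may be far below 1 Mb — fragment scores of short contigs are
volatile by construction); heterozygosity densities use the same windowing.
Low-confidence calls (inside regions of ≥100 bp with NGS depth < m or
> M×mean) and ambiguous positions never enter `N` but are reported.

Degenerate inputs: `AQI(0) = 100` exactly; `L ≤ 0` and negative counts are
fatal; the coverage-discrepancy of an all-zero window set is defined as 1.

## Contig splitting

Each high-confidence CSE breakpoint cuts its contig, with the junction base
starting the downstream part (a 3.6-Mb contig cut at 1,874,290 yields parts
of 1,874,290 and 1,725,710 bp). Which side receives the junction base is
underdetermined; assigning it downstream keeps part 1 equal to the 0-based
breakpoint coordinate. Splitting conserves sequence content exactly;
fragments under `min_fragment` (default 1 kb) are emitted but flagged. The
AGP v2.1 file maps every part to its source interval so the original contigs
are recoverable.

## Synthetic benchmark

The simulator reproduces the standard evaluation protocol at desk scale.
Defaults (the `SimSpec` dataclass) are the package's study conditions: a
2-Mb, 2-contig genome; 300 heterozygous variants (270 small indels of
1–40 bp, 30 SVs of 15–40 kb); 150 regional errors (120 small indels, 30
repeat collapses/expansions of 20–100 bp); 40 structural errors (8 fragment
indels of 0.1–1 kb, 16 misjoin junctions realized as 8 exchanges of
equal-length 2–8 kb segments, 16 inversions of 1–5 kb); 40× NGS (150-bp
single-end) and 30× SMS (lengths N(10 kb, 2 kb) truncated to [1 kb, 60 kb])
coverage; MAPQ 60; substitution errors 0.1% (NGS) / 0.5% (SMS). Heterozygous
SVs default to ≥15 kb because smaller SVs are traversed by long reads as
in-read indel operations and produce no long-read clip evidence; they would
present as regional heterozygosity.

Alignments are **emulated analytically** rather than produced by an aligner:
read starts are sampled uniformly in assembly coordinates and each read's
record is derived from the planted truth. A read crossing an error junction
aligns its longer portion and clips the shorter one exactly at the junction;
variant-haplotype reads crossing a heterozygous anchor align downstream with
a left clip (so they keep supporting depth at the anchor and the ratio sits
at the allele fraction); reads elsewhere emit full-length matches. Clipped
bases are random so they cannot re-align. By default each sampled fragment
is sequenced once from each haplotype ("mirrored" sampling), realizing the
0.5 allele fraction exactly instead of binomially; independent per-read
haplotype assignment is available. Junction anchors of long-read-visible
categories are kept ≥15 kb apart (and ≥20 kb from contig ends) so that one
read rarely crosses two of them; all defect footprints are kept ≥600 bp
apart.

What the emulation deliberately does **not** model: mapping ambiguity in
repeats (every read has MAPQ 60), chimeric or low-complexity reads, GC or
strand bias, indel-containing CIGARs at regional defects (the caller reads
only clips and depth, so substitution/indel detail inside spanning reads is
irrelevant to it), paired-end structure (pairing adds no clip signal), and
the secondary junctions of an exchanged misjoin segment (each truth record
is realized as a single discordant junction at its start). Passing the
benchmark therefore shows that the decision rules recover exactly the
planted signatures under clean mapping; it does not bound performance in
repeat-rich regions of real genomes, where missed calls concentrate.

A known, accepted consequence of the filter stack: at a heterozygous SV the
long-read clipping ratio is not 0.5 but ≈0.45, because the 10% short-clip
filter deterministically suppresses the clip events of reads with small
overhangs while those reads still add depth. With only ~15 informative long
reads per locus at 30×, binomial spread pushes a minority of such loci below
`h_low = 0.4`; they are then recovered as CRH through their short-read
evidence. Heterozygosity as a family is recovered at ≥95% recall and
precision; the CSH/CRH subclassification of large het SVs is the one place
the caller is conservative.

Benchmark scoring matches each call to at most one truth record of its
class, greedily by breakpoint distance (ties leftward), counting a truth
record as recalled when a matching call lies inside its locus or within
±50 bp of a boundary. With no truth records of a class, recall is defined
as 100; with no calls, precision is 100.

## Problem sizes

The test suite exercises the full default 2-Mb simulation once (~15 s) and
otherwise uses 150–500 kb scenarios; the acceptance script re-runs the
2-Mb protocol from scratch. All randomness flows from explicit seeds; the
simulate → emulate → call → evaluate pipeline is bit-reproducible per seed.

## Limitations

* Calling quality is bounded by mapping quality: regions where the q-20 /
  F-1796 filter removes most reads are reported as low-confidence rather
  than called.
* Monoploid/diploid model: polyploid samples violate the 0.5 allele-fraction
  assumption behind the het band.
* The emulator validates logic, not aligners: results on real BAMs inherit
  the aligner's clip-placement behaviour near tandem repeats.
* Per-fragment AQI of very short contigs is noisy since `L` enters as a
  divisor.
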