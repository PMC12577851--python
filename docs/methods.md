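# Methods

## The procedure and its assumptions

refweave turns a reference genome plus target HiFi reads into "alternative
long sequences": long, read-backed sequences that a downstream hybrid
assembler can treat as ultralong reads. The underlying assumptions are

* HiFi reads are long (multi-kb) and highly accurate (≥ 99%), so a gapless
  seed-and-extend model with substitution-only consensus captures nearly all
  of their information content at the scales where this package's builtin
  backends are used;
* the reference is collinear with the target over most of its length —
  same-species (≲ 1% divergence) or closely related (a few %);
* assembly gaps in the target contigs are concentrated in repeats, where a
  polished reference (the *mixed genome*) carries exactly the long-range
  information the contigs lack.

The safety property the design is built around: alternative sequences may
*guide* the downstream assembly but must never contribute bases. The builtin
local assembler enforces this by construction (it emits no column without
read support), and the provenance audit verifies it on the final contigs.

## Stage parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `min_primary_fraction` | 0.9 | read span fraction for haplotype screening; "target haplotype read" has no standard operational definition, so this is surfaced as a flag |
| `consensus_min_depth` / `consensus_min_fraction` | 3 / 0.6 | polishing gate: columns below depth keep the reference base; 0.6 keeps heterozygous columns from flip-flopping |
| `min_placement_fraction` | 0.5 | a contig is scaffolded when its primary placement covers half of it |
| `flank` | 500 kb | window around each scaffold gap searched for collinear support |
| `min_identity` | 0.90 | collinear records below this are ignored for gap-flank blocks |
| `min_read_fraction` | 0.99 | related-species path: primary read alignments must span 99% of the read; span (not matched residues) is the metric, switchable via `length_metric` |
| `merge_distance` | 0 | read-support footprints are merged only when touching/overlapping |
| `min_block_length` | 20 kb | blocks must exceed typical HiFi read length to be useful backbones |
| `builtin_min_depth` | 2 | consensus emission gate: one erroneous read cannot dictate a column |
| `FilterConfig.min_depth` / `max_breakpoint_run` | 1 / 0 | any internal zero-depth base is a coverage breakpoint |
| `identity_ceiling` + `containment_fraction` | 0.999 + 0.95 | "adds nothing new": near-perfect identity over near-complete containment |
| `identity_floor` | 0.90 | "reference artifact": best alignment worse than this fails |
| `min_output_length` | 50 kb | final length floor for alternative sequences |

The coverage-breakpoint filter excludes an edge zone of half the median
read length at each candidate end, because coverage necessarily ramps there.
The five filter thresholds have no canonical published values; the defaults
were chosen so that error-free instances behave as the stage descriptions
intend (gap-spanning survivors; identical or divergent casualties) and every
one is exposed as a flag.

Mode asymmetry: in related-species mode the haplotype screen is skipped
(all reads polish the reference directly) and the identity filter is
recorded as `not_run` — with a diverged reference there is no meaningful
same-species contig comparison, so only coverage and length screening apply.

## The builtin aligner

Exact k-mer anchors (k = 15 for reads-to-genome, 19 for genome-to-genome;
every third query position sampled), grouped by (target, strand, diagonal).
Because every model in this package is substitution-only, all anchors of a
true locus share one diagonal, so collinear chaining degenerates to diagonal
voting: any diagonal with ≥ 3 anchors is extended without gaps using an
x-drop rule (+1 match, −2 mismatch, drop 30), and mismatches are counted
exactly over the extension. One record per surviving diagonal; the best
(most matched residues, ties broken by target name then position) is the
primary, the rest secondaries. K-mers occurring more than 10 times in the
target are not indexed, which keeps exact repeats from flooding the anchor
table; diverged repeat copies (the realistic case) remain mappable.

This aligner is deliberately minimal: no indels, no spliced alignment, no
base-level CIGAR. Production runs should supply minimap2 PAF through
`ingest_external` / the `external_paf` backend; a test cross-checks builtin
primary placements against minimap2 `map-hifi` when the binary is on PATH.
Polishing is likewise substitution-only — with a gapless aligner there is
never unanimous indel evidence — and an externally polished mixed genome can
be passed in directly (`--mixed-genome`), skipping the correction stage.
One polishing round is performed.

## Gap-flank blocks include the gap projection

A scaffold gap's own projected interval on the mixed genome is part of its
block even though, by definition, no collinear record covers it. Without
this the merged block would stop at the gap edges, the extracted backbone
could not cross the gap, and localized assembly could never close it. The
block is still dropped when the retained collinear support around the gap
is too short (`min_block_length`).

## The synthetic generator

`refweave.simulate` produces truth-labelled instances: a random truth genome
with planted, 1%-diverged copies of a repeat unit; a reference derived by
i.i.d. substitution (0.5% same-species, 5% related-species preset); contigs
that are exact truth fragments omitting the planted gap segments (gaps
centred inside repeat copies by default — the failure mode real assembly
gaps concentrate in — with a flag for unique-sequence placement), shuffled
and randomly reverse-complemented; and HiFi-like reads with Gaussian lengths
(mean 9 kb, sd 1.5 kb, floor 1 kb), uniform start positions, random strand
and 0.2% substitution errors. The misjoin preset fuses interior segments of
two chromosomes into one contig, leaving interior junction points and a
region of the second chromosome covered only by the misjoined contig.
Everything is driven by one `numpy` generator, so a fixed seed gives
byte-identical FASTA/FASTQ output (gzip written with mtime 0).

What it does **not** emulate: indels (sequencing or evolutionary),
structural variation beyond the single misjoin, quality-value profiles,
chimeric reads, diploid/polyploid haplotype structure, and chromosome-scale
sequence lengths. Passing tests therefore demonstrate the pipeline's logic
and bookkeeping — projection, merging, consensus, filtering, provenance —
not robustness to indel noise or polyploidy; for that the external aligner,
polisher and assembler adapters are the production path.

### Problem sizes used in tests and the acceptance script

The standard same-species instance is a 200 kb single-sequence genome, four
5 kb repeat copies, two 8 kb gaps, 30× reads; the misjoin instance uses two
100 kb sequences. Unit tests use a 60 kb variant of the same structure.
These sizes keep every derived oracle (brute-force pileups, O(n²) interval
unions, exact substring attribution) cheap while preserving the length
hierarchy the method depends on: read ≪ block ≪ sequence, gaps wider than a
read, blocks longer than the 20 kb floor.

## Numerical and degenerate-input choices

* Consensus ties (equal vote counts) resolve to the lexicographically first
  base — deterministic, and at the 0.2% error rate ties essentially only
  occur at depth 2 columns near candidate edges.
* A missing `tp` tag in external PAF is treated as primary (the dominant
  aligner dialect omits it only in untagged dumps); logged.
* Scaffold gaps are floored at 1 bp so AGP stays valid when placements abut;
  `count_scaffold_gaps`, by contrast, counts only strictly positive
  placement distances, so redundant overlapping contigs are not mistaken
  for missing sequence.
* Zero-gap plans, empty bundles, unaligned candidates and empty alternative
  sequence sets all degrade to warnings plus empty output rather than
  errors; an empty read set or an unplaceable contig set is an error.
* The toy hybrid handoff drops an input contig when its best alignment to a
  consensus contig has identity ≥ 0.99 over ≥ 95% of its length.

## Known limitations

* The builtin assembler is a backbone-guided consensus, not a string-graph
  assembler: it cannot resolve haplotypes, and its candidates inherit the
  backbone's coordinate frame. It exists so the whole pipeline — and the
  filters that are the method's real safety net — can run and be tested
  hermetically; production localized assembly belongs to the external
  adapter (`assembler: external:<template>`).
* Multi-reference usage is independent runs whose outputs are concatenated;
  no cross-reference reconciliation is attempted.
* Polyploid genomes, metagenomes and NGS-only inputs are out of scope, as is
  Hi-C scaffolding (delegated entirely to downstream tooling: the pipeline
  stops at contig-level output).
* Same-species collinearity is consumed as PAF only. Alignments produced by
  other tool chains (e.g. nucmer) should be converted externally, e.g.
  `paftools.js delta2paf aln.delta > aln.paf`.
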