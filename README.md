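# refweave

Reference-assisted generation of **alternative long sequences** for genome
assembly. Given a high-quality reference genome (same species or a close
relative), a target de novo contig assembly, and the target's PacBio HiFi
reads, refweave produces long, quality-filtered sequences that emulate ONT
ultralong reads. Fed to a downstream hybrid assembler alongside the original
HiFi reads, these sequences guide the assembler across gaps and misassembled
regions — improving contiguity **without incorporating any reference-derived
bases** into the final contigs. The intended users are groups assembling many
related genomes (pan-genome / population projects) who cannot afford
ultralong sequencing for every sample but do have one or more finished
reference genomes.

## Method

Four stages:

1. **Reference correction.** HiFi reads are first screened against the
   target contigs: a read is kept when its primary alignment spans ≥ 90% of
   its length (same-species mode only). The reference is then polished by
   per-column majority consensus — a column is rewritten when depth ≥ 3 and
   the majority allele holds ≥ 60% of the votes — yielding the *mixed
   genome*, a reference rewritten to the target's alleles wherever reads
   cover it.
2. **Block discovery.** *Same species*: contigs are scaffolded against the
   mixed genome by homology, and high-identity (≥ 0.90) collinear alignments
   within 500 kb of each scaffold gap, together with the gap's own
   projection, are merged into *gap-flank blocks* (≥ 20 kb). *Related
   species*: collinearity is too disordered to predict gaps, so blocks are
   the merged footprints of primary (`tp:A:P`) read alignments spanning
   ≥ 99% of the read.
3. **Localized hybrid assembly.** Per block, the overlapping reads and the
   mixed-genome excerpt (the simulated ultralong "backbone") are assembled.
   The builtin backend is a backbone-guided consensus that emits only
   read-supported columns (depth ≥ 2); an adapter runs any external
   assembler via a command template for production use.
4. **Filtering.** Candidates are discarded if they have internal HiFi
   coverage breakpoints, if they are completely identical to (identity
   ≥ 0.999 and containment ≥ 0.95) or too divergent from (identity < 0.90)
   the target contigs, or if they are shorter than 50 kb. Survivors are the
   clean alternative long sequences.

A provenance audit verifies the headline safety property: final contigs of
the downstream hybrid assembly are attributable 100% to original HiFi reads,
with the alternative sequences acting as guides only.

All coordinates are 0-based half-open (PAF convention). The builtin aligner
is a deterministic seed-and-extend mapper (exact k-mer anchors, per-diagonal
voting, x-drop gapless extension) adequate for HiFi-accuracy data at toy
scale; externally produced PAF (e.g. minimap2 `map-hifi`/`asm5`) is accepted
everywhere alignments are consumed.

## Worked example

Simulate a same-species instance (200 kb truth genome, a reference 0.5%
diverged from it, contigs with two 8 kb gaps planted inside repeats, 30×
HiFi-like reads), then run the pipeline:

```sh
$ refweave simulate --preset same-species --seed 1 -o sim
wrote truth.fa, ref.fa, contigs.fa, reads.fq.gz, truth.json to sim

$ refweave run --ref sim/ref.fa --contigs sim/contigs.fa \
               --reads sim/reads.fq.gz --mode same -o out
1 clean alternative long sequences -> out/alt_long.fa

$ cat out/blocks.bed
chr1	0	200000	gap_flank:scaffold_chr1:gap0,scaffold_chr1:gap1	5

$ column -t out/verdicts.tsv
candidate            block          length  coverage  identity  length_filter  reasons
chr1_0_200000.cand0  chr1_0_200000  197528  pass      pass      pass           .
```

The two gaps sit 46 kb apart, so their 500 kb flanking windows merge into a
single block covering the whole sequence (`blocks.bed`). Its localized
assembly yields one 197,528 bp candidate — slightly shorter than the 200 kb
backbone because consensus is only emitted where ≥ 2 reads agree, which
trims the low-coverage sequence ends. The candidate passes all three
filters (`verdicts.tsv`) and spans both planted gaps. `out/edits.tsv` lists
the 899 reference columns the polisher rewrote to the target allele
(~0.45% of 200 kb, matching the simulated divergence over the read-covered,
haplotype-screened fraction).

From Python, the downstream toy handoff closes both gaps:

```python
from refweave import (run_hybrid_handoff, count_scaffold_gaps)
from refweave.seqio import load_sequences

truth = load_sequences("sim/truth.fa")
contigs = load_sequences("sim/contigs.fa")
reads = load_sequences("sim/reads.fq.gz")
alt = load_sequences("out/alt_long.fa")

print(count_scaffold_gaps(contigs, truth))   # 2
asm, prov = run_hybrid_handoff(alt, reads, contigs)
print(count_scaffold_gaps(asm, truth))       # 0
```

`refweave audit` then reports 100% original-read attribution for the
consensus contigs and flags nothing — the alternative sequence contributed
no bases.

## Module map

| module | role |
| --- | --- |
| `refweave.seqio` | FASTA/FASTQ (+gzip), PAF, AGP v2.1, BED readers/writers |
| `refweave.align` | builtin toy aligner + external PAF adapter |
| `refweave.correct` | haplotype read selection, consensus polishing |
| `refweave.blocks` | scaffolding, gap-flank & read-support block discovery |
| `refweave.local_assembly` | read partitioning, per-block consensus, external assembler adapter |
| `refweave.filters` | coverage / identity / length filters, provenance audit |
| `refweave.simulate` | truth-labelled synthetic instances (presets) |
| `refweave.pipeline` | orchestration, artifacts, toy hybrid handoff |
| `refweave.cli` | `refweave` command (simulate, correct, blocks, run, filter, audit) |

See `docs/methods.md` for the model, parameter defaults and known
limitations.
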