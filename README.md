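# paremir

Tools for annotating plant miRNAs from deep-sequenced small-RNA tags,
validating their target cleavage with degradome (PARE) data, and detecting
phased-siRNA loci together with the trigger miRNAs that initiate them.

In plants, most miRNAs guide endonucleolytic cleavage of their targets
between positions 10 and 11 of the miRNA:target duplex (counting from the
miRNA 5' end).  PARE sequencing captures the 5' ends of the resulting
downstream fragments at single-nucleotide resolution, so a predicted
target site can be tested directly: is there a degradome tag starting
exactly at the predicted slice position, and how prominent is it?  A small
class of 22-nt miRNAs additionally initiates phased siRNA production: the
cleavage position defines a register mod 21 (or 24) that downstream siRNA
5' ends then occupy.  `paremir` implements all three analyses as a tested,
configurable library with a thin command-line interface, plus a seeded
synthetic-data generator with ground truth so the whole pipeline is
exercisable without any downloads.

## The models in brief

* **miRNA discovery.**  Candidate tags (20-24 nt, ≥ 10 TP2M in one
  library, ≤ 20 genome hits) are evaluated on folded precursor windows:
  strand bias ≥ 0.9, abundance bias ≥ 0.7, and a miRNA:miRNA* duplex with
  ≤ 4 mismatches + bulges, no bulge > 1 nt.  A homology route rescues
  known-miRNA loci under relaxed criteria (≤ 8 defects, abundance bias
  ≥ 0.4).  Folding is deterministic base-pair maximization with a stacking
  tie-break (see `docs/methods.md`).
* **Target prominence.**  Sites are gapless antisense windows scored with
  mismatch 1 / G:U 0.5 (optionally doubled in the 5' core, positions
  2-13).  A site with a PARE tag exactly at its predicted cleavage
  position is classified in its best library on three criteria —
  abundance ≥ 10 TP10M, rank ≤ 2 in the transcript, peak percentage
  ≥ 20% — into Levels 1 (none met) through 4 (all met).
* **Phasing.**  A 9-cycle log-odds phasing score
  `(k-2)·ln(1 + 10P/(1+U))` is evaluated along strand-folded tag 5' ends;
  loci need a score ≥ 25 with boundaries at 20.  PARE ends within five
  phase cycles are scored against candidate trigger miRNAs (penalty 1 per
  mismatch, 0.5 per G:U; calls at ≤ 5) and annotated with their offset
  from the dominant phase register.

Every threshold above is a `PipelineConfig` field, not a code constant.

## Worked example

Simulate a study, then run the three stages:

```bash
paremir simulate --seed 1 --out demo
paremir mirnas  --genome demo/genome.fasta --tags demo/smallrna_tags.tsv \
                --known demo/known.fasta --out demo/mirnas
paremir targets --mirnas demo/mirs.fasta --transcripts demo/transcripts.fasta \
                --pare demo/pare_tags.tsv --out demo/targets
paremir phasing --genome demo/genome.fasta --tags demo/smallrna_tags.tsv \
                --pare demo/pare_tags.tsv --mirnas demo/triggers.fasta \
                --out demo/phasing
```

(`known.fasta`, `mirs.fasta` and `triggers.fasta` are FASTA files of
candidate sequences; in this demo they are taken from `demo/truth.json`.)
The commands print

```
dataset written to demo (seed 1)
7 miRNA calls -> demo/mirnas
3 predicted sites -> demo/targets
2 phased loci, 2 trigger calls -> demo/phasing
```

The seven calls are the three planted matures, their miRNA* partners
(abundant enough to be annotated in their own right), and the
relaxed-structure plant recovered through the homology route.  The
prominence table `demo/targets/prominence.tsv` classifies every planted
cleavage site as Level 4 in its best library:

```
mirna transcript  cleavage_pos_1based best_library  abundance_tp10m  rank  peak_percent_top2  level
   m0   target01                  141      panicle     1.99e+06         1          61.8           4
   m1   target02                  141         root     1.97e+06         1          61.7           4
   m2   target03                  141         root     2.01e+06         1          62.6           4
```

— each site holds ~62% of its transcript's degradome signal (the planted
peak fraction is 0.6), is the most abundant position (rank 1), and far
exceeds 10 TP10M, hence all three criteria and Level 4.  The trigger table
`demo/phasing/trigger_calls.tsv` identifies both planted triggers with a
perfect complementarity score at offset 0 from the phase register:

```
chrom  locus_start_1based  locus_end_1based  period  mirna       pare_pos_1based  score  register_offset
chr1   2675                2779              21      trigger-21  2675             0      0
chr1   3222                3341              24      trigger-24  3222             0      0
```

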