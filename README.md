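# smallrna

A two-library small-RNA sequencing analysis pipeline with a synthetic-data
generator for end-to-end testing. The pipeline takes two raw small-RNA
libraries (FASTQ) plus three reference FASTA files (mature miRNAs, labelled
ncRNAs, transcripts/unigenes) and produces:

- **preprocessing** — quality filtering, 3'-adapter trimming, per-category
  read accounting (adaptor-null, insert-null, 5'-adapter contaminants,
  short, polyA), collapsed unique tags, two-library overlap statistics and
  length distributions;
- **annotation** — ncRNA classification (rRNA/tRNA/snRNA/snoRNA, exact
  substring with precedence), conserved miRNA identification (full-length
  exact match, ≥10 reads in both libraries), isomiR collapsing into family
  members (≤2 nt total 5'/3' end difference, single linkage);
- **novel_discovery** — hairpin-based novel miRNA candidate search on
  transcript-mapped unannotated tags, using a bundled deterministic folding
  engine (stacked-pair DP, GC=3/AU=2/GU=1 tie-break weights, pseudo-energy
  in kcal/mol-like units) with duplex-geometry acceptance criteria and
  miRNA* detection with 2-nt 3' overhangs;
- **diff_expr** — reads-per-million normalization, log2 fold change with a
  symmetric pseudo-count, the exact conditional two-library count test
  (p(y|x) with inclusive upper/lower cumulative tails D and C), and
  significance tiers (extremely significant / significant / not / excluded);
- **target_prediction** — complementarity scanning with an Allen-type
  penalty scheme (mismatch 1, G:U 0.5, gap 2, doubled in miRNA positions
  2–13, expectation cutoff 3.0) and cleavage/translation calls;
- **qpcr_relative** — a 2^-ddCt relative-expression calculator;
- **synthetic_data** — a fully deterministic simulator that plants hairpins
  in transcripts, excises matures with isoforms and low-abundance star
  strands, adds contaminants, draws two-condition Poisson counts with known
  fold changes, and writes a per-read truth manifest.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: published-table
arithmetic identities, exact-test correctness against a rational-arithmetic
oracle, type-I error calibration, planted-truth recovery on a full-scale
simulation, isoform-collapsing agreement with brute force, and
dinucleotide-shuffle specificity.

## CLI

```sh
# generate a synthetic dataset with ground truth
smallrna simulate --seed 11 --outdir sim --n-hairpins 200 --depth 1000000 1000000

# run the whole pipeline
smallrna run --fastq1 sim/lib1.fastq --fastq2 sim/lib2.fastq \
    --mature sim/mature_ref.fasta --ncrna sim/ncrna_ref.fasta \
    --transcripts sim/transcripts.fasta --outdir out

# or stage by stage
smallrna preprocess sim/lib1.fastq sim/lib2.fastq --outdir out
smallrna annotate out/clean_tags.fasta --ncrna sim/ncrna_ref.fasta --mature sim/mature_ref.fasta
smallrna discover out/clean_tags.fasta sim/transcripts.fasta
smallrna diffexpr counts.tsv --n1 1000000 --n2 1000000
smallrna targets mature.fasta sim/transcripts.fasta
smallrna qpcr ct_values.tsv
```

`smallrna run` also accepts `--config pipeline.yaml` with any
`PipelineConfig` key; unknown keys are rejected. Reports are TSV files in
the output directory (read categories, library overlap, length
distribution, ncRNA classes, conserved members, novel candidates with
dot-bracket precursors, differential expression, target hits) plus a run
manifest with the config hash and per-stage counts. Identical seeds and
inputs give byte-identical outputs.

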