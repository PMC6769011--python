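# itrcapture

Analysis of AAV vector integration into CRISPR/Cas9-induced double-strand
breaks.

Adeno-associated virus (AAV) vectors are the workhorse delivery vehicle
for in-vivo genome editing. Their genomes normally persist episomally,
but a Cas9-induced double-strand break captures vector DNA at appreciable
frequency, and the junctions are dominated by the vector's 145-nt
inverted terminal repeats (ITRs). `itrcapture` implements the
computational side of quantifying and characterizing this phenomenon for
anyone analyzing amplicon or junction-library sequencing from AAV+CRISPR
experiments:

* **Amplicon analysis** — per-read editing-outcome classification
  (unmodified / substitutions-only / small indel / vector fusion) in a
  ±5-nt window around the blunt cut (3 bp upstream of the PAM), and the
  **AAV capture ratio**

  > capture ratio = n_fusion / (n_fusion + n_small_indel),

  the fraction of all nuclease-induced editing events that captured
  vector sequence. Also: the indel-size spectrum (bimodal: small NHEJ
  indels vs vector-scale insertions), junction-to-cut-site distances,
  the ITR-at-junction fraction, per-nucleotide ITR breakpoint profiles in
  a shared 145-nt frame, and a two-cut (exon-excision) variant with the
  inter-cut capture ratio.
* **Genome-wide analysis** — integration-site calling from ITR-primer-
  anchored junction libraries (GUIDE-seq-style), with automated curation:
  a shared-homology filter (host flanks matching vector sequence — e.g.
  vector-borne promoters — are false sites) and an ITR-evidence filter
  (vector evidence must extend beyond the primer into unique ITR),
  annotation (exonic > promoter > downstream > intronic > intergenic),
  per-million read normalization, unique-site clustering, and
  cross-condition recurrence.
* **Integrant architecture** — classification of fully sequenced clones
  into integration types: Type 1 (both ITRs + full cargo), Type 2 (full
  cargo, one ITR), Type 3 (ITR only), Type 4 (one ITR + partial cargo),
  concatemers; junction microhomology and host-flank indel measurement;
  whole-vector coverage profiles.
* **Synthetic data** — a fully seeded generator for all three input
  kinds with per-record ground truth, plus a miniature 465-bp ITR-flanked
  test vector and a desk-scale toy host genome. Every analysis here is
  validated against planted truth.

## Worked example

Simulate 2000 amplicon reads (half edited, a quarter of the edits
carrying vector) and analyze them end to end:

```yaml
# demo.yaml
pipeline: amplicon
seed: 7
simulate:
  n_reads: 2000
  edited_fraction: 0.5
  capture_fraction: 0.25
```

```bash
itrcapture run --config demo.yaml --out demo_out/
```

prints

```
INFO itrcapture: amplicon: 2000 reads, 751 indel, 247 fusion, capture ratio 0.2475
```

and `demo_out/report.json` contains (abridged):

```
n_total: 2000         # reads analyzed
n_small_indel: 751    # edits without vector sequence
n_fusion: 247         # edits carrying vector sequence
capture_ratio: 0.2475 # 247 / (247 + 751); planted value 0.25
itr_at_junction_fraction: 0.854  # fusions whose junction involves the ITR
```

The measured capture ratio (0.2475) is the binomial realization of the
planted 0.25; at zero sequencing error it equals the truth-label ratio
exactly. The directory also holds `per_read.tsv` (one classified row per
read), `itr_breakpoint_profile.tsv` (junction counts over the shared
145-nt ITR frame), `truth.tsv` (the generator's labels) and
`manifest.json` (config snapshot, seed, read accounting).

The same `run` entry point drives `pipeline: genomewide` (site calling +
curation on a simulated junction library) and `pipeline: clones`
(architecture classification). File-based subcommands (`itrcapture
amplicon|genomewide|clones`) accept your own FASTQ/FASTA/GFF3 inputs; see
`itrcapture --help`.

As a library:

```python
from itrcapture import aav_lambda_465, quantify_indels, summarize_amplicon
from itrcapture.synthetic_data import SimConfig, make_toy_locus, simulate_amplicon_reads

locus, vector = make_toy_locus(), aav_lambda_465()
reads, truth = simulate_amplicon_reads(SimConfig(seed=7, n_reads=2000), locus, vector)
outcomes = quantify_indels([(r.name, r.sequence) for r in reads], locus, vector)
print(summarize_amplicon(outcomes, locus).capture_ratio)
```

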