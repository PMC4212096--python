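# rrhp

Toolkit for **reduced representation 5-hydroxymethylcytosine profiling (RRHP)** —
a positive-display sequencing assay that maps 5hmC at single-CpG, strand-specific
resolution.

## The assay and what this package computes

Genomic DNA is digested with MspI, which cuts C^CGG regardless of CpG methylation
state. Fragments are ligated to modified adapters so that the CCGG site is
reconstituted only at the P5 adapter–fragment junction. 5hmC in the library is then
glucosylated with β-glucosyltransferase (β-GT), and the library is digested a second
time: MspI re-cleaves every junction **except** those carrying glucosyl-5hmC, so only
fragments with 5hmC at the junction keep both adapters and amplify. Every sequenced
read beginning with the CCGG tag therefore reports one 5hmC event at one junction on
one strand — a positive display with no subtractive second library. Substituting
HpaII (blocked by 5mC, 5hmC, or glucosyl-5hmC) in the second digestion reports any
junction methylation instead.

The package implements the computational side of this workflow:

- **`rrhp.digest`** — in silico MspI digestion of any FASTA genome, fragment size
  selection (default 40–430 bp insert window), and the catalog of *detectable*
  junction sites: a CCGG at position *p* is forward-detectable if a retained
  fragment starts at its cut (interrogating the CpG cytosine at *p*+1) and
  reverse-detectable if one ends there (cytosine at *p*+2).
- **`rrhp.simulate`** — a molecule-level simulator of the library chemistry
  (adapter orientation, junction cytosine state, β-GT on/off, MspI vs HpaII second
  digestion, incomplete digestion, PCR duplication, sequencing error) that emits
  FASTQ plus a ground-truth table, so the whole downstream stack is testable
  without any external data.
- **`rrhp.profiler`** — the core measurement: count reads with a CCGG tag at the
  5′ end, per site and strand, from SAM/BAM alignments or via a built-in exact
  junction matcher; library summary statistics (mappability %, tagged %, sites).
- **`rrhp.qc`** — coverage histograms, replicate Pearson correlation and site
  overlap, strand-asymmetry screening at a fold threshold, and paired differential
  ranking.
- **`rrhp.calibrate`** — false-call calibration against RRBS: over the N CpG sites
  that bisulfite data shows deeply covered (>50×) and unmethylated, the error rate
  at read cutoff *i* is E_i = N_i / N with N_i the sites showing ≥ *i* display
  reads; plus the glucMS-qPCR quantitation
  `5hmC% = 100 · (Ct₍dig−₎ − Ct₍dig+₎) / (Ct₍dig−₎ − Ct₍intact₎)`
  and annotation-category overlap tables.

## Worked example

Simulate a small study end to end (a 50 kb genome with ~350 CCGG sites):

```sh
python -c "
from rrhp import make_genome, make_profile, detectable_sites, digest, size_select
from rrhp.io import write_fasta
g = make_genome(1, 50_000, 150, seed=11)
write_fasta(g, 'genome.fa')
sites = detectable_sites(size_select(digest(g), 40, 430))
make_profile(sites, hmc_beta_params=(2,5), zero_hmc_fraction=0.3, seed=12).to_tsv('profile.tsv')
"
rrhp digest   --fasta genome.fa --out-fragments frags.bed --out-sites sites.bed
rrhp simulate --fasta genome.fa --profile profile.tsv --molecules 50 --seed 1 \
              --out reads.fq --truth truth.tsv
rrhp profile  --fastq reads.fq --fasta genome.fa --sites sites.bed \
              --out counts.tsv --summary summary.json
rrhp asymmetry --counts counts.tsv --out asym.tsv
```

which prints:

```
INFO contigs: 1
INFO CCGG sites: 350
INFO retained fragments (40-430 bp): 263
INFO detectable sites: 328
INFO emitted 1366 reads over 525 (site, strand) pairs
INFO reads: 1366 total, 100.00% mapped, 100.00% of mapped tagged, 254 sites
INFO 254 sites, 197 flagged at fold 2.0
```

350 CCGG sites exist in the genome; 328 of them border at least one fragment in the
40–430 bp window, so only those are interrogable by the assay. The simulated
library carries 5hmC drawn from a Beta(2,5) mixture with a 30% zero-5hmC point
mass; 1,366 reads are emitted across the 525 detectable (site, strand) pairs, all
of which map through the built-in junction matcher and carry the CCGG tag (the
simulation used no sequencing error). 254 sites receive at least one read — sites
with zero or low 5hmC at both strands can emit nothing at this depth — and 197
show a ≥2-fold read-count difference between strands. `counts.tsv` holds the
per-site strand-split counts:

```
contig	pos	fwd_reads	rev_reads	total
contig1	547	5	0	5
contig1	810	2	1	3
contig1	857	0	7	7
```

`rrhp compare`, `rrhp calibrate` and `rrhp qpcr` consume these tables for
replicate comparison, RRBS-anchored error calibration, and glucMS-qPCR
quantitation; the same functionality is available as library calls
(see `docs/methods.md`).

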