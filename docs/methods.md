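# Methods

## The measurement model

The assay is a positive display: a sequencing read exists only because a specific
CpG cytosine at a specific MspI junction carried glucosyl-5hmC through the second
digestion. The package therefore treats the *junction*, not the read, as the unit
of measurement. A CCGG occurrence at 0-based position *p* of the top strand defines
two potentially observable half-sites: the forward-strand CpG cytosine at *p*+1,
reported by reads that start at *p* on the + strand, and the reverse-strand
cytosine at *p*+2, reported by − strand reads whose rightmost aligned base is
*p*+3. The cut coordinate is *p*+1 (between C and CGG); fragment lengths are
measured between consecutive top-strand cut coordinates so that fragments tile
each contig exactly and each fragment has a single unambiguous length. The 2-nt
5′-CG overhang is not double-counted; its only operational consequence is that the
sequenced bottom strand of a fragment stops two bases short of the far cut, which
the read constructor and the junction matcher both respect.

A site is **detectable** only if a size-selected fragment borders it on the
relevant side. Contig boundaries carry no reconstituted junction, so fragments
touching a contig end contribute no detectable site there. The default insert
window is 40–430 bp: the laboratory protocol gel-selects adapter-ligated material
at 110–500 bp, and the ~70 bp of adapter sequence maps that window into insert
space. All size selection in this package operates in insert space.

## Simulator

`simulate_library` models one library preparation per molecule:

1. Each retained fragment spawns `n_molecules_per_fragment` ligation events.
   A molecule is hetero-adapterized with probability `hetero_adapter_prob`
   (default 0.5 — two adapter species at equal molarity; the protocol does not
   pin this number, so it is exposed). Homo-adapterized molecules hairpin and are
   silently lost. The end carrying the junction-reconstituting adapter is uniform
   between the two fragment ends; a boundary end yields nothing.
2. The junction cytosine state (5hmC / 5mC / unmodified) is drawn once per
   molecule from the ground-truth profile at that (site, strand). Internal CpGs
   never matter — only the junction is re-cut — and are emitted as unmodified
   sequence.
3. Second digestion: MspI destroys the molecule unless the junction is
   glucosyl-5hmC (i.e. 5hmC *and* β-GT applied); HpaII destroys it unless the
   junction is 5mC or 5hmC (glucosylated or not). A cleavable molecule escapes
   with probability `digestion_failure_rate`. The escape uniform is drawn for
   *every* molecule, whether needed or not, so the random stream is identical
   across enzyme settings; `enumerate_molecules` + `apply_second_digestion`
   exposes this split, which is what makes the enzyme-nesting property
   (MspI+β-GT survivors ⊆ HpaII survivors on the same draws) checkable
   molecule-by-molecule.
4. Survivors are duplicated with a shifted-geometric copy number on {1, 2, …}
   with mean `pcr_duplicate_mean` (numpy's `geometric(p=1/mean)`): the simplest
   seed-stable family with support starting at one copy and a controllable mean.
5. Each copy emits one read: the reconstituted CCGG followed by the fragment
   sequence from the junction, on the junction's strand, truncated at
   `read_length`, with independent per-base substitution errors at
   `seq_error_rate`. Quality strings are a constant placeholder; quality modeling
   is out of scope. Read names encode (contig, site, strand, molecule, copy) so
   every downstream stage can be validated against the truth table.

All draws come from one `numpy.random.Generator` seeded from the config, making
FASTQ and truth output byte-identical across reruns.

### Synthetic data defaults, and what they do not emulate

`make_genome` plants non-overlapping CCGG motifs at jittered regular spacing in a
uniform-random background, guaranteeing the target site count; `make_profile`
draws per-(site, strand) 5hmC fractions from Beta(2, 5) (right-skewed, mean ≈ 0.29
— most sites carry modest 5hmC, matching the observed dominance of low-coverage
sites) with an optional point mass of exactly-zero sites, and 5mC from Beta(2, 2),
clipped so the fractions sum to at most 1.

The generator deliberately holds per-site molecule depth constant
(`n_molecules_per_fragment` is a single number). Real libraries have
order-of-magnitude per-site depth heterogeneity from amplification and coverage
effects. One observed consequence: in real replicate data the Pearson correlation
*rises* as low-count sites are excluded, because the low-count stratum is
noise-dominated; in this simulator the same filter mostly truncates the signal's
dynamic range, and the correlation falls instead. Tests therefore assert the
depth property that does transfer — replicate pairs correlate better at higher
molecule depth — rather than the cutoff trend. Passing tests demonstrate the
correctness of the chemistry logic and the counting/calibration arithmetic, not
the count distributions of real libraries.

## Counting rules

The tag check is an exact, case-insensitive 4-mer match at the read's 5′ end; a
sequencing error inside the tag drops the read (conservative — in practice some
tagged reads are always lost, and the tagged percentage sits below 100). SAM −
strand records store the reverse complement of the sequenced read, so the tag is
checked in sequencing orientation. Tagged reads that do not start at a cataloged
junction are tallied separately (`off_junction_reads`) and excluded from site
counts. PCR duplicates are intentionally counted — read number is the display
signal. Multi-mapped/ambiguous reads are unmapped in the built-in matcher, which
requires a unique junction agreeing with the read over its full length within
`max_mismatches` substitutions.

## Calibration

The error table reads "at least *i*": N_i counts qualifying sites with display
total ≥ *i*, which is the reading under which error rates are monotone
non-increasing in the cutoff. "Greater than 50×" bisulfite coverage is strict
(`coverage > min_coverage`), parameterized. A bisulfite CpG position is matched to
a CCGG site by membership of its cytosine in the 4-mer: position *p* matches a
site at *p*−1 (forward CpG) or *p*−2 (reverse CpG). The potential-site universe
should be the detectable-site catalog — qualifying unmethylated sites typically
have zero display reads and would be invisible in the count table alone; the
catalog argument exists for exactly this reason.

`glucms_percent` evaluates
100 · (Ct₍dig−₎ − Ct₍dig+₎) / (Ct₍dig−₎ − Ct₍intact₎); it is invariant under a
common shift of all three Ct values. Ct noise can push the ratio outside
[0, 100], so the clamped value is returned together with the raw one, and a
mock-digested Ct below the intact Ct is flagged (digestion should remove
template) but not fatal.

## Replicate statistics

Correlation is computed on per-site total counts over the union of detected sites
(absent = 0) by default, with a binary presence/absence option; count scatter is
what replicate concordance plots show, so counts are the default. When
`min_count` > 0, sites below it in *both* libraries are excluded. Strand
asymmetry reports log2((fwd + 1)/(rev + 1)) — the pseudocount only stabilizes the
ratio — while the flag applies the fold threshold to raw counts (a zero weaker
strand flags when the stronger reaches the threshold), so the two-fold criterion
is exact. The paired differential ranking is a plain absolute difference of raw
counts with (contig, pos) tie-breaks: read totals in a positive display reflect
5hmC abundance as well as depth, global normalization is not meaningful across
samples, and no significance test is fabricated. Callers are responsible for
comparable sequencing depth.

## Numerical and degenerate-input choices

- Overlapping CCGG motifs each cut; an N anywhere in the 4-mer disables the site.
- Empty genomes, inverted size ranges, empty fragment catalogs, a zero qPCR
  denominator, and an empty calibration universe raise `ValueError`; an empty
  read stream yields an all-zero summary, and unassignable reads are values, not
  errors.
- Correlation with fewer than two sites or zero variance returns NaN rather than
  raising; the Venn/threshold logic treats detection as total ≥ max(1, min_count).
- Profile fractions are validated on the simplex with a 1e-9 tolerance and
  re-clipped at the boundary, so TSV round trips (10 significant digits) are
  stable.
- The acceptance script's study scale — a 100 kb single-contig genome with ~300
  planted sites, 30–1000 molecules per fragment depending on the check — keeps
  every Monte-Carlo comparison well-powered (hundreds of sites, ≥10⁴ molecules)
  while running in seconds.

## Known limitations

Single-end reads only; no indels, adapter read-through, gel-mobility or
molarity modeling; no bisulfite read processing (methylation calls are consumed,
not produced); no peak calling or enrichment analysis; the built-in junction
matcher assumes junction-anchored reads and is not a general aligner.
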