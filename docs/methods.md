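# Methods

This note documents the statistical model behind `bulkscan`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that affect results.

## The scan model

A QTL-seq experiment contrasts two DNA bulks of n extreme F2 individuals
sequenced against the genome of one parent (here n = 15, with the *high*
bulk defined as the one matching the reference parent's trait state). At a
biallelic SNP with read counts (ref, alt) per bulk, the SNP-index is
alt/(ref+alt) and Δ = index_high − index_low. The analysis proceeds
per-site → windows → regions:

1. **Site filters.** A site is removed when read depth < `min_depth` (7) in
   either bulk, or when the index is < `min_index` (0.3) in *both* bulks
   (the spurious-SNP rule: a variant supported by a minority of reads in
   both pools is likely an alignment artifact). For causal-SNP calling a
   third filter requires both bulks to be homozygous: index ≤ 0.1 (hom-ref)
   or ≥ 0.9 (hom-alt). All three flags are computed independently of each
   other, so their order of application cannot change the outcome; records
   are flagged, never mutated or silently dropped.

   Two deliberate interpretations are built in, each with a "literal"
   alternative behind a flag. Requiring adequate depth in *both* bulks is
   the stricter and standard convention (`depth_rule="either"` removes a
   site thin in either bulk); `depth_rule="both"` keeps one-sided thin
   sites. Conversely the low-index rule defaults to *both* bulks
   (`index_rule="both"`), because removing any site with index < 0.3 in
   just one bulk would delete every Δ = −1 site — exactly the sites the
   method exists to find; `index_rule="either"` reproduces that literal
   reading for comparison.

2. **Causal flags.** Candidate causal SNPs are filtered sites with
   Δ = −1 exactly (index 0 in the high bulk, 1 in the low bulk: the high
   bulk carries only reference-parent alleles while the low bulk is fixed
   for the other parent). `criterion="abs"` or a magnitude threshold are
   available for designs where the sign convention is unknown.

3. **Windows.** Sliding windows (default 1 Mb, step 10 kb — the typical
   QTL-seq plotting scale; the window parameters are conventions, not
   estimates) average index_high, index_low and Δ over member SNPs.
   Windows average the sites passing the depth and low-index filters; the
   homozygosity filter gates only causal-SNP calls, since genome-wide index
   tracks necessarily include heterozygous bulk sites (most unlinked F2
   sites are heterozygous in a 15-plant pool).

4. **Null bands.** Under no-QTL, each of the 2n gamete-derived alleles in a
   bulk is either parent's with probability ½, so the bulk allele frequency
   is Binomial(2n, ½)/2n — equivalently, individual contributions 0, ½, 1
   with probabilities ¼, ½, ¼ — and the read-level index is
   Binomial(depth, f)/depth. Monte-Carlo replicates of this two-stage draw
   (default `n_reps` = 10,000 per distinct depth pair, cached and seeded by
   the pair so results are independent of query order), with replicates
   failing the low-index filter redrawn to match the observed record set,
   yield the empirical (α/2, 1−α/2) bands at α = 0.05 and 0.01. Depth is a
   parameter of the band, so no depth-filter redraw arises. Band width
   shrinks with depth (read-sampling noise vanishes; bulk-sampling noise
   does not), which the tests check as a monotonicity property.

5. **Regions.** A window is significant when its mean Δ escapes the band
   evaluated at the window's median bulk depths (median: robust to the
   within-window depth spread). Significant windows on one chromosome
   separated by at most one step merge; the region spans the outermost
   window edges and is reported in Mb to two decimals, with its causal-SNP
   census attached.

**Calibration caveat (by construction).** The band is the null distribution
of a *single-site* Δ. A window averaging k sites has smaller read-noise
variance than one site (linked sites share the bulk allele frequency but
not the read noise), so at realistic depths window-level exceedance under
the null is *conservative* — well below α for k ≫ 1, approaching α as
k → 1. The coverage test therefore uses genomes with one marker per
non-overlapping window, where the nominal rate applies exactly; the
companion property is that dense-marker null genomes rarely yield any
region at all. This conservativeness is shared with the standard QTL-seq
procedure, not introduced here.

## Pseudo-reference

Bulk reads are scored against the sequenced parent. Given the public
reference and the parent's variant calls, `pseudoref` substitutes the
parent's confident homozygous SNP alleles into the reference. "Confident"
is not standardised anywhere we could adopt it from, so the defaults mirror
the bulk-side depth filter: depth ≥ 7 and alt fraction ≥ 0.9 (or genotype
1/1), SNPs only; both thresholds configurable. Substitutions whose stated
reference base does not match the sequence are rejected and reported, never
applied — which also makes re-application of an already-applied set fail
loudly for every record (an idempotence guard the tests rely on). Output
FASTA is uppercase, 60 columns, input order preserved; indels are out of
scope throughout the package.

## Effect annotation

Gene models are read from GFF3; only the canonical (first) transcript per
gene is used. A SNP is exon if inside any exon of an overlapping gene,
intron if inside the gene span otherwise, intergenic else; overlapping
genes are all reported with the first by sorted id (exon hits preferred) as
primary. For CDS positions the spliced CDS is assembled, minus-strand genes
reverse-complemented (and the alternate base complemented), the affected
codon substituted, and both codons translated with the standard nuclear
code; the variant base is upper-cased inside the reported codon (aCg →
aTg). Same amino acid ⇒ sSNP, different ⇒ nsSNP; UTR-exon, intron and
intergenic positions are "non-coding", and a partial terminal codon defers
to "non-coding" with a warning. The test oracle is independent: mutate the
chromosome, re-splice, re-translate the whole protein and compare.

## The synthetic generator

`simulate` emulates the statistical structure the scan assumes, with
defaults set to the motivating study design (`study_config`):

| parameter | default | rationale |
|---|---|---|
| n_individuals | 179 | F2 population size |
| bulk_size | 15 | extreme-bulk size |
| mean_depth | 14 reads | per-bulk sequencing depth (reported 13.4–15.1×) |
| DF additive effect | 19 days | half the 105 − 67 day parental difference |
| DF baseline | 86 days | midparent |
| trait_noise_sd | 14 days | single-QTL PVE ≈ 48%, the size of the major reported flowering QTL |
| leaf locus | recessive | obcordate iff dosage 2; 3:1 F2 segregation |
| seq_error_rate | 0.001 | typical Illumina substitution rate |

Genotypes: each individual is two independent F1 gametes; gamete alleles
follow a Markov chain along the chromosome with inter-marker recombination
r = ½(1 − e^(−2d)) (Haldane, no interference — the minimal standard choice
absent a stated map function). Dosage counts reference-parent alleles and
segregates 1:2:1. Phenotypes: baseline + additive·(dosage−1) +
dominance·[dosage=1] + Gaussian noise; the Mendelian class trait is
noiseless by default with a configurable misclassification probability.
Bulks contribute equal DNA per individual (the equimolar-pooling protocol;
a pooled-volume noise model is deliberately not default), so the bulk
alternate-allele frequency is 1 − Σdosage/(2n); depth is Poisson (a
fixed-depth mode exists for exact oracle tests) and alternate reads are
Binomial(depth, f(1−e) + (1−f)e) with symmetric two-allele error folding —
no third allele, no indels.

Not emulated: read-level artifacts (mapping bias, duplicates, indel
misalignment), linked-marker ascertainment, multi-allelic sites,
environment-dependent phenotyping error, segregation distortion. Passing
tests therefore demonstrate correctness of the statistics under the model's
assumptions, not robustness to alignment pathology; on real data the depth
and low-index filters carry that burden.

Marker maps are evenly spaced per chromosome with the marker nearest each
declared QTL snapped onto the causal position, so truth records always
reference an existing marker. Every dataset is written with a ground-truth
JSON (trait, causal position, effects, bulk membership) for recovery tests.

## Determinism and seeds

All randomness flows through `numpy.random.Generator`. `SimConfig.seed`
fully determines a dataset (byte-identical files on re-run). The pipeline's
run seed fans out to per-stage child seeds via `SeedSequence([seed,
crc32(stage_name)])`, isolating stages from each other; null-band draws are
additionally keyed by the depth pair. Output TSV/BED files declare their
coordinate convention in a header comment; positions are 1-based inclusive
everywhere except BED (0-based half-open).

## Test problem sizes

The statistical suites use desk-scale designs chosen for adequate power:
segregation and dosage checks at 1,200–3,000 individuals (3–3.5 binomial
SEs), PVE recovery at n = 2,000 (±5 pp), exact null enumeration at bulk
size 2 / depth 2 (where the full multinomial × binomial lattice is
enumerable) against 10⁵ Monte-Carlo draws, planted-QTL recovery over 100
seeded replicates of the full 179-individual design, and null coverage over
30 single-marker-per-window genomes (≈750 effectively independent windows,
binomial SE ≈ 0.8 pp against the ±2 pp acceptance band).

## Known limitations

- The Δ = −1 causal criterion is exact by design; at modest depth a truly
  causal site can miss it through a single stray read (it remains inside
  the called region; the criterion is a flag, not the region test).
- Null bands condition on depth but not on the marker ascertainment of real
  variant callers.
- Sparse simulated marker maps give wide candidate regions; region width is
  a function of marker density and selection intensity, not of the band.
- The annotation module handles SNP codon changes only — no splice-site,
  frameshift or regulatory classification.
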