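# Methods

## Scope and data model

The package analyses two-condition (0 h = nitrogen sufficiency, 72 h =
nitrogen limitation) epigenomic data at desk scale: one whole-genome
bisulfite library per condition, a replicated small-RNA count matrix, and
degradome 5′-end tag profiles. Inputs are plain text: FASTA genomes and
transcript/miRNA sets, Bismark-CX-style per-cytosine reports (chrom, pos,
strand, methylated count, unmethylated count, context, trinucleotide),
tab-separated gene models with exon structure, and long-format degradome
tables. All genomic coordinates are 1-based inclusive, so a region's
length is end − start + 1; BED/BEDGraph exports convert to 0-based
half-open on the way out and say so.

## Methylation model

A cytosine's context is decided by the two bases downstream on its own
strand: CG, then CHG, then CHH (H ∈ {A, T, C}). Both strands are called
independently; CG sites are *not* merged across strands, so each strand's
cytosine is its own observation in every statistic. Cytosines whose
downstream dinucleotide runs off the chromosome or contains N are dropped
and logged. Methylation level is ML = mC/(mC + umC), defined only when
coverage reaches `min_coverage` (default 3 reads). The package exposes
the threshold as a parameter because published summaries of comparable
data quote both three- and five-read filters; the default follows the
analysis filter, not the sequencing-quality summary. The bisulfite
non-conversion rate is the pooled Σ mC/Σ(mC + umC) over the unmethylated
lambda spike-in contig (`lambda_control`), with no coverage filter —
every read contributes evidence about conversion chemistry.

## DMR procedure

Differential sites require the coverage filter in *both* conditions
(fold change needs both levels). The site fold change is
(ML₇₂ₕ + p)/(ML₀ₕ + p) with pseudocount p = 0.01 to keep zero
denominators finite; the 1.2-fold threshold is applied two-sided
(>1.2 or <1/1.2) because both hyper- and hypomethylation are reported
downstream. Testing tiles the genome into fixed 100-bp bins per context,
keeping bins with ≥5 jointly covered sites. The choice of 100 bp is this
package's: reported DMR lengths in this system are mostly under 100–200
nt, which a 50-kb unit (used only for density/level tracks) could never
produce; both bin size and the site minimum are configurable. Within a
bin, the per-site levels of the two conditions form the two groups of a
tie-corrected Kruskal–Wallis test (scipy's implementation; χ² with 1 df).
With a single library per condition this treats sites within a bin as
exchangeable replicates of the local methylation state — the test detects
a consistent shift of the within-bin level distribution, not biological
replication, and that limitation is inherent to the design. A bin whose
values are all identical carries no rank information and is assigned
p = 1. Benjamini–Hochberg adjustment is applied within each context
family separately, because per-context DMR counts are the quantity of
interest. DMRs require q < 0.05 and ≥3 differential sites in the majority
direction (default); their boundaries are trimmed to the first/last
differential site, which is what yields sub-bin lengths such as 56–183 bp.
Direction is assigned from the mean levels — hyper when methylation is
higher under limitation — and the package's validator applies the same
rule to the bundled reference table of DMRs at nitrogen-metabolism genes,
surfacing the one row whose printed label contradicts its own levels
rather than silently correcting it.

## Gene annotation and metaplots

Functional regions are strand-aware: the 2.0-kb promoter abuts the TSS on
the gene's 5′ side (above the gene end for minus-strand genes), the
2.0-kb downstream flank mirrors it, introns are the body minus the exons,
and regions are clipped at chromosome edges with a warning. TSS/TES are
the strand-aware ends of the gene interval; no isoforms. A DMG needs ≥1 bp
overlap between a DMR and the promoter or body; a DMR spanning both is
reported once with kind "promoter+body". Because a gene can carry hyper-
and hypomethylated DMRs simultaneously, DMG counts are reported in both
conventions: per-direction gene counts (a dual-direction gene counts
twice) and the number of distinct genes. Metaplots divide each region
into exactly 20 bins on fractional coordinates (all bins equal width to
within one base), pool covered site levels over genes per context and
condition, orient every profile 5′→3′, and skip regions shorter than the
bin count.

## miRNA differential expression

TPM is count/total × 10⁶ per sample with no length correction (tags, not
fragments, are counted). The DE decision rule is exactly the published
thresholds: BH-adjusted p ≤ 0.05 and |log₂ fold change| ≥ 0.60 on group
mean TPM with a 1-TPM pseudocount. The p-value engine is a two-sided
moderated t-test on log₂(TPM + 1) replicate values: the pooled per-miRNA
variance (4 residual df at n = 3 per group) is shrunk toward the
across-miRNA mean variance with 10 prior df, and the statistic is
referred to t₁₄. Moderation is required, not cosmetic: with three
replicates a raw per-miRNA variance estimate is so unstable that a plain
Welch test recovers well under half of fourfold planted effects after BH
correction, while the moderated test recovers ≈94% and remains
conservative under the null (observed raw P(p < 0.05) ≈ 0.03 across
expression levels spanning 3–3000 counts). On the log₂(TPM+1) scale
negative-binomial noise is close to homoskedastic for moderately
expressed miRNAs, which is what makes the shared prior informative.
Power simulations plant effects in 20% of the population, mirroring the
substantial differentially expressed fraction this response elicits;
with a handful of non-null miRNAs among hundreds the BH threshold is
necessarily far stricter and recovery of individual effects at n = 3
drops for any count-level test.

## Degradome analysis

Duplexes are ungapped and antiparallel (validated duplexes in this system
are bulge-free; bulges are out of scope). The score table is: Watson-Crick
0, G:U wobble 0.5, any other pair 1.0 per position — the wobble penalty is
the published value, the mismatch cost of 1.0 is this package's declared
convention, applied identically in the implementation and the test
oracle. Windows up to score 4.5 (configurable) are candidates. The
cleavage coordinate is the target base paired to miRNA nucleotide 10 from
the 5′ end, where plant AGO slicing occurs. Hits are categorized solely
by how the degradome read count at the cleavage position ranks within the
transcript's profile: 0 = >1 read and unique maximum, 1 = tied maximum,
2 = above the median but below the maximum, 3 = at or below the median,
4 = exactly one read; no reads, no hit. The 0–4 scheme is a declared
convention consistent with the "single obvious peak" presentation of
validated targets, not a published table.

## Synthetic-data generator

The generator emulates the study conditions and is the ground truth for
every recovery test. Defaults: Poisson coverage with mean 30 (the study's
sequencing depth); context mean levels CG 0.55 > CHG 0.25 > CHH 0.10 and
an A_n subgenome sitting 0.05 below C_n, reproducing the published
ordering and subgenome asymmetry at magnitudes typical for *Brassica*;
beta-binomial methylated counts with overdispersion ρ = 0.05 (the source
analysis states no noise model; overdispersion keeps the rank test's job
nontrivial); a 2-kb `lambda_control` contig drawn binomially at a 0.5%
non-conversion rate; planted DMRs as additive level shifts applied in the
72 h condition only; negative-binomial miRNA counts (var = m + 0.1·m²) in
three replicates with planted log₂ effects and a 0.6 first-base bias
toward U; transcripts with implanted target sites (reverse complement of
the miRNA, perturbed into a requested number of wobbles and mismatches
away from the position-10 core) and degradome profiles of uniform 0–2
background reads plus the planted peak opposite miRNA nucleotide 10.
One WGBS library per condition matches the apparent study design;
replicated methylomes can be produced by reseeding but are not modelled
with library effects. All randomness derives from a single seed through
fixed per-stage streams, so a fixed seed yields byte-identical files.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: read-level artifacts (mapping bias,
M-bias, incomplete conversion gradients), spatial autocorrelation of
methylation beyond planted intervals, transposable-element structure,
linked miRNA families sharing precursors, and compositional coupling
between many simultaneously changing miRNAs beyond what TPM renormalizes.

## Simulation sizes and numerical choices

Null error-control runs use 20 seeds × one 25-kb chromosome
(≈15,000 tested bins); DMR power runs plant 100 CG DMRs of 450 bp
(≈56 CG sites each at random base composition) as 10 per 60-kb
chromosome across 10 seeds; miRNA power runs use 25 simulations of 100
miRNAs. These sizes give stable Monte-Carlo estimates while keeping the
full suite fast on a single CPU. Ties in the rank test use average ranks
with the standard tie correction; BH is the step-up procedure with the
original order restored; fractional metaplot bins break boundary ties
toward the lower bin, and the final bin absorbs the right edge.
Multi-reference qPCR normalization combines reference-gene CT values by
geometric mean before forming ΔCT (with CT values in the usual 15–30
cycle range the difference from an arithmetic mean is negligible).

## Known limitations

* One library per condition: the bin test measures within-bin
  consistency, not biological reproducibility; its p-values are exact
  only asymptotically and small bins (<5 sites) are excluded rather than
  tested exactly.
* The DE engine is a replicate-level moderated t on transformed TPM, not
  a count-model likelihood; it matches the published decision thresholds
  but not any specific package's p-values.
* Degradome categories rank a single profile; no cross-library abundance
  normalization or closed-form p-value for peak enrichment is attempted.
* Weak planted effects (e.g. |Δ| = 0.15 in CHG) sit near the power
  boundary of the default bin test — by design the package reports them
  honestly rather than tuning thresholds per context.
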