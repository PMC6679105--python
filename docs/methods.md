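# Methods

## Data model

A methylome series holds, for every cytosine site (sequence, 0-based
position, strand, context), the pair (methylated calls, total calls) at
each of T sampling dates. Sites are never merged across strands: the CG
dinucleotide is symmetric, but each cytosine is kept as an independent
analysis unit, matching a per-cytosine testing design. Context (CG, CHG,
CHH; H = A, C or T) is read from the two bases downstream of the cytosine
on its own strand; a 3-mer that runs off the sequence or contains an
ambiguity base leaves the site context-less and excluded from all
analyses. Missing coverage at a (site, date) is stored as (0, 0) and
handled by coverage filters downstream, never imputed.

All internal coordinates are 0-based half-open; the 1-based dialects
(per-cytosine count reports, GFF3) are converted at the I/O boundary.
This keeps interval arithmetic uniform (window tiling, exon/gene/repeat
overlap) at the cost of one conversion per read/write.

## SeMC detection

The definition is: a cytosine differentially methylated between at least
two sampling dates. It is operationalised as the minimum over all C(T, 2)
date pairs of the two-sided Fisher exact p-value on the 2×2 table of
(methylated, unmethylated) counts. The two-sided p sums hypergeometric
probabilities ≤ the observed table's probability, with a 1e-7 relative
tolerance for ties (the convention shared by the mainstream
implementations); the tail sum is evaluated from a cached log-factorial
table so that millions of tables (28 pairs × genome-scale sites) run in
seconds, and it is checked in the test suite against exhaustive exact
enumeration for all tables of total size ≤ 40.

A date enters testing only when its total coverage is ≥ `min_cov`
(default 5 calls): Fisher tests on near-zero counts are uninformative and
would only inflate the tested-site count. A site with no testable pair is
excluded, not assigned p = 1.

False-discovery control uses Storey q-values per context: π̂₀(λ) =
#{p > λ}/(m(1 − λ)) on λ = 0.05, 0.10, …, 0.95, a cubic polynomial
smoother read off at λ = 0.95, clipped to (0, 1] (held at 1 below 50
p-values, where the estimate is unstable); q_(i) = π̂₀·m·p_(i)/i with the
cumulative minimum enforced from the largest p downward. A site is called
when p < `alpha` (default 0.001) and q < `fdr_max` (default 0.2) — the
reference thresholds of the pipeline.

**Calibration caveat (important).** Under the null, the minimum of 28
correlated pairwise p-values is stochastically far smaller than uniform,
so feeding p_min directly into Storey estimation drives π̂₀ toward 0 and
the q-values toward 0: the literal pipeline over-calls. This is inherent
to the definition, not an implementation artifact. The package therefore
offers `sidak=True`, which first maps p′ = 1 − (1 − p_min)^k (k = number
of tested pairs). Because the pairs are positively dependent and the
Fisher null is discrete, p′ is conservative, π̂₀ is estimated near 1, and
the planted-truth simulations in the test suite show empirical FDR well
inside the nominal 0.2. The uncorrected minimum remains the default for
fidelity to the original definition; calibration-sensitive analyses
should switch the flag. An omnibus likelihood-ratio G-test on the full
2×T table (df = covered dates − 1) is available as `method="gtest"` for a
single-test alternative.

Peak timing is the date of the maximum raw per-date ratio (no smoothing);
exact ties go to the earliest date and are flagged. Location classes use
the precedence exon > intron > intergenic for overlapping annotations.
Seasonal-profile clustering is average-linkage agglomeration on the
distance 1 − r (Pearson correlation between per-date ratio rows);
zero-variance rows, whose correlation is undefined, sit at distance 1
from everything. The dendrogram is exported as Newick with branch lengths
equal to merge-height differences; above `max_cluster_rows` (default
2000) calls, a deterministic subsample is clustered, since the condensed
distance matrix grows quadratically.

## Profiles

Every regional level is the pooled ratio Σm/Σ(m+u), so the level of a
union of regions is the call-weighted mean of the regional levels and a
region with zero coverage has an undefined (NaN) level, never 0. Windows
tile each sequence as [kw, (k+1)w) with the last window truncated; a site
belongs to the single window containing its position (sites are conserved
exactly), while repeats contribute base pairs to every window they
overlap, after merging overlapping repeat annotations. Repeat families
are parsed verbatim from the BED name column as "Class/Family" strings.
The gene-vs-repeat comparison assigns sites inside both a gene and a
repeat (intragenic repeat islands) to the repeat class only. The
bisulfite conversion rate is 1 − pooled level on the spike-in contig per
date; values above 0.99 indicate efficient conversion.

## gbM and expression stability

gbM is the pooled CG level over the full annotated gene span — introns
included, because intragenic heterochromatin is part of the locus as
browsed — averaged across dates with coverage; an exon-only mode is a
flag. Per-date gene levels are also emitted so the across-date spread (a
stability check) can be inspected directly.

The seasonal summary of expression (log2(RPM+1), required ≥ 0) is the
arithmetic mean across dates and the range max − min of a centred moving
average of width `smooth_window` (default 3, truncated at the series
edges; width 1 disables smoothing). The smoothed range is a pragmatic
stand-in for a published-elsewhere seasonal-range method: robust to a
single noisy date, and reducing to the obvious definition at width 1.

Expressed genes (average > 1) are ranked by gbM and cut at the
20/40/60/80th percentiles; boundary ties fall to the lower bin; an
all-identical gbM vector makes quintiles undefined and is an error, not
an arbitrary split. Pairwise two-sided Mann–Whitney tests (exact for
small tie-free groups via scipy's auto rule; a fully degenerate pair is
p = 1) are Holm-adjusted — valid under arbitrary dependence; Bonferroni
and Benjamini–Hochberg are options. The compact letter display assigns
the maximal cliques of the non-significance graph as letters, so two bins
share a letter exactly when they are not significantly different. The
monotone-trend summary is the gene-level Spearman correlation between gbM
and seasonal range.

## The synthetic generator

The generator emulates the statistical structure of a year-round
bisulfite study of a clonal perennial: 8 sampling dates at ~1.5-month
intervals (2014-11-11 … 2015-09-08), context baselines CG 0.45 /
CHG 0.20 / CHH 0.06, alternating repeat-dense (60% repeat bp) and genic
(5%) blocks of 25 kb, an additive repeat methylation boost per context
(defaults 0.35/0.35/0.15, putting repeat CG near 0.8), genes of 1.5–3 kb
with 2–6 exons placed outside repeats, a fully unmethylated spike-in
contig, and a per-call conversion failure of 0.005 (an unmethylated call
reads methylated), so the measured conversion rate sits near 99.5%.

Counts are depth ~ Poisson(`coverage_mean`, default 20) and methylated
calls ~ Binomial(depth, p) — the model under which the pairwise Fisher
test is exactly calibrated, which is what makes the type-I-error and FDR
recovery tests meaningful. On top of the additive level model, a
log-normal regional multiplier (σ = 0.25 per 5-kb segment, mean 1,
constant across dates) varies the landscape at the window scale the way
real methylomes do; being time-constant, it leaves the within-site
date comparisons of the caller untouched. Gene-body CG sites take their
gene's planted gbM level exactly (drawn Uniform(0, 0.9)), bypassing the
regional multiplier, so planted values are recoverable estimands.

SeMC sites (fraction `semc_fraction`, default 0.005 — a minority, as in
the emulated setting) add a seasonal bump A·exp(κ(cos Δθ − 1)) on the
circle of the year, peaking at a date drawn from the sampling dates
(A = `semc_amplitude`, default 0.4; κ = `peak_sharpness`, default 4,
chosen so the bump falls to ≈ 0.35 one sampling interval from the peak —
adjacent dates stay distinguishable at realistic coverage). Planting is
restricted to sites whose stable level is ≤ 1 − A, so seasonal curves
never clip and every planted site has a unique maximum at its peak date
by construction. Placement can be restricted by context and to
(intergenic) repeats to emulate repeat-borne CHH seasonality.

Expression is simulated per gene as mean(g) + A(g)·cos(θ − phase) +
noise, clipped at 0, with A(g) = 2·max(0, 1 − coupling·g) decreasing in
gbM (coupling default 1), mean(g) = 2 + 1.5g weakly increasing, phase
uniform per gene, and Gaussian noise σ = 0.3. By default expression is
evaluated at the 8 bisulfite dates so that methylation and expression
series share a date grid (the feature-association precondition); a
denser grid is a config override. The truth table stores the noiseless
seasonal average and range.

What the generator does *not* emulate: read-level bisulfite errors and
mapping bias, biological replicates, linkage between neighbouring sites
(sites are conditionally independent given their level), SNP variation,
realistic repeat sequence content (repeat intervals are annotations over
random sequence), or the bimodal gbM distribution of real genomes.
Passing recovery tests therefore demonstrates correctness of the
estimators and calibration of the testing pipeline under the stated
sampling model — not robustness to alignment artifacts or biological
confounding.

## Determinism and numerics

All randomness flows from a single integer seed through per-stage
`SeedSequence` spawns (genome / methylome / expression), so every stage
is independently reproducible and the full pipeline is byte-identical
across reruns (TSVs are written with a fixed float format; the manifest
hashes the configuration minus the output path). Identity checks on
floating-point levels use exact equality of identical inputs rather than
a variance threshold; the window correlation refuses (rather than
returns 0 for) degenerate inputs. Fisher tail sums are accurate to
~1e-12, dominated by the exp/log round trip.

Test problem sizes were chosen to make the statistical assertions sharp
at desk scale: 5×10⁴ sites × 20 replicates for the null calibration
(union bound on P(p_min < 0.001) and emptiness of the calibrated call
set), 2×10⁴ sites × 10 seeds at 10% planted SeMCs for FDR, 10⁴ sites at
amplitude 0.5 / coverage 30 for peak recovery (≥ 80% exact recovery),
2×10³-site series per context for 3-SE baseline recovery, a 400-kb
genome for window-correlation recovery against planted probabilities
(±0.05), and 500-gene × 20-replicate expression sets for the
gbM–stability association.

## Known limitations

- The literal (uncorrected) SeMC mode is anti-conservative by design;
  its absolute SeMC counts are definition-dependent and should be read
  comparatively, not as calibrated discoveries (see the caveat above).
- The per-site statistic ignores spatial correlation between neighbouring
  cytosines; no region-level DMR merging is attempted.
- Storey's smoother needs a healthy p-value distribution; below 50 values
  π̂₀ is pinned at 1 (pure Benjamini–Hochberg behaviour).
- The seasonal range depends on the smoothing width; width 3 over 8
  dates damps single-date spikes but also genuine narrow peaks.
- Newick export quotes no labels; site labels are sanitised
  (`seq_pos[F|R]`) to stay inside the vanilla grammar.
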