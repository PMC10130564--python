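# Methods

This note records the models, estimators, defaults and design choices
behind charrscan, and what the synthetic-data experiments do and do not
show about real data.

## Synthetic genotype model

**Divergence.** Per-site ancestral frequencies are drawn uniformly on
(0.1, 0.9) — avoiding near-fixed sites whose Weir–Cockerham components
are numerically unstable; the range is configurable. Each population's
frequency comes from the Balding–Nichols Beta distribution
Beta(p(1−F)/F, (1−p)(1−F)/F), so Var(p_pop) = F·p(1−p) and the
between-population variance of (p₁−p₂) is 2F·E[p(1−p)]. F = 0 bypasses
the Beta draw (both populations share p) rather than dividing by zero.

**Linkage disequilibrium.** Haplotypes carry a latent stationary
Gaussian AR(1) path with site-to-site correlation exp(−d/λ)
(λ = `ld_block_scale`, default 150 kb); the allele is the indicator
z < Φ⁻¹(p_pop). Properties that motivated this choice over a
founder-haplotype copying model:

* the marginal allele frequency equals the Balding–Nichols draw exactly,
  so the divergence target is not inflated by founder-pool drift (a
  K-founder copying model adds ≈ 1/K of spurious F_ST);
* r² decays monotonically with distance with a tunable physical scale —
  at the default λ the genotype r² is ≈ 0.1 at 100 kb, matching the
  magnitude seen in dense farmed-salmonid panels;
* λ → 0 degenerates to independent (unlinked) sites, which the
  F_ST-recovery experiments use.

The model matches no explicit demographic history: its r² decay is a
single exponential scale rather than the mixture of scales a real
pedigree/recombination process produces, all LD is positive-sign by
construction, and there is no allele-frequency–dependent haplotype
structure. Tests that pass on it demonstrate correctness of the
estimators and detection machinery under controlled truth, not
calibration against any particular wild or farmed population.

**Site positions.** Default: a Poisson process with configurable mean
spacing (385 bp ≈ 2.6 SNPs/kb). A `"uniform"` mode draws gaps from
U(0.5·mean, 1.5·mean) instead; it exists because a Poisson process at
~2 kb mean spacing produces >10 kb gaps every ~300 kb (P = e⁻⁵ per
gap), and any ROH rule that breaks homozygous windows at a 10 kb gap
then fragments every megabase-scale run — a property of the position
model, not of the detector. ROH parameter-recovery experiments therefore
use the uniform mode; everything else uses the Poisson default.

**Sweeps and ROH tracts.** `inject_sweep` replaces a chosen fraction of
one population's haplotypes by a single randomly drawn core haplotype
inside an interval (a hard sweep caricature: maximal haplotype
homozygosity, no soft-sweep diversity, no recombination breakdown at the
edges). `inject_roh` copies haplotype 1 over haplotype 2 inside a tract,
making every site homozygous there while preserving allele frequencies
in expectation.

**Determinism.** One root `SeedSequence` spawns child streams in a fixed
order (positions, frequencies, per-population haplotypes, alleles), so
identical config + seed yields byte-identical VCF output and adding
operations does not reshuffle earlier draws.

**Mitogenomes.** Haplotype sets are built from group founders plus
per-haplotype private mutations at mutually disjoint alignment columns,
so every pairwise Hamming distance is the exact sum of the relevant
mutation counts. The generator takes the maximum within-group distance
and the between-group founder distance as parameters and reproduces them
exactly; it makes no attempt at a realistic substitution process.

## Estimators

**F_ST.** Per-site Weir–Cockerham variance components a (among
populations), b (among individuals) and c (within individuals) are
computed from per-site sample sizes, allele frequencies and observed
heterozygosity; θ = a/(a+b+c), undefined (NaN) when the denominator is
zero. Window values are the unweighted mean of per-site θ (negative
values retained), with the ratio-of-sums variant emitted alongside. The
genome-wide fixation index uses the multi-locus estimator
Σa / Σ(a+b+c) — the form Weir & Cockerham give for combining loci and
what VCFtools reports as the weighted value. The distinction matters:
under Balding–Nichols truth the unweighted mean of per-site ratios
converges to ≈ 0.10 when F = 0.12 (and ≈ 0.21 when F = 0.3) even with
frequencies known exactly, whereas the multi-locus estimator is
consistent for F; recovery tests therefore target the multi-locus value.

**EHH / iES / XP-EHH.** EHH at distance x from a core site is
Σ_h C(n_h,2)/C(n,2) over classes of haplotypes identical from the core
through x (EHH = 1 at the core by definition). Curves truncate below
`min_ehh` (default 0.05; the first sub-threshold point is kept so the
integral includes the final descent) or at an adjacent-site gap over
`max_gap` (default 200 kb). iES is the trapezoidal integral over
physical distance, both directions summed. XP-EHH raw scores
ln(iES_A/iES_B) are standardized genome-wide (mean 0, SD 1 by
construction — no frequency-bin standardization) and converted to
two-sided normal p-values; sites with zero iES in either panel are
dropped. Two-sided tails are used because sweeps in either population
are of interest. The inner identity-class scan is numba-compiled; a
genome scan of ~15k sites per population runs in about a second.

**DCMS.** Per-window empirical right-tail p-values
p_i = (1 + #{j≠i : v_j ≥ v_i})/(N+1) (never exactly 0 or 1) are computed
for both window statistics over the eligible windows (≥ 30 SNPs, both
statistics defined), then combined as
DCMS_w = Σ_t log((1−p_wt)/p_wt) / Σ_i |r_it| with natural logs,
p clipped to [1e-10, 1−1e-10], and r the Pearson (optionally Spearman)
correlation matrix of the statistics across those windows. Absolute
correlations are used in the denominator, following the source method's
reference implementation. Note the duplicate-column invariance of the
weighting is exact only when the duplicated statistic is uncorrelated
with the others (with two copies of S₁ and a third statistic at
correlation ρ the copies' weights are 2+|ρ|, not 2(1+|ρ|)); the test
suite checks the exact identity in the single-statistic case and the
general case against direct formula evaluation.

**Hit calling.** The cutoff is the empirical quantile (linear
interpolation) of the eligible windows' values; every window at or above
the cutoff is flagged, so ties inflate the hit count rather than being
broken arbitrarily. All three statistics are called on the same eligible
window universe so their intersection counts are comparable.

**ROH.** A window of `window_snps` consecutive SNPs slides one SNP at a
time; a window is homozygous when its heterozygous-or-missing count is
at most `max_opposite_per_window` and it spans no adjacent-SNP gap over
`max_gap_bp`. A SNP is in a run when at least `min_window_hit_fraction`
(default 0.05, the detectRUNS default) of its covering windows are
homozygous; maximal stretches pass if they span ≥ `min_length_bp` and
hold ≥ `min_snps_in_run` SNPs (default: the window size). Missing
genotypes count as opposite (conservative; configurable). Run boundaries
are the first/last SNP positions, so detected length understates the
true tract by about one SNP spacing per edge while the lenient hit
fraction extends runs a few SNPs past the edge; at 2 kb spacing the two
effects nearly cancel (recovery within ~0.05 percentage points of
truth). The rule set is oracle-tested against an independent brute-force
scanner, not claimed bit-identical to any particular detectRUNS release
(whose gap-breaking semantics between windows and runs are not fully
specified). F_ROH divides summed run length by the summed contig lengths
of the analysed chromosomes (a whole-reference length can be supplied
instead).

**Length classes.** Runs are binned [1,2), [2,4), [4,8), [8,16) Mb; the
first class keeps the conventional "0–2 Mb" label even though the 1 Mb
minimum length makes its lower edge 1 Mb. Runs ≥ 16 Mb go to a flagged
overflow class.

**GRM / PCA.** Yang's estimator: off-diagonals average
(x_i−2p)(x_j−2p)/(2p(1−p)) over sites where both samples are genotyped
(pairwise-complete); diagonals use 1 + (x²−(1+2p)x+2p²)/(2p(1−p)), whose
expectation is 1+F. Frequencies are estimated from the sample, so an
unrelated panel's off-diagonals centre on −1/n, not 0 (rows sum to ≈ 0)
— tests assert that property. Monomorphic sites are dropped; PCA
mean-imputes missing genotypes after 2p-centring and √(2p(1−p))-scaling
and uses SVD. LD pruning is a greedy left-to-right windowed scan
removing the lower-MAF member of any pair above the r² threshold
(right-hand site on ties); both bp-span and SNP-count windows are
supported. The guarantee is per scan window: pairs closer than
window − step always share a window and therefore respect the threshold.

**LD / Nₑ.** r² is the squared Pearson correlation of dosage vectors
(genotype r², the popLDdecay default regime; haplotype-level analysis is
possible by passing haplotype rows as samples). Decay curves bin all
intra-chromosomal pairs within `max_dist` (default 500 kb). The Nₑ
inversion maps each bin midpoint to Morgans at a constant cM/Mb
(default 1), Haldane-transforms to recombination fraction c, subtracts
1/(2n) from the bin mean and inverts E[r²_adj] = 1/(α + 4Nc) with α = 1
(drift only; α = 2.2 for mutation-adjusted analyses is accepted but
untested against any reference tool), dated at t = 1/(2c) generations.
Bins with non-positive adjusted r² are dropped with a warning. No
standard error is attached: the reference tools' error model is not
reproduced, and between-bin scatter should not be read as a confidence
interval.

**Welch's t.** scipy's unequal-variance t-test with the
Welch–Satterthwaite df reported explicitly.

**Enrichment.** fold = (k/n)/(K/N); p is the hypergeometric upper tail
of k ("fisher") or of k−1 ("ease", the conservative DAVID-style
variant); p-values are reported unadjusted with a Benjamini–Hochberg
column for convenience. Upper-tail hypergeometric p-values are discrete
and super-uniform, so null-uniformity checks need a background large
enough that the probability lattice is fine (the test suite uses
N = 100,000, K = 30,000, n = 10,000).

**Haplotype network.** Kruskal MST with edges processed in
(weight, node, node) lexicographic order, so ties break reproducibly. A
non-tree pair is an alternative link iff its distance equals the maximum
edge weight on the tree path between its ends (an equally parsimonious
connection — the cycle-property characterization). Gap/ambiguity columns
are removed by complete deletion before haplotyping; reference tools
differ in their default gap handling, so haplotype counts on gappy
alignments may differ from theirs.

## Interval and coordinate conventions

VCF and GFF3 are 1-based inclusive on disk; every internal interval is
0-based half-open; BED output is 0-based half-open. Scan windows tile
from 0 every `step` bp while start < chromosome length, so trailing
windows may extend past the contig end. Candidate windows merge when
their overlap is at least `merge_overlap_fraction` (default 0.5) of the
shorter interval, run to closure (order-independent), then extend ±10 kb
clipped at [0, contig length]. Gene–region intersection uses the ≥ 1 bp
overlap rule (the bedtools default).

## Filtering

"MAF above 5 %" is implemented as a strict > 0.05 comparison (VCFtools
`--maf` semantics); the operator is configurable because inclusive
thresholds are also in circulation. Call rate uses ≥. Missing genotypes
are excluded from both the numerator and denominator of allele
frequencies.

## Problem sizes in the shipped experiments

The test suite and acceptance script run at desk scale by design:
F_ST recovery uses 2 × 24 diploids × 20,000 unlinked SNPs × 5 seeds;
inbreeding recovery uses a 500 Mb genome (25 × 20 Mb) at 2 kb spacing
with a 50-SNP detector window (the 2500-SNP default scaled by the same
~6 % opposite-genotype allowance); sweep-power replicates use a 6 Mb
chromosome at 2.6 SNPs/kb with 240 scan windows per replicate. These
sizes keep every experiment to seconds while leaving enough windows for
the 99.5 % empirical quantile to be meaningful.

## Known limitations

* The LD model's single exponential correlation scale cannot reproduce
  the long flat tail of real decay curves; Nₑ trajectories estimated
  from simulated curves are internally consistent but not comparable to
  any published population's history.
* XP-EHH standardization is global rather than per-frequency-bin, which
  slightly miscalibrates p-values when the two panels' frequency spectra
  differ strongly.
* The ROH detector's gap rule operates through window homozygosity only;
  no separate run-level gap split is applied.
* ADMIXTURE-style model-based clustering, statistical phasing, variant
  calling and read-level QC are out of scope; the pipeline consumes a
  phased, filtered VCF.
* Enrichment operates on user-supplied term→gene maps; no ontology
  databases ship with the package.
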