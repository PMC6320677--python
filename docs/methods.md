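# Methods

This note documents the models and procedures implemented in cladeforge,
the defaults they ship with, the choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Alignment filtering and concatenation

`filter_alignment` applies a sequence (row) pass before a column pass;
the order matters and is fixed because a removed sequence no longer
contributes to column ambiguity fractions. Ambiguity means the IUPAC
degeneracy codes (N, R, Y, S, W, K, M, B, D, H, V). Gap characters are
*not* counted as ambiguous by default: gaps record alignment structure,
ambiguity codes record base-call uncertainty. Published pipelines differ
on this point, so `FilterPolicy.count_gaps_as_ambiguous` switches it.
Thresholds are strict inequalities ("more than 10%"): a row or column at
exactly the threshold survives. Defaults: 10% per sequence, 10% per
column, length window 500–4,051 bp, at least one accession per species
(a species present before filtering must survive it).

`concatenate` gap-pads accessions missing from individual genes, since
only one accession per species is required, and returns 1-based
inclusive partition intervals that are contiguous, disjoint and
covering.

## NG86 divergence

`ng86_pairwise` implements Nei–Gojobori (1986) counting: per-codon
synonymous-site fractions averaged between the two sequences (so
N + S = 3 × codons, exactly), difference counts averaged with equal
weight over the mutational pathways of multi-difference codons, and the
Jukes–Cantor correction d = −¾ ln(1 − 4p/3). Two conventions needed
fixing:

- changes that create a stop codon count as nonsynonymous in site
  counting; pathways passing through a stop are excluded unless every
  pathway does;
- codons containing any ambiguity code or gap in either sequence are
  dropped pairwise, mirroring the alignment filter's philosophy.

p ≥ 3/4 is flagged saturated and the corresponding d is NaN; saturated
genes are excluded from per-pair aggregates. Quartiles in
`rate_matrix` use linear interpolation (numpy default, R type 7) —
printed quartiles depend on this choice. Empty cells are NaN, never 0.

## Node dating and ultrametricization

Calibration bounds come from T = dS/r. The rate r is deliberately a
required argument with no default: it is a property of the clade under
study (for the cottons, on the order of 0.01 synonymous
substitutions/site/Myr pairwise) and silently assuming one would be
worse than failing.

`ultrametricize` replaces penalized-likelihood smoothing with a
constrained least-squares problem: choose internal-node ages t and one
global rate ρ minimizing Σ_branches (b − ρ·Δt)², subject to tip ages 0,
parent ≥ child, and the calibration boxes. This keeps the qualitative
output (an ultrametric tree honoring bounds) while being fully
specifiable and checkable by brute-force grid search. Solved with SLSQP;
the initial point scales clock depths to the mid-calibration root age,
which also serves as the tie-break toward equal per-branch rates when
the optimum is flat. Infeasible bound systems (a node's minimum age
above an ancestor's maximum) are rejected up front with the conflicting
nodes named.

## Brownian-motion ancestral states

`bm_ancestral_states` computes ML ancestral states: each internal node's
estimate is the GLS mean of the tips under the tree re-rooted at that
node. Rather than performing tree surgery, the re-rooted tip covariance
is built directly from path lengths, C_v[i,j] = (d(v,i) + d(v,j) −
d(i,j))/2. σ² is the ML estimate at the original root,
(x−â)ᵀC⁻¹(x−â)/n, and node variances are σ²/(1ᵀC_v⁻¹1). Point estimates
agree with phytools::fastAnc to 1e-6 (cross-checked in the test suite
when an R installation is present). A constant trait gives σ² = 0 and is
flagged degenerate; singular covariances (zero-length branches) fall
back to least-squares solves.

## ABBA–BABA and shared-derived SNPs

Polarization drops sites where the outgroup is missing, ambiguous, or
carries a third allele, and counts each exclusion class. Pattern
counting excludes sites missing in any of the four taxa. The jackknife
is delete-one over blocks — 1 Mb genomic blocks by default, or a fixed
number of equal-count blocks (100) for short synthetic genomes, since no
block scheme fits both regimes. On homogeneous i.i.d. sites the
jackknife SE agrees with the analytic binomial SE within 10% at 100
blocks (tested).

The shared-derived tabulation counts sites where the recipient (but not
the control) shares the donor's derived allele, and vice versa, per
partition. Three equality tests are provided because the field's
published tables are ambiguous about which was used: an exact binomial
test (default), the goodness-of-fit chi-square (a−b)²/(a+b), and a
permutation test with B = 2,000 replicates and a p-value floor of 1/B.
Gene intervals are half-open after import; VCF positions are 1-based.

## Indels

Records are left-trimmed to anchor-base form before anything else, since
position conventions otherwise change counts. The outgroup-matching
allele is ancestral; the event belongs to the lineage carrying the
derived allele (insertion if the derived allele is longer). An outgroup
matching neither allele yields polarity `unknown`: kept in counts,
excluded from polarity statistics. Densities (indels/Mb) and SNP:indel
ratios round half-to-even to integers — the rule that reproduces the
published per-accession ratios (16–18) and chromosome densities.

The effect classifier is coordinate-based: frameshift iff the net CDS
length change is not a multiple of 3; in-frame ±3 nt is a single
amino-acid gain/loss; events touching the first/last codon set
start/stop-lost flags; in-frame events introducing a premature stop
(detected by translating the edited CDS when sequence is available) are
stop-gains; events within 2 nt of an intron boundary (the canonical
donor/acceptor dinucleotides) disrupt splicing. Compound outcomes carry
multiple flags. The classifier is validated against a brute-force
translate-and-compare oracle on 1,000 random CDS indels.

## Repeat landscape

A genome-size equivalent (GSE) is floor(fraction × genome size /
read length) reads — 1% at 85 nt by default, so an 880 Mb genome yields
103,529 reads. Cluster retention uses floor(0.0001 × total input reads);
a zero floor degrades to "at least one read" with a warning. Occupancy
is read share × genome size, so occupancies sum to genome size exactly.

Pairwise read identities use edlib global alignment (identity = 1 −
edit distance / alignment length, minimum overlap 55 nt, with optional
random pair subsampling to cap the quadratic cost). Histograms use 1%
bins over 70–100% identity; only non-empty bins enter the regressions
(an empty bin is an unobserved identity level, not a zero-count
observation). BIC is k ln n − 2 lnL under Gaussian residuals with σ²
floored at numerical noise relative to the data scale, so an exactly
interpolating higher-order model cannot win on floating-point residue.
The six trend classes map to ages as: positive linear → young; flat
(null) → old; negative linear → old; positive quadratic with data mass
right/left of the vertex → young/old; negative quadratic with mass
right of the vertex → old; negative quadratic with mass left of a
vertex above 99% identity → old. "Mass left/right" means more than 50%
of counts on that side. The one shape the six classes leave undefined —
a concave parabola rising toward an interior vertex at ≤ 99% — is
called young, since the trend within the data range rises toward high
identity.

Differential abundance at a phylogenetic node is a per-cluster
two-sided Mann–Whitney test between the node's two clades with
Benjamini–Hochberg adjustment (α = 0.05 default); the published
analysis's test is under-specified, and a rank test makes the fewest
distributional assumptions. Brownian ancestral occupancies at the focal
node are returned for use as the next depth's inputs. Singleton clades
are skipped.

## Gene families

Ancestral family sizes minimize total absolute change (linear-cost
Wagner parsimony) via the Farris interval algorithm; for a node with k
children the optimal-state interval is bounded by the k-th and
(k+1)-th order statistics of the 2k child-interval endpoints, which
reduces to intersection-or-gap for binary nodes. Verified against
exhaustive enumeration on trees up to 6 tips. Root ties break toward
the smaller count by default (biasing root-adjacent ambiguity toward
gains), switchable via `prefer_smaller`. Rates are reported per family,
per substitution-unit branch length, and per Myr when node ages are
supplied. Resampling draws orthogroup rows with replacement; note that
because the per-branch rate is a per-family sum, the bootstrap
distribution is centered on the observed value — an influential
orthogroup shows up as inflated spread on the affected branch and
leave-one-out sensitivity, not as the observed value escaping the
envelope.

## Synthetic data

The generator emulates the study conditions at toy scale, every value
drawn from one seeded generator (same seed ⇒ byte-identical files).

- **Tree**: random-join clock topology, internal depths sorted uniforms
  scaled to `tree_height` (default 0.015 synonymous subs/site per
  lineage, giving maximal pairwise dS near the cottons' 0.03); the
  outgroup attaches at twice the root depth. Labels follow join order so
  sp01/sp02 are always a cherry and sp03 their nearest neighbour — a
  canonical ABBA–BABA quartet.
- **Codon evolution**: per-site Monte Carlo — Poisson(branch length)
  proposed changes per nucleotide site, synonymous proposals always
  accepted, nonsynonymous accepted with probability ω (default 0.12,
  the cottons' dN/dS scale), stops rejected. Expected dS per unit
  branch length is 1 and expected dN/dS is ω, which is what makes NG86
  recovery testable. No codon-frequency or transition/transversion
  structure is modelled.
- **SNPs**: infinite-sites mutations placed on branches with
  probability proportional to length; a fraction (`ils_fraction`,
  default 0.1) of sites instead draws a random species pair to share
  the derived allele, emulating deep coalescence symmetrically (this is
  what makes ABBA = BABA in expectation without gene flow).
  Introgression replaces the recipient's allele with the donor's at a
  fraction f of sites. The outgroup is ancestral except at a small
  perturbed fraction (0.5%) that exercises polarization error paths.
- **Indels**: deletion with probability β/(1+β) (default β = 2, the
  observed ~2-fold deletion bias), geometric lengths with mean 6.2 nt
  truncated at 270 nt (the observed mean and maximum).
- **Repeat clusters**: reads are consensus copies with per-read
  divergence centred to a target mean identity; labelled histogram
  *shapes* for the age classifier are generated directly as
  Poisson-noised expected counts per trend class, because the histogram
  of pairwise identity sums cannot be shaped precisely through
  independent per-read draws. Classifier accuracy statements therefore
  apply to histogram-level inputs; the read-level path is exercised
  end-to-end separately.
- **Orthogroups**: per-branch Poisson gains and binomial losses with
  rates scaled by relative branch length (defaults 0.1/0.2 per family
  per average branch, loss above gain to mirror the observed
  asymmetry).
- **Genome sizes**: Brownian motion from an 880 Mb root (the
  *G. raimondii* genome size) with σ² = 70 Mb²/Myr, chosen to spread
  13 tips over roughly the observed 841–934 Mb range.

Toy-scale defaults (50 genes × 250 codons, 2,000 SNP sites, 300 indel
events, 3 clusters, 200 orthogroups, 2 × 0.5 Mb chromosomes) keep the
full pipeline and its recovery suites fast; the acceptance studies use
200 genes × 500 codons for ω recovery, 2,500 events for deletion-bias
recovery, and 50 seeds × 2,000 sites for D-statistic power. What the
generator does **not** emulate: sequencing error, assembly artifacts,
recombination maps, rate heterogeneity among sites, and realistic
repeat sequence families — so passing recovery tests demonstrate
estimator correctness under the stated models, not robustness to those
real-data complications.

## Known limitations

- The dating smoother assumes a single global rate with least-squares
  deviations; strong among-lineage rate variation will pull ages toward
  the clock.
- NG86 is a counting estimator; at high divergence or strong codon bias
  an ML codon model would differ. Saturation is flagged, not modelled.
- The effect classifier assumes single-transcript gene models with
  consistent CDS phase and classifies against one gene at a time.
- Wagner parsimony undercounts events relative to a birth–death model
  when rates are high; per-branch rates are comparable in rank, not in
  absolute value, with likelihood-based tools.
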