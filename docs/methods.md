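# Methods

## Scope and model

`rhizonet` reconstructs microbial co-occurrence structure across a four-
compartment soil–root gradient (non-rhizosphere `Non`, rhizosphere `Rhi`,
root surface `Epi`, root interior `Endo`), each sampled with 12 biological
replicates. Three networks are built per compartment — bacterial, fungal,
and the merged bacterial–fungal association (BFA) network — giving the
twelve-network design the analysis mirrors. Downstream, nodes are
classified into topological roles, and functional potential for microbial
interaction (quorum sensing, cobamide biosynthesis) is profiled from gene
counts.

## Abundance preparation

OTU count tables are screened per compartment by a prevalence rule: an OTU
must be detected (any nonzero count; no minimum-count threshold) in at
least 8 of the 12 replicates. An optional pre-filter (default on) removes
OTUs below 0.01% of total table abundance. Retained OTUs are converted to
per-sample relative abundances. The fixed order is: prevalence filter on
counts, abundance cut, then relative abundance over retained OTUs — the
two operations do not commute, so the order is part of the contract and is
tested. Bacterial and fungal tables are concatenated (namespaces `OTUB_*`,
`OTUF_*`) before building the BFA network; merging happens in counts mode,
where splitting by domain is an exact inverse.

## Similarity threshold by random matrix theory

Pearson correlation (Spearman behind a flag) of relative abundances across
the 12 replicates gives a symmetric matrix with unit diagonal. The edge
threshold St is selected from spectral statistics rather than by hand: for
each candidate St in a scan (default 0.30–0.99, step 0.01), entries with
|r| < St are zeroed, rows left without off-diagonal support are removed,
and the eigenvalues of the remaining matrix are computed. Eigenvalues
closer than 1e-8 are collapsed: exact degeneracies (e.g. from rank
deficiency — a correlation matrix estimated from 12 samples has rank at
most 11) carry no spacing information.

The spectrum is *unfolded* to unit mean spacing by a monotone
piecewise-cubic (PCHIP) interpolant through every 10th point of the
empirical cumulative spectral function. A global polynomial fit is
available (`unfold_spectrum(method="poly")`) but is not the default: the
spectra of thresholded block matrices are strongly multimodal (a cluster
of near-zero eigenvalues plus isolated large block eigenvalues), and no
low-degree polynomial tracks such a density; the local interpolant does,
while leaving genuine spacing fluctuations intact at the scale of one
spacing (knots are ~10 spacings apart).

The nearest-neighbor spacing distribution (NNSD) of the unfolded spectrum
is tested by chi-square goodness of fit with ten equal-probability bins
(trailing bins merged below an expected count of 2) against two reference
forms: the Wigner surmise P(d) = (πd/2)·exp(−πd²/4), the GOE signature of
a noise-dominated matrix, and the Poisson form P(d) = exp(−d), the
signature of superposed independent (modular) spectra. St is the smallest
candidate whose Poisson fit is not rejected (p > 0.05) for two consecutive
candidates. A scan record with both chi-square statistics per candidate is
returned for audit, and failure to find a transition raises rather than
silently defaulting. Both textbook limits are regression-tested: 300×300
GOE simulations fit Wigner and reject Poisson, independent spectra fit
Poisson, each in ≥90% of seeds.

Caveat: with only 12 replicates the scan range, unfolding method and fit
criterion are all configurable and logged; published thresholds from other
implementations are not expected to be recovered exactly.

## Networks, modules, roles

An edge joins every OTU pair with |r| ≥ St; the signed correlation is kept
as an attribute and edges are flagged intra-/inter-domain. Degree-0 OTUs
are not counted as nodes. Summaries: average connectivity avgK = 2E/N
(exact identity, regression-tested), mean local clustering (degree-1 nodes
contribute 0), mean geodesic distance on the giant component (disconnected
pairs excluded, not infinite), and the R² of an ordinary least-squares line
through log10(frequency of degree k) vs log10(k) over nonzero frequencies
(≤2 distinct degrees fit exactly, R² = 1). Density differences between two
networks are tested by a two-sided Fisher exact test on realized vs
possible edges.

Modules come from Clauset–Newman–Moore greedy modularity maximization over
the whole graph (disconnected components jointly), with module ids ordered
by size for reproducibility; Newman's Q is recomputed independently of the
detector, and Q > 0.4 (strict) flags modular structure. Node roles use
Guimerà-style statistics: Zi, the within-module degree z-score (population
SD; Zi = 0 when the SD is zero), and Pi, the participation coefficient
1 − Σ_s (κ_is/k_i)². Thresholds are strict as printed: network hub
(Zi > 2.5 and Pi > 0.62), module hub (Zi > 2.5), connector (Pi > 0.62),
peripheral otherwise — boundary-equal values fall to peripheral. All
non-peripheral nodes are keystone taxa; the report flags the top-3 degrees
per network and marks ties at the boundary instead of breaking them.
Module composition (bacterial/fungal fractions) is reported for modules
with strictly more than 15 nodes.

## Gene panels and enrichment

Panels ship as an editable TSV (quorum-sensing module 1: cqsA, tdh, luxR;
module 2: lasI, rhlI, pqsH, lasR; cobamide biosynthesis with aerobic cobG,
cobF, cobA and anaerobic cbiT, cbiE corrin-ring routes plus further steps).
Counts are displayed as TPM, (c_g/L_g)/Σ_h(c_h/L_h)·10⁶, so every column
sums to one million; a gene with zero raw counts is flagged *undetected*,
which is distinct from a low TPM, and a panel gene absent from the table is
flagged rather than an error. Enrichment between compartment pairs is
tested on raw read counts (gene vs all other annotated reads; TPM is
display-only because the exact test requires counts) with a two-sided
Fisher exact test, BH-corrected across genes within each compartment pair;
q < 0.05 flags significance. The BH family choice (per compartment pair)
and the denominator (all annotated reads) are configuration defaults, as
other groupings are equally defensible. Detection frequencies of the
cobamide panel are summarized per bacterial family and compartment, with
families outside the overall top 10 pooled into `other`.

## Mantel tests

Community distance is Bray–Curtis on relative abundances; environmental
distance is Euclidean on z-scored variables (constant variables dropped
with a warning); both metrics are flags. The Mantel statistic is the
Pearson correlation of upper triangles with a one-sided (positive)
permutation p-value, p = (1 + #{perm r ≥ observed})/(1 + n_perm), so the
smallest attainable p is 1/(n_perm+1). Null calibration (uniform p) is
regression-tested by Kolmogorov–Smirnov over 200 seeds.

## Synthetic data: what it emulates and what it does not

`generate_community` draws, per module m and replicate r, a factor
f_mr ~ N(0,1); OTU i in module m has log-abundance μ_i + λ·f_mr +
N(0, noise_sd), with μ_i ~ N(0, 1). Counts are multinomial at a fixed
library size on the per-sample softmax of log-abundances — the
compositional closure of sequencing — and dropout zeroes entries after the
draw, mimicking the detection limits that motivate the 8/12 prevalence
rule. Column sums equal the library size before dropout.

Background OTUs (those outside every planted module) additionally receive
independent lognormal dynamics of scale `background_sd` (default 1.5).
This term is essential, not cosmetic: under compositional closure the
denominator fluctuates with the winning module's factor, and OTUs whose
own variation is small would all mirror that denominator and correlate
near-perfectly with one another, welding the planted blocks into one
component. With realistic independent background dynamics the correlation
scan shows the expected phase structure — a dense noise-dominated (GOE)
regime at low thresholds crossing to sparse independent blocks (Poisson)
— and the full pipeline recovers planted modules at NMI ≈ 1 (median over
20 seeds) under the default conditions (λ = 3, noise_sd = 0.2, dropout 0,
6 modules of 20 among 360 OTUs), while a λ = 0 community keeps ~1% of
possible edges at the selected threshold.

Two compositional effects are worth knowing when designing scenarios: a
factor shared by *every* OTU cancels exactly in the softmax (relative
abundances are invariant to per-sample shifts), so gradients are only
visible when they affect part of the community; and a strong gradient
saturates Bray–Curtis, so Mantel-oriented scenarios should keep λ moderate
(≈1) to stay in the linear response regime.

`generate_gene_counts` draws Poisson counts with mean depth·rate·length
normalized by the *baseline* rate-length total, so a planted fold change
equals the expected count ratio between compartments exactly.
`generate_env_matrix` reuses the community seed stream so its first
variable can track the first module factor at a chosen correlation.

The generators do not simulate read-level error, chimeras, phylogenetic
correlation, or taxon-specific dispersion; passing tests therefore show
that the statistical machinery behaves correctly under a known latent
model, not that real amplicon data meet that model.

## Problem sizes and numerical conventions

Default test and acceptance problem sizes — 360-OTU communities, 20 seeds
per Monte-Carlo claim, 300×300 GOE matrices, 200 Mantel/FDR replicates,
199–999 permutations — were chosen so each claim's sampling error is well
inside the asserted margins while a full run stays in the minutes range.
All randomness flows from integer seeds through `numpy.random.default_rng`;
the pipeline derives per-stage seeds from a single config seed via SHA-256,
and reruns with the same configuration are checksum-identical. Eigenvalue
dedup tolerance is 1e-8; NNSD needs at least 20 distinct eigenvalues;
correlations are clipped to [−1, 1] and symmetrized against floating-point
asymmetry.

## Known limitations

- St selection with 12 samples is noisy; the two-candidate persistence
  window suppresses single-grid-point flukes but the selected St can move
  by a few grid steps between seeds.
- The power-law R² follows the degree-frequency-histogram convention
  (log–log OLS), which is known to flatter small networks; it is reported
  for comparability, not as a rigorous scale-free test.
- Fisher-exact enrichment on deeply sequenced metagenomes has enormous
  power; biological effect sizes should be read from the odds ratio, not
  the q-value alone.
- `merge_domains` on already-relative tables renormalizes columns (their
  sums would be 2); merging is intended in counts mode, where domain
  splitting is an exact inverse.
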