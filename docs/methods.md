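# Methods

`mircornet` re-implements, as one tested pipeline, an integrative
miRNA-mRNA analysis of two-group bulk expression profiles: fertile (FH)
versus subfertile (SFH) heifers profiled in peripheral white blood cells,
with miRNA counts from 7 + 7 animals and mRNA counts from 7 + 6 (one SFH
mRNA library dropped). The stages are: count QC, negative-binomial
differential expression, seed-based target prediction, PCIT co-expression
networks per group, differential connectivity and rewiring, miRNA:mRNA
duplex minimum free energy, and pathway over-representation. A synthetic
data generator with planted, recoverable truth exercises every stage.

## Count QC

Features that are zero in all samples are dropped first. Counts are scaled
to counts per million (CPM) of the library; a feature is kept iff its CPM
reaches at least `min_cpm` (default 1) in at least `min_frac` (default
50%) of all samples, both groups pooled. The boundary is read as *kept* at
exactly half the samples, matching the "expressed in at least half"
convention of edgeR-style filtering; the CPM used for the decision is
computed once, on the zero-filtered matrix's library sizes, so the filter
does not feed back into its own normalization (under fixed totals it is
idempotent, and `prevalence_filter(..., totals=)` exposes that contract).

## Differential expression

A transparent re-implementation of the DESeq2 skeleton, not a call into
it: median-of-ratios size factors (geometric mean per feature over
samples, features with any zero excluded; per-sample factor = median of
log ratios, exponentiated), per-feature method-of-moments NB dispersion
`alpha = (s^2 - mu)/mu^2` averaged over the two groups and floored at
1e-8, and a Wald statistic on `log2(mean_SFH / mean_FH)` with the
delta-method standard error

    SE^2 = sum_g (mu_g + alpha mu_g^2) / (n_g mu_g^2 ln(2)^2).

Group means carry a +0.5 pseudo-count guard; a feature that is all-zero in
one group gets a +-30 sentinel log2FC and a flag. The two-sided p-value is
referred to a **t distribution with n1 + n2 - 2 degrees of freedom**: the
dispersion is estimated from that many residual degrees of freedom, and at
n = 7 per group a normal reference is measurably anti-conservative
(empirical type-I ~0.075 and a Kolmogorov-Smirnov distance from U(0,1) at
the 0.05 boundary, versus ~0.05 and ~0.02 under the t reference). Features
are called DEMIs (differentially expressed miRNAs) at raw p <= 0.05 and
|log2FC| >= 0.5, both inclusive; positive log2FC means higher in SFH.
A Benjamini-Hochberg adjusted p is reported but not used for the call.
Dispersion-trend shrinkage, Cook's-distance outlier handling and
independent filtering are deliberately omitted; exact numeric parity with
DESeq2 is not a goal (its size-factor estimator, however, is reproduced to
float precision and cross-checked against pydeseq2 in the tests).

## Target prediction

Canonical seed sites in UTRs follow the TargetScan convention: seed =
miRNA nucleotides 2-7; a site is the seed's reverse complement, classed as
8mer / 7mer-m8 / 7mer-A1 / 6mer by the Watson-Crick match to nucleotide 8
and the target adenine opposite nucleotide 1. G:U wobble is not accepted
in the seed; each locus is reported once under its best class; coordinates
are 1-based inclusive on the given strand. The context++ regression of
TargetScan is **not** re-implemented: the pipeline ingests
TargetScan-format tables and applies the cumulative weighted context++
score filter (<= -0.4, inclusive), then intersects predictions with the
expressed gene set. In synthetic runs a TargetScan-like table is generated
from the seed scanner itself.

## PCIT networks

For every unordered trio (x, y, z) of features, the three first-order
partial correlations are computed, e.g. `r_xy.z = (r_xy - r_xz r_yz) /
sqrt((1 - r_xz^2)(1 - r_yz^2))`; the trio tolerance is the mean absolute
ratio of partial to direct correlation (a zero direct correlation
contributes 0 — an absent association cannot justify eliminating others;
a conditioning correlation of magnitude 1 skips the trio with a logged
count). Edge (x, y) is eliminated if some z satisfies `|r_xy| < |eps r_xz|`
and `|r_xy| < |eps r_yz|`; survivors are the significant associations. The
O(n^3) loop is JIT-compiled (numba) and handles the default 757-node
problem in seconds; a pure-Python brute-force loop is the contract in the
tests.

Networks are built per group over the DEMIs plus expressed predicted
target genes, on the samples with both profiles (7 FH, 6 SFH), keeping
PCIT-significant pairs with |r| > 0.6 that involve at least one miRNA;
gene-gene pairs stay in the optional full dump. A correlation-test p per
edge is reported but not used as a filter. Correlations default to
**log2(CPM + 1)**: the generative model of miRNA repression is
multiplicative, and on the raw CPM scale the Pearson correlation of
exponentially coupled variables is bounded far below the 0.6 edge
threshold (corr(e^{sZ}, e^{-2Z}) = (e^{-2s} - 1)/sqrt((e^{s^2}-1)(e^4-1)),
about -0.2 at the defaults), so raw-scale correlation cannot express the
planted signal; `scale="raw"` is available as a switch.

## Connectivity and rewiring

Connectivity K = degree / max degree within each group's own network;
DK = K_SFH - K_FH over the union node universe (absent nodes count degree
0, since gains and losses are both reported); DK is z-scored with the
sample mean/sd of the whole universe, jointly over genes and miRNAs, and
|z| >= 1.96 is called significant, with SFH as the reference for
gain/loss. Rewiring follows the DyNet centroid idea: per node, the two
groups' weighted neighbor vectors over the union neighborhood (entry =
edge r, else 0), Dn = mean Euclidean distance to their centroid (= half
the distance between the vectors for two states), optionally divided by
the union degree. Exact parity with the Cytoscape plug-in is not a
contract. A central-reference merge labels every edge and node FH-only /
SFH-only / shared.

## Duplex minimum free energy

A hybridization-only nearest-neighbor dynamic program in the spirit of
RNAhybrid: intermolecular pairs only (Watson-Crick and G:U), consecutive
pairs scored by the embedded Turner 2004 stack table, bulge and internal
loops up to 15 unpaired nucleotides scored by tabulated length-dependent
initiations (internal loops add a 0.6 kcal/mol-per-nucleotide asymmetry
term capped at 3.0), and a single duplex initiation of +4.10 kcal/mol.
No terminal-AU penalty, helix-length normalization or p-value model is
applied, and intramolecular structure and accessibility are out of scope;
parity with RNAhybrid's printed numbers is therefore approximate by
design. The stack table is asserted symmetric at load (reading a stack
from the opposite strand gives the same energy). The mfe is the minimum
over all target positions; 0 means no stable duplex. Per-gene affinity is
the arithmetic mean over the gene's transcripts and passes at strictly
below -20 kcal/mol, the conventional miRNA:mRNA affinity cutoff. The
parameters ship as a documented plain-text resource.

## Enrichment

Upper-tail hypergeometric over-representation per term (population = the
annotation universe: all genes in the GMT plus the expressed set), Holm
("Bonferroni step-down") family-wise correction at 0.05, and redundancy
clustering by Cohen's kappa of gene-membership agreement: term pairs with
kappa >= 0.4 are linked and clusters are connected components, represented
by their lowest adjusted-p member. The query per group is the set of genes
correlated *with their own predicted miRNA* in that group's network (the
cognate TargetScan pairs); using all network gene partners instead would
dilute the query with spurious-correlation genes at these sample sizes.
ClueGO's term-fusion heuristics and cluster-level aggregate p-values are
not reproduced.

## Synthetic data

The generator emulates the study design so every stage has recoverable
ground truth. Defaults: 341 well-expressed miRNAs plus 273 low-abundance
(log-mean -2.5) and 20 all-zero rows to feed the QC filters (the observed
zero-row count is recorded in the truth); 741 genes; NB counts with
dispersion 0.1 over log-normal baselines (log-mean 5, log-sd 1.5) and
log-normal library factors (sigma 0.2); 16 planted DE miRNAs with
|log2FC| ~ U(0.5, 2.0) and random sign. Twelve of the DE miRNAs act as
regulators of 40 planted target genes (3-4 each): per sample, a
regulator's latent log-abundance adds N(0, 0.8^2) biological variation,
and an active target's latent abundance is baseline - 2.0 x (standardized
regulator latent) + N(0, 0.2^2), exponentiated into NB means — yielding
strong negative within-group correlation only where the pair is active.
A quarter of the pairs are active in one group only (the rewired nodes).
Regulators and planted genes draw baselines from e^{N(6.5, 0.3)} and
regulator effect sizes from the upper half of the range: count-level noise
has a log-scale floor of sqrt(alpha) ~ 0.32, so weak or low-abundance
couplings could not reach the intended near-deterministic regime, and
per-regulator target cliques larger than ~4 lose their weaker true edges
to PCIT's redundancy elimination.

Sequences: random 21-22 nt miRNAs; UTRs of 500-2000 nt. Each planted pair
gets one canonical site of a cycling class at a recorded 1-based position,
with flanking nucleotides chosen to pin the class down exactly, and — by
default — a 3'-supplementary complement of miRNA nucleotides 9..L directly
upstream so the planted duplex carries real binding affinity (-27 to -47
kcal/mol) rather than a bare seed match. Non-target UTRs are
rejection-sampled (chunkwise, cap 1000 per chunk) to contain no
6mer-or-better match to any regulator's seed. Pathways: one term of 15
genes containing 10 planted targets, plus >= 20 uniform decoy terms.

What the generator does *not* emulate: isomiRs, conservation, raw reads,
gene-gene co-expression modules (non-planted features are independent),
and 3'UTR biology beyond the planted sites. Passing tests therefore show
the pipeline recovers multiplicative repression structure planted under NB
noise at the study's sample sizes — not performance on real libraries.

## Recovery at the study's sample sizes

With 6-7 samples per group the null Pearson correlation spread is wide:
P(|r| > 0.6) is ~0.17 (n = 7) to ~0.21 (n = 6) for independent feature
pairs, so the group networks carry a noise-edge backbone (hundreds of
edges — the same order as the real study's 926/689). Three consequences,
quantified by `mircornet.evaluate`:

* planted pair recovery as negative edges is ~0.85-0.95 (mean ~0.89 over
  20 replicates) — the planted correlations (|r| ~ 0.9) survive both the
  0.6 threshold and PCIT;
* DE-test power for the planted DEMI effect sizes is limited by the extra
  regulator variance; recovery metrics therefore build the network node
  set from the planted DE list, isolating network inference from DE power
  (the pipeline itself always uses its own DEMI calls);
* degree-corrected Dn ranking cannot isolate the planted rewired nodes:
  noise edges inflate every node's degree, and both-group pairs whose edge
  is recovered in only one group are indistinguishable from true rewiring.
  On the cognate central-reference subnetwork the planted nodes do occupy
  the top ranks, but a decile bin there is smaller than the planted set.
  The corresponding acceptance test states the intended bound and fails;
  both ranking variants are reported by the acceptance script.

## Numerical choices

Correlation matrices clip to [-1, 1] and zero-variance features correlate
0 with a warning. PCIT trios with a conditioning |r| = 1 are skipped and
counted. The duplex DP caps loops at 15 nt (beyond which the penalty slope
makes extension never favorable). Holm and the hypergeometric tail are
delegated to statsmodels and scipy; Cohen's kappa is computed from the
2x2 membership table directly. All randomness flows from a single seed
through named sub-streams (counts / sequences / pathways / tables), so
identical configurations reproduce byte-identical outputs; the pipeline
writes its config and a manifest with a hash over everything except the
output path.

## Problem sizes used by the test and acceptance runs

Unit tests run on scaled-down matrices (tens of features) with brute-force
oracles; the PCIT oracle comparison uses 50 random 30-node matrices, the
scanner oracle 10,000 random 1 kb UTRs, DE calibration 2000 null + 500
planted features, and the recovery studies 20 full-size generator
replicates (741 genes, 634 miRNA rows) — sizes chosen so each study gives
stable estimates while the whole suite stays in the minutes range.
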