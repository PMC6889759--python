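# Methods

`panagrokit` re-implements, as a tested library, the desk-scale inferences
used to characterise parthenogenetic, cryptobiotic panagrolaimid nematode
genomes: ploidy from variant-frequency spectra, Alien-Index HGT screening,
Dollo-parsimony gain/loss reconstruction, allo-/autopolyploid origin
testing by gene-tree reconciliation, generation-time-calibrated divergence
dating, and the supporting enrichment/contingency statistics. This note
records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Ploidy from variant-frequency spectra (`afs_ploidy`)

**Model.** At a heterozygous site, the fraction of reads carrying the
alternative allele estimates its copy dosage: 1/2 in a diploid
heterozygote, 1/3 or 2/3 in a triploid (depending on whether one or two of
the three homeologous copies carry it). A homozygous genome yields no
dosage signal — only an error-driven background. Spectra are **folded**
(f → min(f, 1−f)) so the 1/3 and 2/3 triploid modes coincide at 1/3; the
folded support ends at 0.5, which is why the diploid window is capped
there.

**Parameters.** Defaults: `min_depth` 20 reads (dosage resolution: at
depth 20 the binomial sd of f at p=1/3 is ≈0.105, enough to separate 1/3
from 1/2 after pooling thousands of sites); trim (0.05, 0.95), removing
fixed-allele spikes at 0 and 1; bin width 0.02; 5-bin moving-average
smoothing; peak windows [0.28, 0.40] (triploid) and [0.44, 0.50]
(diploid); flatness threshold 1.5 on peak prominence (smoothed max /
smoothed median); `min_variants` 200. All are exposed as arguments. These
are classifier knobs, not reconstructions of the original study's
(unstated) filters.

**KS comparison.** Between-sample spectrum comparison uses the two-sample
Kolmogorov-Smirnov test. For pooled sizes ≤ 12 the p-value is the exact
permutation tail (every C(n1+n2, n1) label assignment enumerated; with
ties this is the natural permutation extension); larger samples use the
asymptotic Kolmogorov distribution at effective size n1·n2/(n1+n2).

**Degenerate inputs.** An empty frequency list is allowed and produces an
all-zero spectrum; a spectrum with median smoothed count 0 but a nonzero
maximum is treated as maximally peaked (prominence ∞), not flat.

## Alien-Index HGT screen (`hgt_alien`)

AI = ln(E_meta + e⁻²⁰⁰) − ln(E_nonmeta + e⁻²⁰⁰), with missing hits encoded
as e-value 1 and e-values capped at 1, bounding |AI| ≤ 200 + ln 2. The
cascade: AI ≤ 0 → not a candidate; AI > 0 with best non-metazoan identity
> 70% → contaminant (the identity rule wins over integration evidence when
they conflict; the reasons trail records what else was seen); AI > 30 with
≥ 1 intron and TPM > 100 → high confidence; AI > 30 → strong candidate;
else weak candidate. Best hit per partition = lowest e-value, ties broken
by higher bitscore then lexicographic subject id, for determinism.
"Neighbour hitting Metazoa" is operationalised as another gene on the same
contig with AI < 0; taxonomic self-exclusion is delegated to the partition
map at read time. The tier report tallies integration features over the
strong (AI > 30, non-contaminant) candidates, the set those screens
target.

## Dollo gain/loss reconstruction (`hgt_ancestry`)

Each family is assumed gained exactly once (multiple independent
acquisitions of the same family being less parsimonious) and lost freely;
regain is disallowed. The gain node is the MRCA of the carriers; the
minimal loss set is the set of maximal subtrees below the gain containing
no carrier — minimal because any valid loss set must cover exactly those
leaves. Losses are counted on edges and attributed to the child node in
reports. Per-node cumulative content satisfies
cum(n) = cum(parent) + gains(n) − losses(edge above n), with
cum(root) = gains(root). Families present in a single species gain at that
leaf. Note that losing carriers can only move the inferred gain node
*tipward* (the MRCA of a subset is a descendant-or-self of the MRCA of the
full set), so under-calling of ancient gains, never over-calling, is the
failure mode under heavy loss.

## Polyploid origin test (`polyploid_origin`)

Full MUL-tree reconciliation is reduced to single-donor-leaf grafting: a
DONOR leaf is attached midway on every edge of the species tree in turn,
all extra copies (copy index ≥ 2 in a parthenogen) are mapped to DONOR —
the single-origin hypothesis — and each grafted tree is scored against
every gene tree by LCA duplication-loss reconciliation with unweighted
cost duplications + losses. This is sufficient to separate the two
hypotheses (donor outside the sampled lineages vs within-lineage
duplication) while keeping the kernel standard and oracle-testable.
The verdict reads the best edge: inside the clade spanned by the
parthenogen leaves (including its crown edge) → autopolyploidy; outside →
allopolyploidy; cost ties across the two classes → ambiguous. The margin
is the aggregate-cost gap to the second-best edge.

## Divergence dating (`divergence_dating`)

Ages are linear in distance and in generation time:
age(i,j) = cal_age · d(i,j)/d(cal pair) · gen_target/gen_cal. Linearity in
generation time is the minimal model consistent with reporting the same
distances under 8- and 50-day generation times (ratio 50/8 = 6.25
exactly); rescaling round-trips are exact. Alignment-free genome distances
(e.g. ANDI PHYLIP matrices) are consumed as input, not recomputed;
Jukes-Cantor distances on aligned pairs (d = −(3/4)ln(1 − 4p/3), gap/N
columns dropped, error at p ≥ 3/4) serve the synthetic recovery tests.

## Enrichment and contingency statistics (`comparative_stats`)

Per-domain Fisher exact tests (default one-sided "greater", the natural
alternative for overrepresentation; exact at small counts) with
Benjamini-Hochberg step-up correction across domains. The counting unit is
proteins carrying ≥ 1 copy of a domain, keeping 2×2 margins fixed across
domains. The 2×2 chi-square is Pearson's with optional Yates correction;
a zero expected cell raises with advice to use Fisher.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their spec (seed included).

* **Variants.** Depth ~ Poisson(mean 50, floored at 1 — no coverage model
  was available, Poisson is the neutral choice); alt count ~
  Binomial(depth, p′) with p′ = p(1−e) + (1−p)e, a symmetric
  single-parameter error flip (it blurs but does not bias the spectrum).
  Defaults: 5,000 sites, error 0.005, `frac_two_thirds` 0.1 — the
  collapsed reference holds the majority allele at most divergent triploid
  sites, so the spectrum shows a single visible 1/3 peak. Not emulated:
  mapping bias, paralog collapse, allele-specific expression. A
  consequence of the error-only homozygous class: almost no sites survive
  the trim window, so homozygous samples classify as `ambiguous`
  (insufficient spectrum) rather than `homozygous_flat`; the flat-spectrum
  branch is exercised directly with flat binned backgrounds. Real
  homozygous samples carry residual artifact variants that this generator
  deliberately does not invent a model for.
* **HGT evidence.** E-value exponents are drawn so the designed AI gaps
  survive the e⁻²⁰⁰ floor; every true-HGT gene shares a contig with a
  metazoan-hitting gene (a dedicated anchor gene is added when no native
  genes are requested). Classification of the three designed classes is
  exact by construction — the recovery test checks wiring, not statistical
  power on borderline cases.
* **Presence matrices.** One gain node per family drawn by weight
  (uniform default); each edge strictly below loses independently at
  `loss_rate`; all-absent families are redrawn. Truth (gain node, lost
  edges) is returned for recovery tests.
* **Gene trees.** Base topology mirrors the species tree; extra copies
  attach as a clade on the designated donor edge (allo — default: the
  edge above the clade of all congeners, matching a donor basal to
  parthenogenetic plus outcrossing species) or as sisters of their
  conspecific copies (auto); `noise_nni` random NNI moves perturb each
  tree. No sequence evolution, branch lengths, or incomplete lineage
  sorting.
* **Aligned pairs.** Site-independent substitutions at the designed JC
  divergence; no rate heterogeneity or indels.

Passing recovery tests therefore demonstrates correct inference under the
designed generative models, not robustness to the full noise structure of
real sequencing data.

## Problem sizes

Recovery suites use 5,000-site spectra over 50 seeds per class, a 10-leaf
tree with 200 families for gain-node recovery, and 100 replicates of 100
gene trees per origin scenario; oracle suites enumerate all ≤ 6-leaf Dollo
cases on five topologies, all 3–4-leaf gene-tree shapes (plus 300 sampled
5-leaf cases) over a 3-leaf species tree, all 2×2 tables with total ≤ 12,
and all 3-vs-3 KS comparisons on a fixed grid. These sizes were chosen to
make the combinatorial checks exhaustive where cheap and well-sampled
where not.

## Known limitations

* The ploidy classifier is peak-based; it does not fit mixture models and
  cannot call aneuploidy or per-contig ploidy.
* The origin test assumes one donor/one polyploidisation event; multiple
  simultaneous hybridisations are out of scope.
* Contaminant flagging is a hard identity rule; genuinely recent
  transfers with > 70% identity to the donor are misclassified by design.
* Dating has no confidence intervals and assumes strict linearity of
  divergence in calendar time per generation.
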