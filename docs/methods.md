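# Methods

This note records the models, conventions and numerical choices behind
`nirtools`, in the order data flows through the package.

## Trees, supports, edges

Trees are rooted, with branch lengths in expected substitutions per site.
Internal nodes may carry an (SH-aLRT, UFboot) support pair, both percents
in [0, 100], stored on the child node of each edge (the usual newick
convention); re-rooting is out of scope, so supports never need
remapping. The slash-joined label dialect (`"80/95"`) is the default
because that is what tree-inference tools emit when both measures are
requested; a single-value dialect stores its number in the UFboot slot
and leaves SH-aLRT absent, and `extract_supported_clades` accepts
`sh_min=None`/`uf_min=None` to skip a missing component.

Edges are numbered depth-first in preorder from the root. This matches
the `{n}` edge-tag habit of jplace files and makes synthetic jplace
output deterministic; files whose tags disagree with preorder are still
read faithfully (the tags win).

The newick reader/writer is a small recursive-descent implementation
because two required dialect features — slash-pair supports and jplace
curly-brace edge tags — fall outside standard newick libraries. The
writer emits a canonical form (lengths trimmed to six decimals), and the
reader/writer pair is the identity on canonical strings.

**Zero-length branches** are replaced by one tenth of the smallest
positive edge before any depth-based statistic. The rule is idempotent
and errs when no positive edge exists (no reference scale).

**Clade extraction.** A node qualifies at SH-aLRT ≥ 80 and UFboot ≥ 95
(both configurable). Without seeds the maximal qualifying nodes are
returned, so clades are disjoint by construction. With seeds — the
field's clade names are curated knowledge, not inferable from supports —
each named clade is the *smallest* qualifying node containing the seed
tips; a seed whose only containing node is the root is rejected rather
than silently producing a trivial clade. Overlapping named clades are an
error unless nesting is made explicit by the caller.

## consenTRAIT τ_D and Glass' D

τ_D is computed by a root-ward scan: a clade qualifies when at least
`share_threshold` (default 0.90) of its non-missing tips are positive and
it contains at least two positive tips; qualifying nodes nested inside a
qualifying ancestor are absorbed (maximality). Each maximal clade
contributes its mean node-to-tip distance; each positive tip outside all
such clades contributes half its terminal branch length, following the
original reference implementation's singleton rule (exposed as
`include_singletons`, default on). Missing trait entries are pruned from
the tree before any count or depth is taken — dropping them from both
numerator and denominator avoids the bias either imputation would
introduce. τ_D scales exactly linearly with a uniform branch-length
rescaling and is invariant to tip order.

The null shuffles trait values uniformly across scored tips, preserving
prevalence; 1000 permutations by default (200 in the calibration
experiments, where thousands of τ_D evaluations are nested inside an
outer loop). The null is computed on the best tree only; bootstrap trees
enter the observed side. The alternative — rebuilding the null per
bootstrap tree — multiplies cost by the bootstrap count while leaving the
numerator of the effect size unchanged in expectation.

Glass' D = (mean τ_obs − mean τ_null) / sd(τ_null), with the *null* SD in
the denominator (the control group sets the scale). A numerically
constant null (SD at float-rounding magnitude relative to its mean) is
reported as undefined rather than as a noise ratio; traits fixed across
tips end up there. `contrast_trees` flags a trait as gene-associated when
D_gene > D_org + margin and D_gene > 0; the margin defaults to 0 (strict
inequality) and is exposed because the biological reading of "larger"
may reasonably require a buffer.

## Tree-constrained Mantel test

The statistic is the Spearman correlation of the vectorised upper
triangles; undefined (NaN) pairs are excluded from the observed and every
permuted correlation. The p-value is permutational with the add-one
correction, one-sided for positive association by default (two-sided by
flag). Ranks are computed once on the condensed vectors; a label
permutation only reorders a symmetric matrix, so permuted statistics are
Pearson correlations of permuted rank vectors — this keeps 1000×999
permutation experiments affordable.

The phylogenetic restriction follows the weighted-transposition
(Lapointe–Garland) construction: swap weight w(i,j) = 1 − s·ĉ(i,j), with
ĉ the cophenetic distance min-max scaled to [0, 1] and s the restriction
strength (default 0.9, s=0 reduces to free permutations). A permutation
is assembled from ⌈N log₂ N⌉ weighted transpositions; each is verified to
be a bijection. On a star tree all weights are equal and the restricted
null coincides with the free null — a property the tests check. The
construction is documented and parameterised rather than asserted
identical to any particular prior implementation.

## Placement filtering, BWPD, composition

Read mass is the like_weight_ratio; distal/pendant lengths are carried
through I/O but play no role in mass accounting. An edge belongs to a
group iff *all* tips below it belong to that group; boundary edges count
toward no clade but toward the ingroup. A read counts toward a group when
its in-group mass fraction is ≥ `min_mass` (default 0.95) **and** its
outgroup mass is zero within 1e-12 — the zero-outgroup rule is mandatory,
so an outgroup clade must be defined. "Mass" rather than raw
log-likelihood is the filtering currency because that is what placement
mass fractions express; the alternative reading (raw likelihood) is noted
but not implemented. Query fragments are assumed pre-truncated to 150 nt
upstream; that is an input contract, not an operation.

Sensitivity is the fraction of true ingroup reads retained for any
ingroup group; specificity the fraction of true outgroup reads *not*
retained for an ingroup group. Reads whose entire mass sits in the
outgroup are reported under the reserved `outgroup` group.

BWPD_θ = Σ_e λ_e (2 min(m_e, 1−m_e))^θ with m_e the fraction of total
mass distal of edge e; θ defaults to 1 (the exponent is exposed since the
one-parameter family admits any θ ∈ [0, 1]). At θ=0 the statistic is the
classical PD of the mass-spanning subtree: edges with mass strictly on
both sides count fully, with a 1e-12 tolerance on the membership test
because float summation order can leave an all-mass-below edge at
1 − 2⁻⁵² instead of exactly 1.

Rarefied composition draws `depth` placements (default 15) without
replacement `n_rare` times (default 100) via the multivariate
hypergeometric distribution; samples below the depth are flagged excluded
rather than extrapolated. Per-edge environmental correlations are
Spearman, pairwise-complete over samples, with edges under `min_n=5`
complete pairs reported as insufficient rather than dropped.

## Community statistics

δnir = 10⁹ (nirK − nirS) / (total reads × 150 bp). The read length is a
constant 150 by default — the truncation length, not the sample's native
read length — and algebraically δnir ≡ per_gb(nirK) − per_gb(nirS) at
that length, an identity the tests verify to 1e-9. The index is defined
for every sample, including zero counts.

"Pairwise comparison of ranks following Kruskal–Wallis" is implemented as
Dunn's test (joint-rank z statistics with tie correction), the standard
reading; pairwise Mann–Whitney is available by flag. BH adjustment runs
across all pairs of one comparison. Biomes under a sample-count floor
(e.g. 10) can be excluded and are reported. The clade–trait screen is a
global Pearson chi-square plus per-cell adjusted standardized residuals
(O−E)/√(E(1−row/N)(1−col/N)), two-sided normal p, BH across the cells of
the table — the correction scope is per table, a documented choice since
only the α = 0.05 level is fixed by convention. Zero expected counts are
an error advising category merge; >20 % of cells under expected 5 sets a
warning flag on the result instead of failing.

## Synthetic data: what it emulates, what it does not

The generators encode the study conditions the statistics are calibrated
under. Trees are pure-birth (Yule): downstream statistics consume only
topology and branch lengths, and the Yule expectation
E[height] = Σ_{k=2..n} 1/(kλ) gives a closed-form check; extinction adds
nothing the statistics would see. Bootstrap stand-ins jitter branch
lengths with a *mean-one* lognormal (σ = 0.10) and apply a bounded number
of NNI moves (default 2), so Robinson–Foulds distance to the source is
≤ 2·nni_count; supports on rearranged nodes are dropped. One hundred
replicates by default, mirroring standard bootstrap counts.

Traits are planted (`clade_gain`: up to `n_trait_clades` disjoint clades
whose mean node-to-tip depth is nearest the target, plus an optional flip
noise) or evolved (`markov_switch`: two-state chain with closed-form
transition probabilities, root state drawn from the stationary
distribution a/(a+b) unless fixed). Placement uncertainty is mass leakage
to topologically adjacent edges — the minimal mechanism that exercises a
mass-fraction filter; it does not model alignment error or HMM score
noise. Metagenome counts are negative-binomial (dispersion 2 by default,
Poisson as the `dispersion=None` limit) around biome-specific per-Gb
effects scaled by log-uniform sequencing depth with a 100 000-read floor;
default effects mirror the reported global structure (terrestrial
nirK:nirS ≈ 19:1, marine ≈ 34:1, engineered slightly nirS-dominant).
Covariates act linearly on log-means. None of this emulates read-level
error, chimeras, or biome label noise, so passing calibrations bound what
the methods do under clean, correctly specified inputs — not their
robustness to upstream artefacts.

Every generator draws from an independent stream spawned from
`SimConfig.seed` (fixed spawn keys per operation), so outputs are
bit-reproducible and regenerating one artefact never shifts another.

## Problem sizes and numerical conventions

The calibration experiments use 200-tip trees for depth recovery (5
planted depths × 20 trees), a 100-tip tree with 100 bootstrap replicates
and 200-permutation nulls for Glass'-D calibration (50 null + 50 planted
traits), 20-label matrices with 999 permutations × 1000 simulations for
Mantel size, and 1000 two-group simulations (n = 20 per group) for the
Dunn test — sizes at which the Monte-Carlo standard errors are small
relative to the acceptance bands while the whole battery remains a
desk-scale computation. Spearman statistics are pinned to ±1 when within
1e-12 of the bound (tied rank vectors are identical up to float noise).
Distance matrices must be symmetric to 1e-12 with an exactly zero
diagonal. Glass' D uses ddof=1 for the null SD.

## Known limitations

- Clade extraction never invents nesting; hierarchical clade systems must
  be expressed through seeds by the caller.
- The restricted-permutation Mantel null is one defensible construction
  of a qualitative description; its exact null distribution depends on s
  and the proposal count, both exposed.
- `contrast_trees` computes the null on the best tree only (see above);
  with very few bootstrap replicates the observed mean is noisy.
- BWPD orientation (the "distal" side) is fixed by the root; the
  statistic is only re-rooting-invariant across edges carrying mass
  fraction 0 or 1.
- The placement simulator leaks mass only to adjacent edges; real
  placement clouds can be multimodal across distant clades.
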