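# Methods

## The profiling rule

The profiler is a two-node binary decision tree applied to each molecule's
descriptor row: accept if `RDF070m ≥ 13.31`, else accept if
`UI ≥ t_UI` (3.95 for the permissive DT1 profile, 4.13 for the stringent
DT2), else reject. Both comparisons use ≥, so a row exactly at a
threshold is accepted; because the two profiles differ only in the UI
cut, DT2's accepted set is nested inside DT1's on any collection. Each
accepted molecule is attributed to the rule that admitted it (`RDF` at
the root, `UI` at the fallback), which makes the accepted set's flag
ratio a useful diagnostic of what a given deck is rich in.

## Descriptors

**Unsaturation index.** `UI = log2(1 + b)` with `b = Σ_bonds π* − B`,
where π* is the conventional bond order (single 1, double 2, triple 3,
aromatic 2) and B the bond count of the hydrogen-explicit graph. Every
single bond contributes π* = 1 and cancels against B, so b counts one per
double/aromatic bond and two per triple bond and UI is invariant to
hydrogen addition. Two representational choices are forced by this
definition and fixed package-wide:

* aromatic rings carry aromatic bond order, never a Kekulé alternation
  (benzene must contribute b = 6, not 3);
* hydrogens are explicit throughout the graph model, so B is the
  H-explicit bond count (aspirin: B = 21, b = 8, UI = 3.17).

Because UI is a step function of an integer count, its thresholds map to
discrete multiple-bond counts: the smallest b with `log2(1+b) ≥ 3.95` is
15, with `≥ 4.13` it is 17 (`min_multiple_bonds_for_ui`).

**Radial distribution function.** `RDF(r) = f Σ_{i<j} A_i A_j
exp(−B_s (r − r_ij)²)` over unordered atom pairs, with A the standard
atomic weights in amu, r_ij the Euclidean distance in Å, and constants
f = 0.007, B_s = 100 Å⁻², r = 7.0 Å (RDF070m) or 8.0 Å (RDF080m), held in
`RdfParams`. The weighting uses unscaled atomic masses: f = 0.007 ≈
1/12.011² effectively expresses the pair product in carbon units, which
is what puts drug-like molecules on the 0–25 scale the 13.31 threshold
assumes; carbon-scaled masses combined with f = 0.007 would shrink values
~144-fold. Hydrogens are included in the pair sum by default
(`include_h`); their mass products are small but nonzero, and whether the
original descriptor implementations included them is not documented, so
the flag is exposed.

RDF descriptors are conformer-dependent. Input 3D coordinates take
priority; otherwise one conformer is generated deterministically per
(molecule, seed) by ETKDG distance-geometry embedding followed by MMFF94
relaxation (UFF for atoms outside MMFF coverage), default seed 42,
exposed as a CLI flag. Different seeds may legitimately give different
RDF values; identical seeds reproduce coordinates bit-for-bit. No
published coordinate-generation protocol exists for the thresholds, so
absolute transferability across embedders is an open caveat — the
package's own thresholds, seeds and embedder are at least internally
consistent and reproducible.

**ATS8m.** Broto–Moreau autocorrelation at topological lag 8 with
carbon-scaled masses: Σ over heavy-atom pairs at bond-path distance 8 of
(m_i/12.011)(m_j/12.011). This is the standard topological definition; a
geometric variant (pairs within 0.5 Å of an 8 Å Euclidean distance) is
available behind a flag because descriptions of this descriptor sometimes
speak of an 8 Å inter-atomic distance. ATS8m is informational — the
shipped profiles do not use it, it exists because it is the main
alternative root descriptor that consensus training surfaces.

**Counts and physico-chemical properties.** nBM/nAB count multiple and
aromatic bonds, nBnz counts six-membered all-carbon aromatic rings. The
seven-property profile (MW, logP, TPSA, HBD, HBA, nROT, nRIG) delegates
to RDKit's standard implementations on the heavy-atom graph: Crippen
atom-contribution logP (pluggable — published logP estimators disagree,
and the ADMET band −5 < logP < 6 is wide enough that the choice rarely
flips a verdict), Ertl TPSA, N–H/O–H donor and N+O acceptor counts, and
the rotatable-bond SMARTS with amide C–N excluded. nRIG is defined as
heavy-atom bond count minus nROT.

## ADMET pre-filter

Deliberately soft ranges: 100 < MW < 900, 0 ≤ HBD < 8, 0 ≤ HBA ≤ 12,
−5 < logP < 6, 0 ≤ nROT < 20, 0 ≤ TPSA < 160, plus at most one Lipinski
rule-of-five violation (MW > 500, logP > 5, HBD > 5, HBA > 10). Strict
inequalities are honored exactly as written (MW = 900 fails). The count
ranges admit zero — zero H-bond donors is not a plausible exclusion
criterion for drugs — and the HBA bound is read as ≤ 12. The Lipinski cap
is applied on top of the ranges; it can only bite via the HBD 6–7 /
HBA 11–12 corner that the ranges permit. Verdicts list every failed rule.

## Screening metrics

`EF = [TP/(TP+FP)] / [(TP+FN)/N]` — precision over active prevalence,
algebraically equal to sensitivity divided by selected fraction; EF = 1
for random-rate selection and at most N/(TP+FN) (reached exactly when
specificity is 100%). An empty selection returns EF = 0 with a warning
rather than an error, because degenerate splits during tree induction
need a defined, minimal value. Sensitivity/specificity on zero actives or
zero inactives raise instead of returning NaN. Display rounding follows
screening-report convention — half-up to integers for Se/Sp percentages,
two decimals for EF — with raw floats always retained in machine output.

## Enrichment-tree induction

Preprocessing culls a descriptor block in three fixed stages: drop
zero-variance columns; group columns with |Pearson r| > 0.9 (connected
components of the correlation graph) and keep each group's member with
the smallest Welch two-sample t-test p-value between classes; drop
remaining columns with p > 0.2. Welch rather than pooled-variance is the
default because descriptor variances routinely differ between actives
and inactives; pooled is available.

Splits maximise the enrichment factor of the ≥-side treated as a selected
subset, over candidate thresholds at midpoints between consecutive
distinct sorted values. Equal EF implies equal precision, so ties are
resolved toward the split selecting more observations (same purity,
higher recall), hence toward the smaller threshold. A split is rejected
when either child would hold fewer than `min_leaf` observations
(default 5) or when no candidate achieves EF > 1. Leaves are labeled
positive when their contained actives are enriched relative to the full
training table (leaf EF > 1); this makes a two-descriptor tree reproduce
the profiler's OR semantics. Depth is capped at 3 by default — the
shipped profiles have depth 2.

Consensus training grows one tree per training portion of k stratified
cross-validation folds (default k = 20; stratification is required
because rare-positive tables would otherwise produce positive-free
folds). Position by position, a node is kept when a strict majority of
contributing folds agree on its descriptor, with the threshold set to the
modal value across those folds (a tie between modes, including the
all-distinct case, falls back to the median of the tied modes — float
thresholds are rarely exactly equal). The per-fold report retains every
fold's choices so minority alternatives remain visible.

**Known limitation — threshold recovery under label noise.** With any
label-flip noise, the EF criterion is biased upward at the root: a flip
inside the true ≥-region leaves some shorter suffix perfectly pure, and a
pure suffix's EF (1/prevalence) strictly exceeds the true threshold's
((1−noise)/prevalence). The induced root threshold therefore tends to
land above a planted cut whenever noise is present, however the data are
distributed. On noise-free tables recovery is exact (tested); the noisy
recovery property in the acceptance suite documents this bias honestly
rather than masking it. Consensus over folds does not remove the bias,
since all folds share the same flipped labels. Practical use of the
learner should treat induced thresholds as conservative (high-precision)
estimates and, as with any enrichment-driven rule, inspect the per-fold
report before adopting a threshold.

## Diversity clustering and applicability domain

Fingerprints are hashed path-based (Daylight-like) 2048-bit vectors.
Clustering is complete-linkage agglomeration on Tanimoto distance
(1 − similarity) cut at 1 − 0.8, which guarantees every within-cluster
pair keeps similarity ≥ 0.8 — the defensible reading of a "diversity
criterion of 0.8"; the representative is the member with the highest mean
within-cluster similarity, ties by input order. The applicability-domain
check standardises descriptor tables on a reference set, projects both
sets onto the leading principal axes (default 3), and flags query points
whose coordinates all fall within the reference min/max envelope — the
simplest quantitative rule consistent with a visual overlap check;
loadings are orthonormal and full-axis reconstruction is exact to
numerical precision.

## Synthetic data generator

`make_molecule` assembles molecules from a fragment grammar on an
sp3-carbon scaffold: each benzene ring adds exactly 6 to the
multiple-bond count, each carbonyl adds 1, alkyl linkers add 0 — so the
generated molecule's b equals the requested target exactly and its UI is
known in closed form. Scaffold shapes (linear chain / branched chain /
four-armed star) change the 3D placement of fragments without touching
UI; star scaffolds put more atom pairs near the 7 Å shell and score
higher RDF070m than equally unsaturated linear chains, which the tests
assert as a median ordering only. RDF ground truth is never planted,
because it is conformer-dependent. Deck defaults: 60 molecules, target b
uniform on [0, 30], shape mix 0.4/0.3/0.3 linear/branched/star, seed 42.

`make_labeled_table` plants a two-descriptor OR rule
(X ≥ 10 or Y ≥ 4) with label flips at a configurable rate
(default 5%, capped below 50%). X is continuous and RDF-like
(Gamma(4, 2.5): mean 10, sd 5, so the cut sits in the bulk of the
distribution); Y is UI-like, log2(1 + Poisson(10)) on the coarse grid a
count-derived descriptor actually lives on; two irrelevant columns (one
uniform, one Gaussian) give preprocessing and induction something to
discard. Default table size 600 at ~25% positive prevalence — the scale
of a small curated learning set rather than an HTS deck.

What the generator does *not* emulate: real chemistry (the molecules are
valence-correct but synthetically meaningless), realistic descriptor
correlations beyond the UI/count identity, assay noise structure
(flips are independent and symmetric), or the class imbalance of real
screens (~1% hit rates). Passing tests therefore demonstrate the
correctness of the descriptor definitions, rule logic and learner
mechanics — not field performance on real collections.

## Numerical conventions and degenerate inputs

Multi-fragment input records keep the largest covalent component
(logged). Unparsable records carry their line/record index and can be
skipped or aborted on, per caller. Molecules that fail 3D embedding are
excluded from conformer-dependent descriptors and counted as failures in
reports; a profiling run never aborts on a single bad molecule. RDF of a
single atom is 0; ATS8m of a graph with diameter < 8 is 0; splits on
constant columns return no-split; metrics on empty classes raise.
Report-level percentage rounding is half-up; all machine outputs keep
full precision.
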