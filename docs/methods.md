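# Methods

## The residue interaction network

A structure is reduced to its standard amino-acid residues (first model
only; waters, glycans and hetero groups removed; for alternate locations
the highest-occupancy conformer wins, ties broken by altloc letter).
Atoms are classified main-chain (N, CA, C, O, OXT, plus backbone
hydrogens) or side-chain; author residue numbering is kept verbatim, which
for the FVIII structure 2R7E coincides with legacy mature-protein
numbering.

Two residues are connected when at least one heavy-atom pair lies within a
distance cutoff, default **5.0 Å**. Contact detection uses a k-d tree but
is contractually identical to the all-pairs scan (and tested against
one). Excluded pairs: intra-residue pairs, the peptide-bond C(i)–N(i+1)
pair of sequence-adjacent residues, and disulfide SG–SG pairs under
2.5 Å. Hydrogens present in a file are kept for chain-part bookkeeping but
never enter distance or surface calculations; the ~5 Å heavy-atom cutoff
subsumes typical hydrogen-mediated contacts. This distance rule is a
deliberate replacement for probe-rolling contact detection (as in
RINerator-style tools): the probe algorithm is not specified in
reproducible detail, while a cutoff is exact, configurable and recorded in
the graph's provenance. Consequence: on real structures the node count is
reproduced exactly but the edge count only approximately, so edge counts
are treated as indicative.

Edges are unweighted; each carries the set of interaction classes observed
(mc_mc, mc_sc, sc_sc) and the minimum qualifying distance. Duplicate
contacts merge (union of classes, minimum of distances), self-contacts are
dropped, and contact-free residues stay in the graph as isolated nodes so
the node count always equals the residue count. Inter-chain contacts are
included: the molecule is analysed as one network.

## Centrality measures

All seven measures are always computed; the observation that three
(degree, betweenness, closeness) suffice to describe protein RINs is
reported through the correlation matrix, not enforced.

| measure | convention |
|---|---|
| degree | neighbour count |
| betweenness | Brandes pair-dependency counts, unnormalised, each unordered pair once |
| closeness | (n_comp − 1) / Σ d(v,u) within v's component; isolated nodes 0 |
| Burt's constraint | p_ij = 1/degree(i); undefined (NaN) for isolated nodes |
| PageRank | damping 0.85 (configurable), uniform teleport, tolerance 1e-12, ≤10,000 iterations |
| k-core | largest k with the node in the k-core |
| authority | HITS by power iteration on the full adjacency from the uniform vector, tolerance 1e-12, max-normalised |

Component-wise closeness avoids infinite distances while preserving the
ranking inside the giant component; NaN constraints propagate into the
classifier's missing-row filter, mirroring the "drop examples with any
missing attribute" preprocessing rule. On disconnected graphs the HITS
power iteration concentrates mass on the spectrally dominant component —
a deterministic, documented convention.

## Surface areas and relative exposure

Per-residue surface area is solvent-accessible area by Shrake–Rupley
quadrature: probe radius 1.4 Å, 960 golden-spiral points per atom (both
configurable), standard van der Waals radii by element. SASA was chosen
over solvent-excluded area because it has a standard, testable algorithm
and the downstream use is a monotone burial ranking; the two differ
smoothly for that purpose. Residue areas are sums of atom areas, so they
are additive to the structure total by construction. Quadrature error at
960 points keeps rigid-motion deviations under ~1%; tests that assert the
1% bound use 1920 points.

Relative exposure divides each residue's area by the reference area of the
same type in an extended Gly-X-Gly tripeptide (theoretical maxima,
shipped as a versioned CSV in `fviiirin/data/`, swappable for empirical
scales). Ratios are not clamped and can exceed 1 in extended
conformations.

## Criticality

HDHB / LDHB / LDLB groups use quantile thresholds on degree and
betweenness — high = 90th percentile, low = 50th, both configurable.
Quantiles make the partition scale-free and invariant under
rank-preserving transforms; descriptions of such groups in the literature tend to rest on
hand-drawn regions, which quantiles approximate reproducibly.
Super-critical residues are the Pareto front of (degree, betweenness,
closeness): v is in the front iff no u is ≥ v on all three and > v on at
least one. Exact ties on all three keep both nodes (no arbitrary
tie-break). A corollary worth noting: a *unique* maximiser of any single
measure is always in the front, but a tied maximiser can be dominated
through the other measures. Nodes missing a measure (isolated-node NaNs)
are excluded with a warning; on real structures the front is computed over
the largest connected component. Domain closeness summaries report
median and quartiles with the linear-interpolation convention (recorded in
the output metadata).

## Binding interfaces

Binding-site residue lists are inputs (TSV: partner, chain, position), not
constants — published site curations aggregate dozens of primary studies
and are inherently incomplete. The neighbourhood operation returns the
distance-1 network neighbours of the site union, minus the sites
themselves (shell radius configurable for exploration). Distribution
comparisons use the unpaired two-sided Wilcoxon rank-sum test: exact
enumeration when both groups have ≤25 members and the pooled values are
tie-free, otherwise the normal approximation with tie correction.

## Activity classifier

Mutant constructs are labelled High when chromogenic activity exceeds 50%
of wild-type and Low below it; exactly 50% is assigned Low (conservative;
configurable). Features default to the seven centralities (relative
exposure optional). Normalisation (z-score by default, min-max optional)
is fit on training folds only inside each model pipeline — no leakage —
a point on which informal descriptions of such pipelines are often
ambiguous.

The three members are an RBF-kernel SVM with probability outputs, Gaussian
naive Bayes (no tuned parameters) and gradient-boosted trees
(binary-logistic objective, 50 trees). Hyperparameters are selected per
member by mean out-of-fold Cohen's Kappa over ten stratified folds, AUC as
tie-break, with all randomness derived from one seed. A single CV layer
selects and evaluates; nested CV would roughly square the cost for little
benefit at these sample sizes, and the out-of-fold ensemble metrics remain
honest because the ensemble combiner has no tuned parameters.

Default (scaled-down) grids: SVM γ ∈ {0.05, 0.10, …, 1.50}; tree depth
∈ {1, 3, …, 25}; learning rate η ∈ {0.1, 0.3, 0.5}; L2 penalty λ ∈
{0, 0.5, 1}. The full granularity (γ step 0.01, every depth 1–25, η and λ
on the 0.1 lattice over [0, 1]) is available behind `full_grid=True` /
`--full-grid`; defaults keep a 400-instance, 10-seed study within minutes
on one CPU.

The ensemble prediction is the median of the three member probabilities;
label High at ≥0.5; flagged when the median falls inside the flag band,
default [0.4, 0.6] — a configurable operationalisation of "not clearly
predicted", reported in output metadata. Evaluation reports accuracy
(overall and on unflagged instances), Kappa = (p_o − p_e)/(1 − p_e), and
AUC as the rank statistic over median probabilities. Note that widening
the flag band raises unflagged accuracy only insofar as instances near
0.5 are genuinely the least reliable; it is a calibration property of the
probabilities, not an algebraic identity.

## Clinical sanitation and enrichment

Sanitation applies, in order: (1) keep Point/Polymorphism types with
Missense effect; (2) drop positions outside the mature protein (≤0 or
>2332); (3) drop ambiguous severity strings ("mild/moderate" etc.);
(4) drop stop-codon records; (5) bound substitutions ">5"→5, "<10"→10,
"<11"→11, "<1"→0 (the ">5" direction is odd — it caps values above 5 —
but is applied literally, matching the curation convention of these exports); (6) ranges "a to b" average to
(a+b)/2 unless the endpoints straddle a severity boundary (severe <1,
moderate 1–5, mild >5–40), in which case the record is ambiguous and
dropped; (7) drop non-numeric leftovers, missing activities, values >100
and disagreeing duplicate assays. Parsing is whitespace- and
unicode-tolerant (non-breaking spaces normalise away). Every record
appears exactly once in the log with the rule that kept, transformed or
excluded it; the procedure is idempotent. Severity bands are
configuration constants used only for the ambiguity rule — severity is
never re-derived.

Enrichment uses the two-sided Fisher exact test on the 2×2 table
{position group} × {has ≥1 reported mutation}, odds ratio by
cross-product with an infinity marker on zero cells. The legacy→HGVS
conversion adds the 19-residue signal peptide.

## Synthetic data: what it emulates, and what it does not

Structures are built from standard backbone internal coordinates (N–CA
1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; φ/ψ = −57°/−47° helical,
−120°/120° extended; ω = 180°), with one pseudo side-chain atom 2.4 Å
along the outward radial direction (tetrahedral bisector for the extended
fold) — enough to exercise main-chain/side-chain edge typing without
rotamer modelling. The ideal helix reproduces the characteristic
(i, i±1), (i, i±3), (i, i±4) contact pattern. The two-domain fold places
two helices a configurable axis separation apart (default 30 Å: zero
inter-domain contacts, hence a disconnected network). Optional Gaussian
coordinate jitter (seeded) breaks the perfect symmetry of the ideal
helix — without it some centrality columns (k-core) are exactly constant,
which the feature-table builder rejects by design. Classifier studies use
jitter 0.3 Å.

Activity labels are drawn with P(Low) = logistic(β·z), z the z-scored
chosen centrality, default β = 4 on closeness; percentages come from
triangular distributions (modes 10 and 90) conditioned on the drawn
class, so the 50% rule sees realistic spread. The exact per-instance
probabilities are recorded: the mean of max(p, 1−p) is the Bayes accuracy
bound against which classifier recovery is judged.

Clinical tables sample positions with odds multiplied by the enrichment
factor (default 3×) inside a designated harmful set, and plant a known
census of messy activity strings (default 7) covering every sanitizer
rule. The enrichment study uses 2000 candidate positions and 500
records: in this sparse-occupancy regime the position-level "has ≥1
mutation" odds ratio tracks the planted sampling odds (expected ≈3.4 for
3×); with denser occupancy the measurable odds ratio saturates upward and
would no longer reflect the multiplier.

None of the generators produce physically realistic folds, rotamers, real
mutational spectra or assay noise structure; passing recovery tests shows
the pipeline's statistics behave correctly under known ground truth, not
that predictions on real FVIII data reach any particular accuracy.

## Problem sizes and numerical choices

Routine runs and tests use: 20–40-residue structures for geometry checks;
random graphs of ≤40 nodes for oracle equivalence (50 replicates);
400-residue, 400-mutant classifier studies over 10 seeds with the
scaled-down grids; 100-replicate enrichment studies at 500 records each.
Tolerances: centrality oracle agreement 1e-8; PageRank/HITS iteration
1e-12; SASA oracle agreement 1%; contact and Pareto agreement exact.

## Known limitations

- Contact edges approximate probe-rolling contacts; edge counts on real
  structures differ from probe-based constructions by design.
- SASA stands in for solvent-excluded area; absolute exposure values are
  not comparable across the two conventions, rankings are.
- Binding-site starter lists shipped with examples are explicitly
  incomplete; real analyses should supply curated site files.
- The classifier's reported metrics carry a mild selection optimism from
  single-layer CV hyperparameter choice; the label-permutation null in
  the acceptance study quantifies it (mean Kappa ≈ 0 within ±0.15).
- Hydrogen placement, mmCIF input, NMR ensembles, conservation scoring
  and interactive visualisation are out of scope; networks export to
  GraphML/TSV/CSV for external viewers.
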