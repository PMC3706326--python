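# Methods

## Model and scoring

The metabolic network is an undirected bipartite graph: reaction nodes and
metabolite nodes, one edge per participation. Undirectedness is a modelling
commitment, not a shortcut — with a draft reconstruction there is no basis
for claims about flux direction, so nothing downstream may depend on it
(reversible and irreversible SBML reactions import identically). Ids are
opaque case-sensitive strings; compartment suffixes, if present, are part of
the id. Exchange and transport pseudo-reactions are ordinary reaction nodes.
Currency metabolites are *not* removed; they are handled entirely by the
connectivity weights below.

Reaction scores are the mean log2 fold-change of the reaction's measured
genes (flat mean; gene–protein–reaction boolean logic is ignored, and a gene
mapped to k reactions contributes fully to each). Reactions without a
measured gene receive the median of the data-derived scores, computed before
any direction flip, and are flagged `imputed`; modules consisting solely of
imputed reactions are excluded from significance testing, since nothing in
the data supports them. Down-regulation is handled by negating every
reaction score after imputation, so a single maximiser serves both
directions and the two directions are exact mirrors (bit-for-bit: the same
seed on negated data reproduces the up-direction result).

Metabolite weights are linear in connectivity, `w_m = −c · d_m`. The default
constant is

    c = 1.5 × SD(data-derived reaction scores)   (per unit of degree)

so the cheapest possible bridge — a degree-2 metabolite — costs 3 SD of
reaction score. The reasoning: in a network of ~10³ scored reactions the
largest single background reaction score expected by chance is about 3.1 SD,
so no lone background fluctuation can buy itself a metabolite, while a
handful of coordinately shifted reactions can easily pay for their shared
intermediates. Weaker penalties (we examined down to 0.1 SD per median
degree) let the search agglomerate unrelated strong singletons through
currency hubs; much stronger ones start splitting genuine modules at their
internal metabolites. `c` is a configuration knob and is logged with every
run.

## Search

The annealer's state is a binary on/off vector over all nodes. A *candidate
module* is a connected component of the on-subgraph containing at least one
metabolite — in a bipartite network reactions are only linked at all through
metabolites, and an isolated reaction is not a pathway. The objective is

    Σ (top-K positive candidate-module scores)  +  Σ (negative component scores)

with K the number of modules sought per direction (default 20). The second
term matters for search dynamics: lone metabolites and negatively scoring
blobs are actively charged, so the state cannot percolate into large
meaningless components (which would also make single-node updates expensive),
and what survives cooling is exactly the set of components that pay for
themselves. Proposals toggle one uniformly random node; the objective delta
is maintained incrementally (component merge on switch-on, connectivity check
with early-exit BFS on switch-off, a running top-K sum over component
scores). Worsening moves are accepted with probability exp(ΔS/T).

Schedule defaults: T0 = 1 SD of the reaction scores, geometric cooling at
0.9 over 60 temperatures, 4 × (number of nodes) proposals per temperature,
2 restarts (restart r is seeded with seed + r), best-ever state returned and
its objective recomputed exactly at the end. A 963-reaction network anneals
in under a second per direction on one core, and on networks small enough to
enumerate (≤ 14 nodes, 2^n subsets) the annealer attains the exhaustive
optimum in ≥ 95% of random instances — correctness is pinned by that oracle,
not by the schedule, and every schedule parameter is overridable.

Extraction takes the connected components of the best state, drops
metabolite-less and non-positive components, sorts by score (ties: more
reactions, then smallest reaction id) and truncates to the top 20 per
direction. Modules can be merged across a shared metabolite after the fact
(the bridge's weight is paid once, connectivity is verified, the merged set
is rescored) — the pattern needed when several small modules surround one
highly connected metabolite that the weighting rightly refused to include —
and extended to all metabolites adjacent to member reactions for context
display (extensions are never re-tested).

## Significance

Each tested module is compared with B = 1000 random *connected* node sets of
its exact (reactions, metabolites) composition, drawn by seeded random
growth (uniform random start of a needed type, then uniform random frontier
neighbours of needed types, restart on dead ends) and scored identically.
The empirical p is `(r + 1)/(B + 1)` with r the number of null sets scoring
at least the observed value, so p is never 0 and floors at 1/(B+1); in
reports a module sitting exactly on the floor is printed as an upper bound
("<0.004" when B = 249). Connected sampling is deliberate: observed modules
are connected, and unconstrained sets (available behind a flag) are a more
liberal reference for hub-adjacent compositions. Null distributions are
cached per composition with a composition-derived seed, so caching cannot
change results. Up- and down-direction modules form one multiple-testing
family per run (BH by default, Storey optional), called significant at
q < 0.05.

**Known limitation — selection bias.** The modules being tested were found
by *maximising* score, but the null sets are not maximised over; the
comparison is therefore anti-conservative, increasingly so for the
top-ranked modules. Under a global null (no planted signal) the pipeline
still extracts a handful of modules per direction and most of them reach
q < 0.05. Empirical module significance of this form should be read as a
ranking diagnostic, not a calibrated error rate; a calibrated alternative
would compare each rank against the same search run on score-permuted data,
at ~B times the search cost.

## Enrichment comparison

The conventional analysis: genes with |fold change| > 2 (strict) and
BH-corrected p < 0.01 (strict) form the DE sets; each pathway is tested by
the one-tailed Fisher's exact test for over-representation, computed as the
hypergeometric upper tail P(X ≥ overlap) on the 2×2 table against the gene
universe (all genes in the annotation by default). FDR uses Storey q-values
with π0 estimated at a single λ = 0.5, `π0 = min(1, #{p>λ}/((1−λ)m))`,
applied multiplicatively to the BH step-up values (plain BH available);
pathways with q < 0.05 are reported sorted by p. A gene in several pathways
counts in each.

## Synthetic data

The generator emulates a draft automated reconstruction at the scale of a
small bacterial genome: 963 reactions (one gene each, 10% left gene-less to
exercise imputation), ~960 ordinary metabolites attached 2–4 per reaction by
degree-biased draws, and 8 currency metabolites of exactly degree 12 — the
connectivity at which a promiscuous metabolite in a network of this size
starts bridging unrelated chemistry. Every ordinary metabolite has degree
≥ 2 (an intermediate with a single adjacent reaction is not mass-balanced;
dead-end draws get a second reaction, unused metabolites are dropped), a
bridging pass guarantees a single connected component without touching
currency degrees, and the resulting metabolite degree distribution is
right-skewed with the hubs as maxima.

Planted modules are pathway backbones: n reactions chained through fresh
dedicated intermediates (consecutive groups share a linker reaction), default
composition 8 reactions / 2 metabolites. Expression is simulated at replicate
level — 3 replicates per condition, per-replicate noise set so the
fold-change estimate has SD `noise_sd` (default 0.5), genes of planted
reactions shifted by ±`effect_size` (default 2, i.e. 4-fold) — and p-values
come from a plain two-sample t-test, so the DE filter and BH stages see
honest p-values. An optional mode makes 16% of background genes responsive,
emulating a genome-wide stress response for specificity testing.

What the defaults do and do not show: at effect 2 / noise 0.5 the planted
module is recovered as the top module (Jaccard ≥ 0.8 against truth) in ~18–19
of 20 seeds; the misses are seeds where the noise genuinely leaves part of
the backbone unsupported (the fragmented state scores above the truth, and
the search correctly finds it). A 4-fold mean change is, however, *below*
what a 3-replicate t-test can push through BH at q < 0.01, so fixtures that
exercise the DE filter and the enrichment comparison use effect 6–8
(64–256-fold), the magnitude real strong stress responders show. Real data
differ from the simulation in ways that matter: moderated test statistics
upstream, correlated genes within operons, multi-gene and multi-reaction
mappings, and far higher-degree currency metabolites than the synthetic
hubs — passing these tests demonstrates algorithmic correctness, not field
performance.

## Numerical and reporting choices

Thresholds are strict inequalities, matching the conventions ">2-fold" and
"<0.01". Module tables print q to 2 significant figures with the "<floor"
rule above; scores print at 4 decimals; all tabular outputs are
byte-reproducible from the configuration (a mandatory integer seed, no
wall-clock seeding anywhere). Tie-breaks in ranking and all sampling orders
are derandomised (sorted candidate lists) so results are identical across
processes regardless of hash randomisation. Degenerate inputs fail loudly:
empty networks, all-unmeasured score tables, non-positive weight constants,
infeasible null compositions, p-values outside [0, 1].
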