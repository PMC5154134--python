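# Methods

This note records the models implemented in `genokit`, the defaults and why
they are what they are, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Ontology representation and information content

Every knowledge collection — structured ontology or flat term list — is a
rooted DAG of terms with `is_a` (child → parent) edges. Only `is_a`
relations are honoured; other OBO relation types are ignored, since all
downstream machinery treats the ontology generically as a DAG. A flat
collection, or any parsed graph with multiple sources, receives an
artificial root (`GK:ROOT`) linking all top-level terms, so propagation, IC
and MICA work identically on both kinds.

Annotation propagation follows the true-path rule: `propagated[t]` is the
union of direct annotations over the subtree below `t`, computed in one
reverse-topological sweep (children before parents), which makes
propagation idempotent and guarantees `propagated[parent] ⊇
propagated[child]` for every edge.

Information content is `ic[t] = −log10(|propagated[t]| / |universe|)`, in
base-10 log units exactly. The universe defaults to `propagated[root]`
(every annotated entity); an explicit background can widen or restrict it —
this covers both readings of what the annotation universe should be when the
source data do not pin it down. Terms with no propagated annotations carry
no IC. The MICA of two terms is the common ancestor (ancestor sets include
the term itself) of maximal IC, ties broken lexicographically on term id;
every tie-break in the package is lexicographic and every sort stable, so
all outputs are deterministic.

## Enrichment

The overlap table is (N background, M term entities in background, k input
entities in background, x overlap). The three tests are one-sided for
enrichment: Fisher = inclusive hypergeometric tail P(X ≥ x); hypergeometric
= strict tail P(X > x); binomial = P(Bin(k, M/N) ≥ x). The strict-vs-
inclusive split is the only reading under which the hypergeometric test
always reports a smaller p than Fisher. Against the binomial the comparison
is tail-dependent: throughout the significance regime (Fisher p below ~0.1,
k ≥ 2) sampling without replacement thins the tail and
p_fisher < p_binomial exhaustively for all tables with N ≤ 15, but near the
null mean the binomial can dip below Fisher, and at k = 1 the two laws
coincide exactly (with one draw, replacement is irrelevant). The acceptance
checks therefore assert the strict-tail inequality everywhere and the full
triple ordering on the significance regime.

Term-size bounds default to [10, 2000] propagated entities within the
background — standard practice for gene-set testing; both bounds are
configurable and the tests on small fixtures lower `min_size` explicitly.

Tree-aware mode processes terms in reverse topological order. A term whose
raw p at the elimination stage is below `alpha_elim` (default 0.05) claims
its input-overlapping entities; every ancestor is subsequently tested with
those entities removed from both its overlap x and its annotation count M.
Raw p (not adjusted) drives elimination: the eliminated-stage decision is
local and sequential, and adjusting within a partially processed traversal
would make the procedure order-dependent. Reported counts, fold changes and
member lists are the post-elimination ones, so what is printed is what was
tested.

The redundancy filter for flat collections scans records in ascending-p
order. B is flagged iff `|B∩A|/|B| > c1` (default 0.90) and `|A∩B|/|A| > c2`
(default 0.50) for some already-retained A; flagged records are excluded
from later service as A. Retained-only comparison keeps the procedure a
single deterministic pass; the alternative (comparing against all
significant A's, flagged or not) can only flag more, and the c1/c2 defaults
sit where flagging is monotone in c1 (raising c1 can only unflag).

FDR uses Benjamini–Hochberg step-up, FWER uses Bonferroni — the standard
procedures for those error rates; both order-preserving and clipped to 1.

## Semantic similarity

Entity profiles keep two layers: the directly asserted terms and the full
ancestor closure. The best-matching formulas run over the **direct** term
sets (sizes n1, n2); inherited terms enter only through the MICA machinery.
Running them over the closed sets instead would put the root in every
profile, and since the root's best-match IC is identically 0, the complete
(minimum) rule would collapse to 0 for every pair — so the direct-set
reading is the only one under which the three rules behave comparably.

With best-match vectors bm12 (each t1's max MICA-IC against T2) and bm21:
average = mean of the two directional means; maximum = the larger
directional mean; complete = the minimum over all best-match values. The
averages grow with annotation density, the minimum does not, hence complete
is the default. Self-similarity is defined (complete = the entity's least
informative direct term's IC) but never emitted as an edge. Terms lacking
IC are dropped from a profile with a warning; a profile with no IC-bearing
terms cannot be compared.

## SNP → gene → subnetwork

SNP score: `r2 × (log10((1−p)/p) − log10((1−p_thresh)/p_thresh))`, with
`p_thresh` = 5e-8 (genome-wide significance) and lead SNPs at r2 = 1. The
formula is negative for sub-threshold SNPs; scores are truncated at 0 so
such SNPs contribute no prize. P-values are floored at 1e-300 to keep the
logit finite for association p printed as 0.

LD expansion retains proxies with R² strictly above 0.8. Proxies inherit
the p-value of their lead (the scoring formula has one P per SNP, with R²
as the attenuation for the proxy's indirect evidence); a proxy linked to
several leads keeps the most significant lead, ties broken by larger R².
Proxies without a known position are dropped with a summary warning.

Gene score: over all SNPs within distance d ≤ D of the gene span (d = 0
inside, measured base-to-base from the span edge), take the **maximum** of
`Score_SNP × (1 − d/D)^λ` — only the most informative SNP counts, so stacks
of interdependent SNPs in one LD block cannot inflate a gene. Defaults
D = 50 kb and λ = 2 give conservative near-gene weighting; both are
exposed on the API and CLI. Spans, not TSSs, define proximity.

Subnetwork search is a prize-collecting Steiner-tree heuristic in the
shift–collapse–connect–prune family: node scores are shifted by a baseline
(so weak genes carry negative prizes), positive nodes are joined by a
Steiner/minimum-spanning tree under edge costs `(cost(u)+cost(v))/2 + ε`
where `cost(v) = max(0, −shifted(v))` (the ε = 1e-9 per-hop cost resolves
zero-cost ties toward fewer linkers), and an exact dynamic program on the
resulting tree extracts its maximum-weight connected subtree. The result is
compared against the best single positive component and the better kept, so
the returned subgraph is always connected, never keeps a strictly negative
leaf, and never scores below the best single positive node. On random
graphs of ≤ 10 nodes the heuristic matches the exhaustive optimum on ~99%
of instances and never exceeds it. A requested size is met by bisecting the
baseline (size decreases as the baseline rises) for up to 20 iterations;
if the exact size is unreachable the closest achieved size is returned with
a warning.

## Region enrichment

Coordinates are half-open 0-based (BED-native) throughout; all region sets
are merged per chromosome before any arithmetic, so duplicated or
overlapping input intervals cannot double-count bases. Strand is ignored.
Input falling outside the background is clipped with a warning.

Binomial mode: trials n = input bases in background, success probability
q = annotation bases in background / background bases, observed x = overlap
bases; p = P(Bin(n, q) ≥ x), BH-adjusted across tracks. Trials are bases,
not regions — the test is at base resolution.

Sampling mode: each of B iterations re-places every input interval
uniformly at random among all positions where it fits inside the
background, preserving its length and its chromosome whenever the
background covers that chromosome (chromosome-level composition is part of
the null; no finer structure is invented). Empirical
p = (1 + #{null ≥ observed})/(B + 1); a z-score against the null mean/sd is
reported. On a single contiguous background with short intervals the null
mean converges to the binomial expectation n·q, which the acceptance run
checks within 3 Monte-Carlo standard errors.

Nearest-gene mapping returns **all** genes within the distance gap of each
region (window semantics, overlap = distance 0), not the single closest —
the pooled gene set is what downstream ontology enrichment consumes, and a
region sitting between two equally near genes should implicate both.

## Trait taxonomy

Cumulative gene-score difference is read as the L1 distance over the union
of scored genes (missing genes score 0) — the only arithmetic matching
"cumulative difference", and a true metric. Neighbour joining is the
classic Saitou–Nei agglomeration with two deterministic conventions: Q-
criterion ties break on the lexicographically smallest label pair, and a
negative limb length is clamped to 0 with the deficit transferred to its
sibling limb (path lengths preserved). NJ is exact on additive distances,
which the tests exploit as the module's oracle; an independent NJ
implementation (scikit-bio's) serves as a cross-check on random inputs.

"Consensus" is constructed as a gene-column bootstrap: columns (canonically
sorted by gene label, resampled by position) are drawn with replacement B
times, each replicate's distances feed NJ, and splits appearing in more
than half the replicates form the majority-rule consensus topology.
Internal edges carry their support fraction and the mean length over
replicates containing the split; leaf edges the mean over all replicates;
B = 1 reduces exactly to the single NJ tree. The tree is emitted unrooted
(trifurcating root) in Newick, supports as internal-node labels. All
scored genes enter by default; a minimum-score filter is available on the
CLI.

## Synthetic data generator

One seed deterministically produces: a random rooted ontology DAG (each
term one parent, 10% a second parent — diamonds included) with annotation
sizes growing rootwards; a flat pathway collection with a planted
redundant pair (B = 80% subset of a same-scale A) and a planted
specific-subset pair (D ≈ 1/7 of broad C); a Barabási–Albert (scale-free,
m = 3) gene interaction network with the top hub and four neighbours as the
planted module; a two-chromosome genome with 20 kb gene spans every 100 kb
(spacing exceeds the default scoring window, so a SNP scores only its own
gene and recovery is unambiguous); GWAS SNPs with uniform null p-values
plus one genome-wide hit (p = 10^−U(9,15)) inside each module gene, each
with one valid LD proxy (R² in 0.82–0.98) and one sub-threshold proxy
(R² in 0.2–0.7); and annotation tracks with input regions drawn 70% inside
track A. Scales: `tiny` (10 terms/10 genes/20 SNPs) keeps exhaustive
oracles trivial, `small` (50/200/500) is the working test scale, `medium`
(200/2000/5000) approximates a realistic workload.

What it does **not** emulate: LD structure beyond explicit proxy pairs,
realistic minor-allele-frequency or gene-length distributions, correlated
annotation tracks, overlapping gene models, or any real biology — passing
tests demonstrate the algorithms' correctness and calibration under
controlled conditions, not biological validity of results on real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run at deliberately modest sizes:
exhaustive table enumeration at N ≤ 15, subnetwork brute force at ≤ 10
nodes over 200 instances, 500 null draws per input size, 50 planted
fixtures, B = 2000 sampling iterations — sizes at which exhaustive oracles
stay trivially cheap while estimates (fractions, Jaccard means, Monte-Carlo
deviations) are stable across seeds. Oracle comparisons for analytic
p-values use an absolute tolerance of 1e-12; stochastic checks use 3
standard errors. Degenerate inputs are defined, not guessed: zero-overlap
tables give p = 1, an all-zero null sd yields an undefined (NaN) z-score, a
term annotating nothing is skipped, and an empty effective input or empty
background is an error naming the cause.

## Known limitations

- The elimination variant is the classic leaf-to-root one; other
  tree-aware weighting schemes (e.g. down-weighting rather than removing
  claimed genes) are out of scope.
- The subnetwork search is a heuristic; optimality is empirical (anchored
  to an exhaustive oracle at small n), not guaranteed.
- Edge weights in the interaction network are carried through IO but do not
  influence the subnetwork objective, which is node-prize-based.
- The sampling null places intervals independently; it does not preserve
  inter-interval spacing.
- Genome-build conversion, LD computation from genotypes, and all
  visualisation beyond DOT/Newick/TSV exports are out of scope.
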