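# Methods

## Data model and assembly

Webs are ingested at the life-stage level (a larva and an adult may have
different diets) and aggregated to species before any metric is computed.
Aggregation re-keys links to species, collapses exact duplicate
(consumer, resource, class) triples, and OR-combines the life-cycle flags — a
species-level link is trophically transmitted if any stage-level instance was.
A species is a parasite if any stage is parasitic, but predator–prey links
contributed by free-living stages are retained, so a parasite species can
carry both parasitic and predatory links. Self-links created by cross-stage
feeding are kept in the data model but excluded from trophic-level solving,
the motif census and diet-gap counting (standard census behavior; switches on
the respective functions).

Species flagged extinct are removed, with their links, before anything is
counted. The three assembly versions are nested link-class filters: PP
(predator_prey only, free-living species only), PP_PH (adds parasite_host),
PP_PH_PC (adds predator_parasite; the parasite_parasite class is permitted
but typically empty). Links flagged as statistically predicted false
negatives are excluded unless the assembly explicitly folds them in. Link
classification is exclusive: a predator–prey encounter that transmits a
parasite appears once, as a trophic-transmission parasite_host link, never
double-counted in the predator–prey sub-web.

## Metrics

* **Connectance** is L/S² with self-links counted. **Adjusted connectance**
  restricts the denominator to link types possible for the assembly:
  S_free·(S_free+S_par) for PP_PH (parasites cannot be resources without
  concomitant links) and S²−S_par² for PP_PH_PC (the parasite-on-parasite
  quadrant is excluded as unobserved). It is undefined for PP.
* **Degree statistics.** Generality g_i = resources of i, vulnerability v_i =
  consumers of i, degree d_i = g_i+v_i. Means and SDs average over *all*
  species by default, so mean generality = mean vulnerability = L/S exactly;
  a participants-only denominator (consumers for generality, resources for
  vulnerability) is provided as an option because published tables sometimes
  use it. SDs use the sample convention (ddof = 1), switchable.
* **Trophic level** is prey-averaged: TL = 1 for basal species, otherwise
  1 + mean TL of the diet, solved as (I−W)t = 1 so feeding loops are handled;
  concomitant links and self-links are excluded from the diet matrix because
  accidental ingestion of a parasite carries no meaningful energy. A web with
  no reachable basal species raises an explicit error.
* **Longest chain** is the node count of the longest simple path from a basal
  species (no resources) to an apex species (no consumers of any kind). The
  apex-termination requirement is what lets concomitant links *shorten* the
  longest chain: they strip apex status from most species, leaving only
  enemy-free parasites as chain endpoints. On cyclic webs the computation is
  exact via the strongly-connected-component condensation: a simple path
  crosses each component once, so within-component longest-path tables
  (exhaustive DFS over the component only) are chained by DAG dynamic
  programming. Longest simple path is NP-hard, so a configurable expansion
  budget guards the within-component search; concomitant-rich webs can fuse
  into one giant component, in which case the metric is reported as undefined
  rather than approximated. Null-ensemble draws where the chain is undefined
  (no apex, or budget exhausted) are recorded as NaN and ignored by the
  model-error quantiles.

## Niche-model nulls and model error

Null webs come from the one-dimensional niche model: niche values
n_i ~ U(0,1); feeding range r_i = x·n_i with x ~ Beta(1, β),
β = (1−2C)/(2C); range center c_i ~ U(r_i/2, n_i); species i consumes
everything with niche value in [c_i−r_i/2, c_i+r_i/2]; the smallest-n species
gets r = 0 so a basal species always exists. Webs with isolated species or
more than one weakly connected component are rejected and redrawn (cap 10,000
attempts), the standard protocol; duplicate-diet species are allowed, since
rejecting them would bias realized connectance. Ensembles are matched on S
and on C — adjusted C for parasite-containing assemblies, since that is the
connectance the assembly could actually attain. Realized connectance is
unbiased for the target within Monte-Carlo error (checked at S=50, C=0.10
over 1000 draws in the test suite).

Model error uses asymmetric half-interval normalization (above vs below the
median scaled by the 97.5% vs 2.5% distance), the unique simple form making
|ME| > 1 equivalent to falling outside the central 95% of null values.
Quantiles use linear interpolation. The sign is positive when the empirical
value exceeds the null median. Note that published ME tables in this
literature sometimes show a negative chain-length ME alongside prose saying
chains were *longer* than predicted; this package implements the stated sign
convention and leaves such discrepancies to the reader.

## Motif census

The 13 connected three-node digraph classes ship as an explicit fixture of
canonical adjacencies (`kelpweb/data/motif_classes.json`), the single source
of truth; the S/D split (no mutual pair vs at least one) is a property of the
fixture verified in tests, and all 64 possible edge subsets on three nodes are
checked against brute-force isomorphism. The census itself is edge-driven
(Batagelj–Mrvar-style enumeration of connected triples) with a 64-entry lookup
table, equals brute-force all-triples classification on every random instance
tested, and is cross-checked against python-igraph's triad census with the
class correspondence derived programmatically. The ordering of labels within
S1–S5 and D1–D8 is fixed by the fixture; only the S-vs-D dichotomy and the
chain class are asserted to match external conventions, since drawn orderings
vary between publications.

Standardization reports, per class, the empirical proportion of connected
triads, the null-median proportion, their ratio (with a 1/n_triads pseudocount
and a flag when the null median is zero), and the ME.

## Diet-gap minimization

For an ordering of all species, a consumer's contribution is
(span of its diet positions) − (diet size); the objective is the sum over
consumers, zero exactly when every diet is an interval. Self-links are
excluded; which link classes count as "diet" follows the assembly, so
concomitant links are diet items in PP_PH_PC orderings. Annealing uses
position-swap proposals with incremental objective updates, Metropolis
acceptance, and geometric cooling; the default schedule is T0 = (initial
objective)/ln 2, α = 0.95, 100·S proposals per temperature, stopping at
10⁻³·T0 — schedules are explicit, overridable and reported in output. The
headline statistic is the mean over 10 independent restarts (the minimum is
also reported); on null webs inside ensembles a single optimization per web
keeps thousand-web ensembles tractable. On 8-species webs the annealed
minimum matches the exhaustive optimum over all 40,320 orderings in the test
suite.

## Rank-sum comparisons

The Wilcoxon rank-sum (Mann–Whitney) test uses mid-ranks for ties, the
tie-corrected variance of U, and the continuity correction in the normal
approximation (matching common statistical packages); with n1+n2 ≤ 12 it
switches to full exact enumeration of rank assignments. The normal and exact
two-sided p agree within 0.02 at n1 = n2 = 6.

## Synthetic metawebs: what they emulate and what they do not

The generator produces the regime these analyses assume: a free-living niche
core (default 485 species at connectance 0.036), a parasite fauna (default
433 species) dominated by host specialists under a heavy-tailed zeta(2.5)
breadth law (median host count ≤ 4), a few supergeneralists whose paratenic
host sets are recruited from predators of their intermediate hosts, complex
life cycles whose first hosts sit in the lowest trophic-level tercile and
whose later hosts are predators of the current host (links flagged
trophically transmitted), and extinct/false-negative flags for testing the
assembly filters.

Host placement for direct specialists is weighted toward higher trophic
levels and low-vulnerability consumers — the pattern in parasite-resolved
webs, where the average top predator hosts many parasites but has few
predators. This choice also keeps the concomitant sub-web a small multiple of
the parasite–host sub-web, as observed empirically; uniform host placement
would make concomitant links overwhelm the web.

Concomitant links are composed exhaustively: for every parasite–host pair
(p, h) and every free-living predator q of h, q→p is added unless p→q exists
as a *trophic-transmission* parasite_host link (in which case eating h
transmits p to q rather than killing it). A predator that hosts p
non-trophically still ingests and kills the p individuals riding in its other
prey, which is the mechanism that makes mutual-consumption (D-class) motifs
more common once parasites are added.

The proportion of complex life cycles (default 0.45) and the extinct and
false-negative rates are order-of-magnitude choices exposed as parameters;
no published value pins them down. The generator targets qualitative
structure — it makes no attempt to fit any deposited web's degree sequences,
so tests passing on synthetic webs demonstrate correct mechanics and the
direction of parasite effects under the stated structure, not numeric
agreement with any particular empirical web. Body sizes, biomass, spatial
structure and microbial symbionts are not modeled.

Under the default (paper-scale) parameters, seeded replicates reproduce the
qualitative headline directions: adding the parasite fauna lowers connectance
(and the full web's adjusted connectance stays below the free-living
connectance), while concomitant links raise the D-class motif proportion.
These hold in 20/20 replicates in the test suite; the acceptance tests check
the connectance and motif directions on 20 replicates at a reduced size
(120 free-living + 110 parasite species) chosen to keep the census affordable,
and the adjusted-connectance direction at the full default scale.

## Problem sizes used in tests

Oracle comparisons run at sizes where brute force is exact and fast: triad
censuses on 100 random webs with S ≤ 30 against all-triples classification;
diet gaps on 8-species webs against all 8! orderings (annealing with a
lighter explicit schedule: 150 proposals per temperature, floor 10⁻²·T0);
niche calibration with 1000 webs at S = 50; model-error calibration with 1000
trials against a 1000-value ensemble; rank-sum exactness at n1 = n2 = 6.
Pipeline tests use 30-simulation ensembles; production runs default to 1000.

## Known limitations

* Longest chains in concomitant-rich webs are frequently undefined (no apex)
  or intractable (giant strongly connected component); the package reports
  these honestly instead of substituting a heuristic.
* Adjusted connectance for the full assembly computes to 0.0306 on the
  published full-web counts while the source table prints 0.030 (their
  rounding convention is unknown); the false-negative-corrected value rounds
  cleanly to 0.032.
* Published mean degree/generality values in this literature imply a
  restricted denominator inconsistent with L/S from the same tables; both
  conventions are provided and the default is the self-consistent one.
* The rank-sum Z of published analyses may come from different software
  conventions (exact vs asymptotic, continuity on or off); both modes are
  exposed.
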