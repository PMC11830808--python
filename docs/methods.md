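# Methods

## Scope and data model

The unit of analysis is the *intervention record*: one drug program by one
sponsor against one indication, with its mechanism of action (MoA), therapy
modality, development phase (`early_clinical`, `late_clinical`, `approved`),
collaborator list, and — for approved assets — orphan drug designation (ODD)
status, approval year and annual revenue in million USD. A drug marketed for
several indications appears as several records sharing `drug_name`;
uniqueness counts deduplicate on the drug name. Revenue is a single-currency
figure; any conversion must happen upstream. An approved record may lack an
approval year (it is tallied in the timeline's `unknown` bucket); a
non-approved record never carries one.

Entity names are canonicalized through an alias table whose lookup folds
case, accents, whitespace and punctuation, and through a company table with
parent (merger/acquisition) links. Roll-up replaces a subsidiary sponsor by
its ultimate parent while retaining the original name in `sponsor_original`,
so portfolios can be reported including or excluding the subsidiary.
Malformed table rows never abort a run: they are skipped, counted and
reported with row numbers.

## Tripartite network and knockout

Sponsors, collaborators and diseases are role-based node layers in a directed
multigraph; each program contributes one annotated edge per hop (multigraph
semantics preserve program multiplicity; activity queries deduplicate). A
direct sponsor→disease edge exists only for solo programs. A company active
on a disease is one with a program reaching it; per-disease MoA diversity is
the number of distinct MoA strings among those programs (exact string match —
no MoA ontology is imposed).

Knockout removes a company in both roles, modeling market exit: its sponsored
programs vanish, it is scrubbed from surviving collaborator lists, and
collaborator nodes left without any sponsor edge are pruned. Impact is the
per-disease difference in developer count and unique-MoA count, computed as
an exact recount over the surviving programs — so the simulation is by
construction equivalent to rebuilding the network from the record table minus
the company's rows, and removal is monotone (counts never increase) and local
(only diseases the company reached change).

## Competition and innovation indexes

Per asset, two independent axes: *contested disease* (≥1 other company
develops against the same indication) and *shared MoA* (≥1 other company uses
the same mechanism). Company scores are asset-weighted fractions, giving
graded values in [0,1] rather than binary labels; `innovative_index` (fraction
with an exclusive MoA) and `competitive_index_moa` are exact complements. A
company re-using its own MoA across assets remains innovative — exclusivity
is judged across companies. The default scope is the developmental pipeline
(non-approved assets); `scope="all"` includes approvals. Sharing is assessed
after normalization and roll-up, so a merged group counts as one player;
running with `rollup=False` reproduces the pre-merger view.

## Market analytics

Shares are `100 · key_revenue / grand_total`; the grand total is always the
sum over the analyzed table and is reported explicitly, so the denominator is
never ambiguous. Organ-system aggregation treats combination labels
("liver/heart/lung") as atomic categories, counting an asset's full revenue
once; an indication missing from the organ map falls into an `unmapped`
bucket rather than being dropped. Tier bands are leader ≥ 6%, upcoming major
in [2.5, 6), challenger < 2.5; the source intervals carry no open/closed
notation, so lower-edge inclusivity was fixed as the convention and the
bounds are configurable. Percentages are reported to one decimal place.

The top-asset profile computes, per company, total revenue, highest-grossing
asset revenue and their ratio, plus the Pearson correlation between totals
and tops across companies — a concentration read-out (blockbuster-driven vs
portfolio-driven markets). The correlation needs ≥3 companies and nonzero
variance in both series; degenerate inputs are flagged (`None`) rather than
forced. ODD segmentation computes group percentages over approvals with known
designation status; the two group counts plus timeline buckets (including
`unknown`) always conserve the approved total.

## Drug–target networks

STITCH-style link tables score each chemical–protein (or chemical–chemical)
association on [0,1]; downloaded files use 0–1000 integers. The parser
detects the dialect per file (integers above 1 ⇒ integer dialect, divided by
1000), rejects rows outside both ranges, and refuses files mixing dialects.
Partner kind (protein vs chemical) is taken from an explicit `partner_kind`
column when present, otherwise inferred from identifier shape (ENSP-style ⇒
protein, CID-style ⇒ chemical).

A network for a drug set keeps edges at or above the confidence threshold
(default 0.4, the common medium-confidence convention; always recorded in
provenance). The node universe is threshold-independent: every listed drug
and every protein partnered with a listed drug is a node even if all its
links fall below the threshold. This makes density `2E/(N(N−1))` and mean
degree `2E/N` strictly monotone in the threshold, which is the property the
group comparison relies on. Drug–drug edges come only from explicit
chemical–chemical links; drug pairs sharing a protein target are counted
(`shared_protein_pairs`) but not materialized as edges, keeping the two edge
semantics distinct. Group comparison reports signed metric differences and a
denser/more-connected verdict on four connectivity metrics (density, mean
degree, shared-protein pairs, isolated-drug fraction — the last inverted); no
statistical test is attached. Pathway context is a plain join against a
user-supplied protein→pathway table emitting membership counts — no
enrichment statistic is defined.

## Synthetic ecosystem generator

The generator emulates the features the analysis assumes: disease assignment
with probability ∝ `rank^(−exponent)` (one parameter reproduces the
crowded-indication pattern), per-asset collaboration with probability
`collaboration_prob` (one partner drawn uniformly), ODD flags at
`odd_fraction` among approvals, exclusive-MoA assignment at
`unique_moa_fraction` (fresh label no other company uses) vs draws from a
shared pool, approval years uniform on `year_range`, and log-normal revenues
attached only to approved assets. One pseudo-random stream per table
(companies / assets / financials), all spawned from the master seed, so
generating one table never perturbs another; output is byte-identical for a
fixed seed.

A shared-pool draw can by chance end up used by a single company, which would
bias the downstream innovative index above the planted rate. A deterministic
post-pass therefore reassigns such labels to the most-used cross-company
shared label, so "shared" is shared in fact; in the degenerate case where no
cross-company label exists (tiny ecosystems) the draws are left untouched.
With this, the mean innovative index is an unbiased estimator of
`unique_moa_fraction` (verified at 3 standard errors across seeds in the
test suite).

Defaults are the study conditions: 43 companies, 295 diseases, a 283-label
shared-MoA pool, mean 14 assets per company, approved fraction 0.345, ODD
fraction 0.35, approvals 1995–2021, revenue log-mean 5.5 and log-sd 1.5
(million USD) — a heavy-tailed distribution whose ~200 approved assets sum to
a market in the 1.4–1.7 × 10⁵ million range. Collaboration probability 0.3
and popularity exponent 1.0 are the remaining free choices, set once to
values typical of a collaborative, moderately skewed development landscape.

What the generator does *not* emulate: real entity-name noise (aliases are
exercised by hand-built fixtures instead), multi-indication assets,
multi-collaborator consortia, secular trends in approval rates, and any
correlation between revenue and indication crowding. Passing tests therefore
validate the statistical machinery, not the fidelity of any particular real
dataset.

## Numerical and testing choices

Share normalization is checked to 1e-6; index complementarity is exact by
construction; ties in rankings break alphabetically everywhere
(`sorted(key=(-count, name))`). Knockout correctness is established against a
brute-force rebuild oracle on random small ecosystems (≤8 companies, 100
cases), chem-network metrics against brute-force adjacency recounts, and the
top-asset Pearson correlation against the closed-form formula on a 3-company
toy. Test problem sizes (50 companies × ~12 assets for index recovery, 20
seeds for the density contrast) are chosen so each suite completes in
seconds while leaving the statistical assertions well-powered.

Known limitations: MoA identity is exact-string; no fuzzy entity resolution
beyond the alias table; no enrichment statistics, forecasting, currency
conversion, or figure styling — the package emits the underlying tables.
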