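# Methods

## Data model

The store is analyte-centric: harmonized genes and metabolites are the hub
records, joined to pathways (membership edges tagged by source database),
to each other (undirected gene–metabolite catalysis edges), and to ontology
terms (biofluid, cellular location, origin, tissue). Every entity carries
an internal unified ID — `RAMP_C`/`RAMP_G`/`RAMP_P`/`RAMP_OL` plus a
nine-digit zero-padded serial issued sequentially per kind — used only as a
stable join key; user-facing answers are keyed by names and native
identifiers. The backing implementation is an in-memory Python store with a
TSV-directory persistence format and an optional plain-text SQL dump
export; a relational server would add deployment cost without changing any
query semantics.

## Identifier unification

Dumps are processed in caller order; within a dump, analytes are processed
before pathways before ontology terms, in file row order, so serial
assignment is reproducible. Each analyte row contributes an association
group: its own (source, native_id) pair plus all cross-linked identifiers.
Match-or-mint proceeds per group; when a group bridges k ≥ 2 pre-existing
IDs, all are merged into the lowest serial and the retired IDs are recorded
as tombstones. Bridging is inevitable with multi-source data, and silent
duplication would break the one-ID-per-analyte contract, so the merge is a
deliberate extension of plain match-or-mint. Consequences verified by
property tests: the final partition equals the connected components of the
pooled link graph (independent of dump order, which affects only serial
numbering), and re-ingesting the same dumps over the produced mapping mints
nothing new.

Two deliberate exclusions: synonyms never drive merging (shared synonyms
like "triglyceride" connect thousands of distinct compounds), and an
identifier claimed as a gene by one source and a metabolite by another is a
hard validation error rather than a silent union.

Ontology terms harmonize on (category, case-folded term) across dumps.
Pathways are keyed per (source database, native pathway ID); dumps tagged
`hmdb` contribute their pathways under the `smpdb` label, mirroring the way
metabolite-centric databases carry small-molecule pathway sets from a
sister resource.

## Overrepresentation analysis

For each tested pathway, `P_m` is the one-sided Fisher exact p-value for
the metabolite hits — the hypergeometric upper tail P(X ≥ hits) with
population = the source's metabolite background, successes = pathway
metabolite members, draws = the number of input metabolites resolvable to
that source's pathway space (capped at the background). `P_g` is the same
for genes against a genome-wide background. Defaults: KEGG 3603, Reactome
1771, WikiPathways 1421 metabolites; 20,000 genes. One-sidedness is forced
by the overrepresentation question; an input analyte counts once per
pathway regardless of how many identifiers matched it.

Combination uses Fisher's method, `T = −2[ln P_m + ln P_g]`, referred to a
chi-square distribution. The default is 2 degrees of freedom, for which the
survival function gives the closed form `P_comb = P_m·P_g`; the textbook
value for two independent p-values is 2k = 4, available via `df=4`. The
df=2 default is deliberately conservative-looking but anti-conservative in
aggregate — under the null `P_m·P_g` is not uniform (its CDF is
t − t·ln t, supremum deviation 1/e ≈ 0.37) — so the null-calibration
simulation documents both: df=4 yields a near-uniform combined p, df=2 the
product distribution. A missing component (pathway has no members of that
type, or the input has none) passes the other p through unchanged. p = 0 is
floored at the smallest positive double before the log.

Pathways with fewer than 10 or more than 1000 total member analytes are
removed before testing (both boundaries retained, i.e. exactly the
complement of "<10 or >1000"). `P_comb` is adjusted across all tested
pathways in one family spanning the selected sources — the conservative
reading; per-source grouping remains a display concern. BH and Holm are
computed via statsmodels' `multipletests`, cross-checked elementwise
against independently coded step-up/step-down implementations.

## Null calibration simulation

The calibration harness draws metabolite and gene input lists uniformly
from their backgrounds and tests them against random pathways, recording
the combined p per pathway. Sizes used: universes of 20,000 per analyte
type, input lists of 4,000, 2,000 simulated pathways of 1,500–2,500 members
per side, lists redrawn every 25 pathways. These sizes are chosen so the
discreteness of the exact hypergeometric p-value — which is super-uniform,
touching the diagonal only at achievable values — leaves a gap small
relative to the 0.05 Kolmogorov–Smirnov acceptance distance; with small
pathways or short lists the step size of the discrete p dominates and no
continuous-uniformity check is meaningful. Observed KS distance under df=4
is ≈ 0.02–0.035 across seeds.

## Redundancy clustering

All pathway pairs are scored with the Jaccard index over analyte member
sets (`O_mn = I_mn/(L_m + L_n − I_mn)`; empty sets score 0, keeping empty
pathways inert). A pathway is a seed when it overlaps at least
`seed_overlap_threshold` (default 0.30) with at least `min_seed_neighbors`
(default 2) others. Each seed anchors a cluster holding every pathway
within `member_overlap_threshold` (default 0.30, a parameter separate from
the seed threshold though equal by default); one pathway may sit in several
clusters. Cluster pairs are then scored with the same formula over shared
member *pathways*, identified by case-folded pathway name so the same
pathway reported by two sources counts as shared, and the top pair merges
while its score strictly exceeds `merge_threshold`. The loop performs at
most (initial − 1) merges and leaves no pair above the threshold.

Determinism is pinned down where the procedure is otherwise tie-ambiguous:
equal-score pairs merge in lexicographic label order, merged clusters keep
the smaller label index, and labels are `cluster_<k>` in seed-discovery
order. Presets mirror the two published use cases: metabolite-only runs use
(seed 0.2, neighbors 2, merge 0.75), combined gene+metabolite runs
(0.2, 2, 0.5).

For mixed input, the default overlap basis is pooled Jaccard over the union
of gene and metabolite members; per-type bases (`metabolites`, `genes`) are
available. Computing the two overlaps separately is well-defined, but no
reconciliation rule for a single clustering is fixed by the procedure, so
the pooled basis is this package's documented choice.

## Synthetic sources

The generator emulates the structural features that exercise the stack:
several sources sharing a configurable fraction of analytes through
cross-links to common reference identifiers (so the true co-reference
partition is the link-graph component structure by construction, recorded
in a manifest); nested pathway hierarchies realized as random subsets of a
parent, creating the high within-source overlaps typical of
reaction-hierarchy databases; pathway sizes drawn uniformly from a
configurable range; planted promiscuous analytes added to every pathway of
a source; planted synonym collisions; random catalysis pairs and ontology
assignments. Defaults (3 sources, 200 metabolites + 200 genes per source,
30% sharing, 30 pathways of 10–60 members, nesting depth 2) are sized for
fast, fully offline testing.

What the generator does not emulate: realistic metabolite naming or
mass-spec identifier conventions, correlated pathway content across sources
beyond literal sharing, and the extreme size skew of real collections.
Passing tests therefore demonstrate algorithmic correctness on structurally
faithful data, not fidelity to any particular database release — content
counts of real 2017-era releases are version-dependent and out of scope.

The planted-enrichment fixture (1000-metabolite universe, one 30-member
target, 50 decoys of 10–100 members, input of 20 target + 5 background
metabolites) gives a recovery problem hard enough to be non-trivial but
with an expected planted p of ~1e−30, so a sub-95% recovery rate would
indicate a defect, not noise.

## Numerical and interface choices

- Exact hypergeometric tails come from scipy (`hypergeom.sf`), vectorized
  over hit counts; test oracles use exact integer arithmetic.
- All name matching is case-insensitive with surrounding whitespace
  stripped; no fuzzy matching, which would compound synonym ambiguity.
  Native-identifier matches take strict precedence over name/synonym
  matches, and ambiguity is flagged per match rather than resolved.
- Batch queries report unmatched or partnerless inputs in a side channel
  instead of raising, so one bad row never aborts a batch; empty input
  lists are errors.
- Output tables are deterministically ordered (source, then rendered
  internal ID, then query string) and serialized as header-bearing TSV with
  absent p-values rendered `NA`.
- Problem sizes in the test suite and acceptance script (200 unification
  fixtures, exhaustive tables to background 40, 100 recovery replicates,
  2,000 calibration tests) are sized to verify each property at full
  strength while keeping a complete run in tens of seconds.

## Known limitations

- No converters from real source formats (HMDB XML, KEGG REST, GPML,
  Reactome mapping files) to the normalized dump format; the dump format is
  the ingestion contract.
- Custom per-experiment backgrounds (the assayed-metabolite universe) are
  not supported; backgrounds are per-source constants.
- The df=2 combination default is anti-conservative under the null (see
  calibration above); df=4 is the statistically calibrated choice and both
  are exposed.
- Enrichment treats pathways as independent; overlap-aware statistics are
  exactly what the redundancy clustering is meant to aid, not replace.
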