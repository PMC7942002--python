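# Methods

## Problem and model

Secondary use of clinical data (registries, multi-site studies, data
integration centers) requires assessing data quality — completeness,
conformance, plausibility — in a way that is reproducible and portable
across source systems. `dqmm` formalizes every DQ metric as a *measurement
method* (MM): a 5-tuple of tags, domain paths, an optional check, an
optional grouping, and a characterization. Executing an MM against a
dataset proceeds in four stages:

1. **assembly** — each domain path contributes one input vector; dataset
   paths yield one value per dataset row (repeated elements are flattened
   to one input row per matched node, with the originating row index kept
   as provenance), filter paths yield one value per (matched MM, group)
   pair of previously executed MMs;
2. **check** — the rule is evaluated per input row, producing
   true/false/missing;
3. **grouping** — each row is assigned a group label; no grouping means a
   single group `ALL`; a missing grouping key pools into `MISSING`;
4. **characterization** — each group's vector (the check vector if a check
   exists, otherwise `item0`) is summarized.

Multi-layered MMs (inputs = other MMs' results) enable assessment layers:
the constraint summary TDConstraints selects every MM tagged `check`
excluding `per_*` dimension variants and averages pass fractions per
variable. Dependencies are resolved by topological sort over the
filter-match graph (an edge from MM *x* to MM *y* whenever *y*'s filter
matches *x*'s tags); independent MMs keep their input order, cycles are
reported as errors, and any valid topological order produces identical
results because MMs communicate only through their named results.

## Data model and path dialect

A dataset row holds one *composition*: a finite tree of named nodes. A node
carries either a scalar payload (optionally with a unit) or children, never
both. Paths take the form

```
dataset-row/segment/segment[at0098,'biopsy result final']/name[.value|.magnitude|.unit][.countChildnodes(only_child|all)]
```

Segments match by name, optionally constrained by a node-id/archetype-id
predicate and a quoted human-readable name; a bare `[id]` segment matches on
the id alone (archetype roots). `.countChildnodes(mode)` counts child nodes
instead of reading content; `only_child` demands a unique matched parent and
treats ambiguity as an error rather than silently picking the first match.
Child nodes whose payload is the missing marker are *not* counted, so
cardinality rules catch null-flavor tokens as well as absent subtrees.

**Missing semantics.** A value is missing iff it is absent from the tree or
its text form is in the configurable `missing_tokens` set (default `""`,
`"NA"`, `"ND"` — token sets vary between sources, and a source emitting an
unexpected flavor like `"ND"` must still be caught). A single missing
marker propagates through every expression: any missing operand makes the
result missing. Characterization builtins skip missing values, except
`count_total`/`count_missing` (and `fraction_present`, whose denominator is
the total input length). This keeps completeness and correctness measures
orthogonal: a missing value is never counted as a constraint violation.

**Type inference.** When no schema covers a path: NUMERIC if every
non-missing value parses as a number, DATE_TIME if ISO-8601, BOOLEAN for
true/false, CODED_TEXT up to 50 distinct values, else TEXT. A declared
schema type always wins.

**Formats.** Nested records are newline-delimited JSON, one composition per
line: `{"template_id"?: str, "children": [node…]}` with
`node = {"name", "value"?, "unit"?, "children"?, "node_id"?,
"archetype_id"?, "display_name"?}`. Flat tables are RFC-4180 CSV whose
header cells are leaf paths; numeric-looking cells are parsed as numbers.
Both encodings of the same logical data resolve identically for leaf paths.

## Expression dialect

Checks, groupings and custom characterizations use a closed, sandboxed
expression language rather than a general-purpose host language: arithmetic,
comparisons, `and`/`or`/`not`, conditional `a if cond else b`,
`in_list(x, [...])`, `concat`/`format` (printf-style), regex `matches`, and
date parts `year`/`month`/`quarter`/`day`/`weekday` (ISO weekday, 1 =
Monday). There is no I/O, no loop, no attribute access and no user-defined
function, so MMs imported from a foreign knowledge base cannot execute
arbitrary code. Ordering comparisons between incompatible types (`"a" < 3`)
are errors, not false; equality across types is false. Unit-conditional
range rules are chained conditionals; an unknown unit yields missing (the
value cannot be judged), not a violation.

Tag filters are a separate, even smaller language: `has_tag(t)` /
`lacks_tag(t)` atoms combined with `and`/`or`/`not`; a trailing `*` makes
the atom prefix-matching (so `lacks_tag('per_*')` excludes all dimension
variants).

## Generation

*Type-based*: per variable and per entry of a pinned, caller-overridable
matrix — NUMERIC/COUNT → `count_present, min, max, mean, median, sd,
histogram`; TEXT/CODED_TEXT → `count_present, frequency_table,
relative_frequency_table, barplot`; DATE_TIME → `count_present, min, max`;
BOOLEAN → `count_present, frequency_table`. The matrix is pinned because
reproducible counts require a fixed default even though sensible choices
vary by project.

*Constraint-based*: per constraint one ungrouped check MM with `mean`
characterization — range, unit-conditional range (one conditional MM with a
value item and a unit item), value set, cardinality/mandatory (a
`countChildnodes(only_child)` rule on the variable's parent element, which
assumes each leaf sits in a dedicated parent element, the usual
element/value modeling), and regex pattern. Constraint schemas are a
purpose-built YAML document, not parsed archetype/template files: the
information content (paths, types, constraints) is what the generator
needs.

*Dimension variants* copy an MM, append a domain path for the grouping
variable, set the grouping expression (optionally a date-part derivation)
and add a `per_<dimension>` tag. Originals are kept, so grouped and
ungrouped variants are distinct MMs distinguishable by tags.

MM identity is a content hash (SHA-256, 16 hex chars) of the canonical
5-tuple document, giving stable ids across knowledge-base round-trips.

## The three harmonized measures

* **RepresentationComplete** = `count_present / count_total` per variable;
  the denominator is the dataset row count, so an absent subtree counts as
  missing. By construction the value plus the missing fraction is exactly 1.
* **TaskComplete** = per mandatory variable, the number of rows where the
  cardinality rule `count >= 1` fails; 0 iff no mandatory value is missing.
  The heatmap emits both the raw count and a normalized goodness score
  `1 − count / n_rows` for coloring, since either reading can be wanted.
* **TDConstraints** = per variable, the *unweighted* mean of the pass
  fractions of all contributing check MMs (selected by
  `has_tag('check') and lacks_tag('per_*')`). Unweighted is a deliberate
  pin: weighting by judged-row counts would entangle the measure with
  completeness. Variables without any check are not applicable.

Heatmap coloring is a continuous green (1.0) → yellow (≈ 0.8) → red (0.0)
scale; not-applicable cells are white. Cells are pure functions of the MM
results — re-rendering never changes values.

## Synthetic fixtures

The generator emulates a two-site transplant-study dataset (facility name —
mandatory, patient id with a `P\d{4}` pattern, gender with the value set
Weiblich/Männlich/Divers, recipient age 18–90, donor age 0–99, a weight
with kg/g unit-conditional ranges, transplant and biopsy dates, a
months-since-transplant variable 0–120). Clean values are drawn inside the
constraints (numerics uniform within range, codes uniform over the value
set, dates uniform in a 2018–2021 window); each cell is then independently
flipped to missing with its missing rate (emitting a weighted null-flavor
token, default NA/ND/empty at 0.6/0.3/0.1) or to a violating value with its
violation rate (out-of-range numerics above the admissible band, off-list
codes, absent subtrees for cardinality constraints). A cell is never both
missing and violated — missing wins — so ground-truth counts are
unambiguous and a brute-force rescan of the emitted dataset reproduces them
exactly. The seed fully determines the output: the serialized dataset is
byte-identical across runs.

The fixture default is 200 rows and 2 sites (desk-scale); rate-recovery
checks run at n = 1000 where the 3-sigma binomial band around an injected
rate is a meaningful test. The fixtures deliberately do not model
cross-variable clinical correlations, longitudinal structure, or realistic
marginal distributions; passing tests demonstrate the correctness of the
measurement machinery on data with known defects, not clinical realism.

## Numerical and design choices

* `sd`/`variance` use the sample convention (ddof = 1) and are missing for
  fewer than two values; statistics on empty vectors are missing, not 0.
* `mean_density` is the mean absolute successive difference of the
  non-missing vector.
* Histograms/barplots are data structures (bin edges/labels + counts);
  image rendering happens only at the reporting layer so results stay
  comparable.
* Group labels are ordered lexicographically; `min`/`max` order ISO-8601
  date strings lexicographically, which is chronological.
* Multi-item alignment with repeated elements: per dataset row, the number
  of input rows is the maximum match count over items; single-valued items
  broadcast, shorter multi-valued items pad with missing.
* An MM's domain paths must be all-dataset or all-filter; mixing kinds has
  no defined row alignment and is rejected. Multiple filter items must
  select the identical (MM, group) sequence.
* Batch execution is fail-soft: one MM's error is recorded in its result
  and never aborts the batch; a DQ report must surface partial results.
* Knowledge-base export writes one YAML file per MM with a fixed key order
  and no timestamps, plus a manifest of SHA-256 hashes; import verifies
  hashes and the format version. Governance (review, history, merge) is
  left to external version control by design.

## Limitations

* The path dialect is a pragmatic subset of archetype-path semantics
  (name + id predicate + attribute projection); full ADL path features and
  real openEHR canonical serializations are out of scope — datasets arrive
  as files in the two documented formats.
* The expression dialect is intentionally closed; statistics beyond the
  builtin registry require extending the registry in code, not embedding a
  host language in MM documents.
* Terminology-bound value sets are not resolved; value sets are literal
  code lists.
* No streaming or distributed execution; datasets are held in memory.
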