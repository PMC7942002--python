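# dqmm — knowledge-based data-quality assessment for clinical datasets

`dqmm` measures the quality of path-addressed clinical datasets with
portable, declarative **measurement methods (MMs)**. It is aimed at data
integration engineers and researchers who need reproducible, shareable
data-quality (DQ) checks across sites and studies — completeness profiling,
constraint conformance (ranges, value sets, cardinalities, patterns), and
multi-layered summary measures — without hard-coding any of it per project.

## The measurement-method model

An MM is a 5-tuple:

1. **tags** — descriptive keywords (`check`, `range`, a variable path,
   `per_site`, …) that identify what the MM does and let other MMs select it;
2. **domain paths** — the input bindings `item0, item1, …`, each either a
   dataset path (a slash-separated archetype-style path such as
   `dataset-row/composition/context/health_care_facility/name`, optionally
   with a `.countChildnodes(only_child)` instruction) or, for multi-layered
   MMs, a tag filter over other MMs' results
   (`other_data_input: has_tag('check') and lacks_tag('per_*') .resultsValue`);
3. an optional **check** — a rule evaluated per input row, e.g.
   `item0 >= 0.0 and item0 <= 1000.0`, yielding true/false/missing;
4. an optional **grouping** — an expression assigning each row to a group
   (per site, per patient, per month of a date, combined keys); without it
   all rows form one group `ALL`;
5. a **characterization** — the summary per group: builtin statistics
   (`count_present`, `mean`, `median`, `sd`, `frequency_table`,
   `relative_frequency_table`, `histogram`, …) or a custom expression.

For a check MM with the `mean` characterization the result per group is the
pass fraction, i.e. `1 − violation fraction ∈ [0, 1]`.

Because variables are addressed by path rather than by source system, an MM
written once runs unchanged on any dataset that exposes the same paths; MM
compilations are stored as diff-friendly **knowledge bases** (one YAML file
per MM plus a hash manifest).

MMs are also **generated automatically**: per variable reference type
(distribution measures for numerics, frequencies for categoricals) and per
constraint in a schema (range, unit-conditional range, value set,
cardinality, pattern — one check MM each). Three harmonized DQ measures are
built on top as MMs: *RepresentationComplete* (fraction of non-missing
entries per variable), *TaskComplete* (count of missing values in mandatory
variables) and *TDConstraints* (a multi-layered MM averaging each variable's
constraint-check pass fractions), summarized in a per-variable heatmap.

## Worked example

Real clinical data is access-restricted, so the package ships a synthetic
two-site transplant-study fixture with known injected defects:

```python
from dqmm.synthetic import (make_study_spec, generate_dataset,
                            GENDER_PATH, RECIPIENT_AGE_PATH)
from dqmm import (generate_constraint_mms, build_hdqf_mms, execute_all,
                  build_heatmap)

spec = make_study_spec(seed=42, n_rows=500,
                       missing_rate={GENDER_PATH: 0.1},
                       violation_rate={RECIPIENT_AGE_PATH: 0.2})
dataset, truth = generate_dataset(spec)
mms = (generate_constraint_mms(spec.schema)
       + build_hdqf_mms(dataset.variables, spec.schema))
results = execute_all(mms, dataset)

age_check = next(r for r in results.values()
                 if "range" in r.tags and RECIPIENT_AGE_PATH in r.tags)
print("recipient-age range check pass fraction:", age_check.value())
print("judged true/false/missing:", age_check.checked_counts)

heatmap = build_heatmap(results, variable_name_map={
    GENDER_PATH: "gender", RECIPIENT_AGE_PATH: "recipient_age"},
    n_rows=len(dataset.rows))
print(heatmap.values.loc[["gender", "recipient_age"]].round(3).to_string())
```

prints

```
recipient-age range check pass fraction: 0.778
judged true/false/missing: {'true': 389, 'false': 111, 'missing': 0}
               RepresentationComplete  TaskComplete  TDConstraints
gender                          0.896           NaN          1.000
recipient_age                   1.000           NaN          0.778
```

The range check recovers the injected 20 % violation rate (0.778 ≈ 0.8, a
binomial draw at n = 500); RepresentationComplete recovers the 10 % missing
rate on gender (0.896 ≈ 0.9, with null-flavor tokens like `"ND"` normalized
to missing at load time); `NaN` marks measures not applicable to a variable
(e.g. TaskComplete for non-mandatory variables), rendered white in the
heatmap image.

The same workflow is available from the shell:

```bash
dqmm fixture --seed 42 --n-rows 500 --out fx/
dqmm generate --dataset fx/dataset.ndjson --schema fx/schema.yaml --out kb/
dqmm run --dataset fx/dataset.ndjson --schema fx/schema.yaml --out out/
dqmm kb bind kb/ --dataset fx/dataset.ndjson
```

## Layout

- `src/dqmm/data_model.py` — nested-record datasets, the path dialect,
  missing-value semantics, loading (NDJSON nested records, CSV flat tables)
- `src/dqmm/mm_model.py` — the MM 5-tuple, the sandboxed expression dialect,
  tag filters, the characterization registry, validation
- `src/dqmm/executor.py` — input assembly, check/grouping/characterization,
  dependency resolution for multi-layered MMs, fail-soft batch execution
- `src/dqmm/generator.py` — type-based and constraint-based MM generation,
  dimension variants, MM-set filtering
- `src/dqmm/hdqf.py` — the three harmonized DQ measures and the heatmap
- `src/dqmm/knowledge_base.py` — KB export/import/binding
- `src/dqmm/synthetic.py` — synthetic fixtures with ground truth
- `src/dqmm/cli.py` — the `dqmm` command

See `docs/methods.md` for the method description, file formats, parameter
defaults and known limitations.
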