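# Knowledge-base document schema

A knowledge base round-trips through a YAML mapping (`save_kb` / `load_kb`;
`diakb validate-kb FILE` checks both schema and self-consistency).  Top-level
keys:

| key | type | meaning |
| --- | --- | --- |
| `version` | int | document version (currently 1) |
| `config` | mapping | `ThresholdConfig` fields; omitted fields take defaults |
| `root_plan` | string | plan executed at the start of every run |
| `hypotheses` | list | one entry per hypothesis (below) |
| `plans` | list | one entry per plan (below) |

Each **hypothesis** entry:

| field | type | meaning |
| --- | --- | --- |
| `hypothesis_id` | string | stable identifier (report diffs depend on it) |
| `description` | string | human-readable claim |
| `scope` | `dataset` \| `event` \| `night` | instancing granularity |
| `evaluation_rule` | string or null | registered rule or detector name |
| `requires` | list of strings | activation atoms: `data:<type>`, `profile:<field>`, `lab:<field>`; a failed atom yields NA naming the missing context |
| `children` | list | marks a default-TRUE parent, invalidated only when all children are FALSE or NA |
| `siblings` | list | marks a lack-of-evidence hypothesis, TRUE when no sibling branch is TRUE |
| `template` | string or null | explanation text; placeholders must be evidence keys the rule produces (checked by `validate`) |

Each **plan** entry:

| field | type | meaning |
| --- | --- | --- |
| `plan_id` | string | identifier |
| `members` | list of `[kind, id]` | ordered tasks (`["task", "T_<hypothesis_id>"]`) or nested plans |
| `trigger` | `[hypothesis_id, state]` or null | when non-null, the plan is appended (scoped to the triggering result) whenever such a result is stored; null marks a root-reachable plan |

Unknown keys are rejected.  `validate` additionally reports dangling
task/rule/hypothesis references, plan-membership cycles, hypotheses
unreachable from the root plan or any trigger, and template placeholders
that no evidence key backs.
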