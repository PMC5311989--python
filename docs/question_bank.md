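# Question-bank document schema

A bank is a JSON or YAML mapping:

```yaml
bank_id: dsm5-mdd-default      # short stable identifier
version: "1.0"                 # recorded in every transcript
entry: a1                      # id of the first question asked
questions:
  - id: a1                     # unique within the bank
    text: "Over the last two weeks, have you felt sad ...?"
    criterion: A1              # DSM-5 element this question resolves
    response_kind: binary      # binary -> domain {yes, no}
    branch_rules:              # encoded answer -> next question id, or END
      yes: a2
      no: a2
    present_if: "yes"          # which answer marks the criterion PRESENT
                               # (optional, default "yes"; exclusion screens
                               # phrased favourably use "no")
```

`criterion` must be one of `A1..A9` (symptoms), `DUR` (two-week
duration), `B` (impairment), `C` (substance/medical exclusion), `D`
(psychotic exclusion), `E` (manic exclusion). Several questions may
share a criterion (the bundled bank probes `C` twice); the criterion is
PRESENT if any of its questions answered PRESENT.

Validation enforces: unique ids; a known `entry`; a branch rule for
every response in the domain; every branch target existing or `END`;
`present_if` inside the response domain; and an acyclic question graph —
so every interview terminates. Violations raise a
`BankValidationError` naming the offending node.

Load with `mddtool.load_question_bank(path_or_mapping)`; the bundled
banks are available as `mddtool.default_bank()` / `mddtool.reduced_bank()`.
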