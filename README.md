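# cardiotriage

Computational core of a rule-based cardiac-symptom self-management app,
plus the usability statistics used to evaluate it:

- **core_model** — validated domain types (event profiles, symptom episodes,
  heart checks), closed symptom vocabularies, and coded body-map regions.
- **triage_engine** — compares each heart check to the user's stored event
  profile (quality, location, radiation, associated symptoms), applies the
  high-risk rule (≥3 new typical features or any new associated symptom),
  and assigns a red / yellow / green level of care with a machine-readable
  rationale (red ≤ 24 h, yellow ≤ 7 days, green otherwise).
- **wellness_engine** — scores the 7-domain wellness check (0–10, higher is
  better) and recommends library content for domains scoring ≤ 4.
- **dialogue_engine** — deterministic scripted chatbot (declarative
  finite-state scripts with pacing metadata) and the check-in scheduler
  (heart check every 72 h or on demand; wellness check every 168 h).
- **usability_stats** — SUS scoring, adjective-anchor mapping, pooled
  mean/SD from group summaries, pooled-variance two-sample t intervals,
  and usability-error tallies.
- **synthetic_cohort** — seeded generator of synthetic users (profiles,
  episode streams with ground-truth triage labels, wellness trajectories,
  SUS tables) so everything is testable without patient data.

## CLI

The package installs a `triage` command:

```bash
triage simulate --seed 5 --out cohort/           # synthetic session logs + SUS table
triage classify --session cohort/user-0000.json  # red/yellow/green as JSON
triage wellness --session cohort/user-0000.json  # flagged domains + content
triage sus --responses cohort/sus.csv            # SUS scores and summary
triage pool --groups groups.csv                  # pooled mean/SD from (mean,sd,n) rows
triage chat --inputs inputs.txt                  # replay the bundled chatbot scenarios
```

Session logs are JSON; scripts and rule configs are YAML; SUS tables and
error logs are CSV. All timestamps are ISO-8601 UTC, and every operation
takes an injected clock — nothing reads system time.

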