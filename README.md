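# triadrem

Relational event models (REMs) for proximity-logger contact data from
triads of animals.

## The problem

When an unfamiliar animal is introduced to an established pair, the social
re-organisation that follows plays out second by second: contacts start,
stop, and recombine. Collar-mounted proximity loggers capture this as a
continuous stream of time-stamped encounters (who met whom, when, and for
how long). Aggregating such streams into association indices throws the
timing and ordering away; a relational event model instead treats every
contact *onset* as a draw among the onsets that could have happened at that
moment, conditional on the history of prior events.

`triadrem` implements the full pipeline for three-animal groups (two
familiar residents coded 1 and 2, one unfamiliar introduction coded 3):

1. **Ingestion** (`triadrem.logger_io`) — parse the logger dialect, drop
   sub-threshold contacts (default: anything under 2 s), merge reciprocal
   reports from the two collars of a dyad into maximal disjoint intervals,
   re-express time as seconds since introduction, and de-duplicate
   coinciding onset seconds.
2. **Event classification** (`triadrem.events`) — convert intervals into a
   time-ordered stream of onsets/offsets classified by the triad
   configuration: *pair* (isolated dyad forms), *group* (third animal joins
   a standing pair), *triangle* (last open dyad closes; forced, so never
   modelled), and the corresponding dissolutions.
3. **Design matrix** (`triadrem.design`) — for each modelled onset, build
   the risk set of actual and potential events with five history
   statistics: an unfamiliarity indicator and counts of prior pair/group
   events of the candidate dyad over two timescales (trailing hour and
   current day). Count statistics are z-scaled per fitted dataset.
4. **Fitting** (`triadrem.fit`) — maximum likelihood for the stratified
   conditional (multinomial) logit by Newton–Raphson, with standard
   errors, Wald tests and significance stars (* P<0.05, ** P<0.01).
5. **Simulation** (`triadrem.simulate`, `triadrem.recovery`) — a
   continuous-time generative model over the same statistics, emitting
   logger-dialect files so the whole pipeline can be validated end to end
   and parameter recovery demonstrated with known truth.

## The model

With event rates λ_a = exp(Σ_h θ_h s_h(a)), the probability that onset *a*
was the one realized, rather than any alternative a′ possible at the same
moment, is

    p(a) = λ_a / Σ_a′ λ_a′ .

A pair onset competes with the other two dyads (risk set of size 3); a
group onset competes with the other way the lone animal could have joined
the standing pair (size 2). Anything shared by all candidates in a stratum
— baseline rates, waiting times under the ordinal timescale — cancels, so
the likelihood is a stratified conditional logit and θ is estimated without
any intercept. Models are fitted separately per day and per event type,
with history statistics never reaching into the previous day.

## Worked example

Parse the bundled example fragment (six encounters between the two
familiar animals) and classify its events:

```python
import triadrem as tr
from triadrem.sample_data import SAMPLE_LOGGER_TEXT, sample_manifest

manifest = sample_manifest()
records = tr.parse_logger_file(SAMPLE_LOGGER_TEXT, manifest)
print("parsed:", [r.duration_s for r in records])
kept = tr.filter_short_contacts(records, min_duration_s=2)
print("kept after >=2 s filter:", [r.duration_s for r in kept])
intervals = tr.break_onset_ties(tr.compress_reciprocal(kept, manifest))
print("intervals (1,2):", [(iv.onset_t, iv.offset_t) for iv in intervals[(1, 2)]])
grid = tr.DayGrid("calendar", intro_offset_s=18 * 3600 + 49 * 60 + 34)
stream = tr.build_event_stream(intervals, grid=grid, triad_id="sample")
print(tr.summarize_event_counts(stream).to_string())
```

```
parsed: [1, 183, 16, 110, 16, 3]
kept after >=2 s filter: [183, 16, 110, 16, 3]
intervals (1,2): [(203, 386), (391, 407), (434, 544), (689, 692)]
     pair  group  triangle  pair_dissolution  group_dissolution  triangle_dissolution  total_onsets  total_offsets
day
1       4      0         0                 4                  0                     0             4              4
```

The 1 s encounter is removed by the minimum-duration filter, the two
identical 16 s reports collapse into one interval, and all four surviving
contacts are pair events (the unfamiliar animal recorded nothing yet).

Simulate a 36-triad study with known parameters and recover them:

```python
from triadrem.simulate import SimConfig, simulate_study
from triadrem.recovery import recover_study

study = simulate_study(SimConfig(n_triads=36, seed=1))
for model, r in recover_study(study).items():
    print(f"{model} model ({r.fit.n_strata} strata, converged={r.fit.converged})")
    for eff, th, se, truth, st in zip(r.fit.effects, r.fit.theta, r.fit.se,
                                      r.truth_scaled, r.fit.stars):
        print(f"  {eff:<11} B={th:+.3f} (SE {se:.3f}){st:<3} truth={truth:+.3f}")
```

```
pair model (5806 strata, converged=True)
  unfam       B=-0.479 (SE 0.032)**  truth=-0.500
  pair_hour   B=+0.030 (SE 0.018)    truth=+0.037
  pair_day    B=+0.132 (SE 0.028)**  truth=+0.098
  group_hour  B=+0.029 (SE 0.030)    truth=+0.022
  group_day   B=+0.019 (SE 0.045)    truth=+0.037
group model (1942 strata, converged=True)
  unfam       B=+0.493 (SE 0.077)**  truth=+0.500
  pair_hour   B=-0.066 (SE 0.036)    truth=-0.037
  pair_day    B=+0.148 (SE 0.055)**  truth=+0.093
  group_hour  B=-0.009 (SE 0.052)    truth=+0.036
  group_day   B=-0.071 (SE 0.089)    truth=+0.038
```

`B` is the estimated effect on the z-scaled statistic; `truth` is the
generating coefficient rescaled to the same scale. The strong
unfamiliarity contrasts (pairs avoid the newcomer; group formation
involves it) are recovered with two-star significance; the weaker history
effects sit within sampling error of their targets at this study size.

The same workflow is available from a shell:

```
triadrem simulate --out study --seed 1
triadrem ingest --data study/triads --out ingested
triadrem fit --events ingested/events.tsv --out fits
triadrem recover --out rec --seed 1
```

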