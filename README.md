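# ecnsim

A design toolkit for **emergency care networks (ECNs)** — clusters of
hospitals and points of care (POCs) that collaborate by transferring
low-acuity emergency patients so that waiting times fall network-wide while
every node stays financially sustainable.

It is written for healthcare operations researchers, ED administrators and
health-system planners who need to answer, quantitatively:

- How capable is each ED of meeting a waiting-time standard (upper
  specification limit, USL = 30 min by default)?
- If nodes collaborate, who should transfer whom, where, and when?
- What does the network look like in steady state — waits, bed occupancy,
  blocking — under realistic weekday × time-slot arrival patterns?
- How should the per-admission payment be split between origin and
  destination nodes so that collaboration pays for both?

## What is inside

| module | purpose |
|---|---|
| `ecnsim.scenario` | network domain model, YAML/JSON (de)serialisation, a built-in 2-hospital + 8-POC case network, and a seeded synthetic-scenario generator |
| `ecnsim.des_engine` | discrete-event simulation of patient flow (triage → admission → bed preparation → nursing → physician → treatment), warm-up detection, replication sizing, validation statistics |
| `ecnsim.transfer_policy` | the transfer rules: triage-4/5 only, insurer agreements on both ends, no patient dumping, destination = argmin(expected wait + transfer time) |
| `ecnsim.payment` | the collateral payment model: destination share `max{floor, M(1+r)/(1+γ+θ)}`, coalition statements, network profit aggregation |
| `ecnsim.capability` | six-sigma diagnostics: `Zu = (USL−μ)/σ`, `Cps = Zu/3`, PPM, efficiency, short/long-term sigma levels, X-mR control charts |
| `ecnsim.input_analysis` | runs test, Kruskal-Wallis homogeneity, chi-squared goodness of fit, 21-pipeline (weekday × slot) arrival partitioning |
| `ecnsim.fmea` | failure-mode scoring, `RPN = S·F·D`, prioritisation flags for RPN > 125 |
| `ecnsim.cli` | `ecnsim` command: `gen-scenario`, `simulate`, `transfer-plan`, `settle`, `capability`, `control-chart`, `input-analysis`, `fmea` |

## The models in brief

**Capability.** Waiting times are judged against a one-sided upper limit.
Under a normal model, `Zu = (USL − μ)/σ` is the short-term sigma level, the
long-term level subtracts the conventional 1.5-sigma shift, and
`PPM = 10⁶·Φ(−Zu)` is the expected number of admissions per million that
exceed the standard.

**Transfer policy.** After triage, a level-4/5 patient at origin *o* may move
to destination *d* iff both nodes hold an agreement with the patient's
insurer and

```
E[wait_d] + transfer_time(o → d, slot)  <  E[wait_o]
```

choosing the *d* with the lowest sum (ties: lowest node id). Uncovered and
special-regime patients are always treated at the origin.

**Collateral payment.** For each transferred admission with insurer-agreed
unit utility `M`, the destination receives
`max{floor_arrangement, M(1+r)/(1+γ+θ)}` and the origin the remainder, where
`r` is the correlation between the destination's waiting time and the
transferred admissions it receives, and `γ, θ` are the triage-4/5 population
shares (0.19 and 0.46 in the case network). Same-node admissions pay `M` to
the treating node.

## Worked example

```python
import ecnsim

case = ecnsim.case_study_scenario()          # 2 hospitals + 8 POCs

# 1. how capable was the worst POC before improvement?
rep = ecnsim.capability_metrics(mean=201.6, sd=81.6, usl=30)
print(round(rep.zu, 2), round(rep.sigma_long, 2), round(rep.p_error, 4))
# -2.1 -3.6 0.9822   -> catastrophic: ~98% of patients exceed the standard

# 2. where should a triage-4 patient at POC1 go (planning mode)?
est = ecnsim.planning_estimates(case)
cands = ecnsim.eligible_destinations(4, "S", "POC1", case)
d = ecnsim.select_destination(1, "POC1", cands, est,
                              case.transfer_times, "P2")
print(d.verdict, d.destination, round(d.candidate_scores["H2"], 2))
# transfer H2 22.71   -> 3.71 min expected wait + 19 min transfer < 126.03

# 3. what does the destination earn per transferred S-insured patient?
rule = ecnsim.SettlementRule.from_scenario(case)
print(round(ecnsim.destination_share(10.34, 0.015, "A", rule), 2))
# 6.36   (and the origin keeps 10.34 - 6.36 = 3.98)

# 4. simulate the network with transfers for 40 days (10 warm-up)
pol = ecnsim.TransferPolicy(case)
res = ecnsim.simulate(case, pol, horizon=40, warmup=10, seed=3)
print(res.arrivals == res.departures + res.in_system_at_end)  # True
```

Or from the shell:

```bash
ecnsim capability --usl 30 --mean 201.6 --sd 81.6
ecnsim transfer-plan --case-study --outdir plan/
ecnsim simulate --case-study --reps 10 --horizon 40 --warmup 10 --seed 7 \
       --transfers --outdir simout/
```

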