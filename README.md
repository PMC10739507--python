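# hypnoval

Validation statistics for automatic sleep staging against multi-rater manual
scoring.

Sleep laboratories validate an automatic sleep-stage scorer by comparing its
30-second-epoch hypnograms against manual staging — typically several
technicians scoring the same polysomnograms independently, plus the staging
produced during clinical practice. `hypnoval` implements the full statistical
pipeline for such a study, for method developers and sleep-lab analysts:

- **Hypnogram I/O and alignment** over the five-stage vocabulary W, N1, N2,
  N3, R (plus U for unclassifiable epochs). Scorers may stop staging at
  slightly different end points; each analysis uses exactly the epochs staged
  (non-U) by every scorer it considers.
- **Majority-vote consensus** across a technician panel: an epoch gets a
  consensus stage when a unique plurality ≥ 2 raters agree, with explicit
  full / partial / non-consensus bookkeeping.
- **Epoch-level agreement statistics** from pooled confusion matrices
  (reference scorer in rows, test scorer in columns): overall percent
  agreement OPA = tr(C)/N; Cohen's κ = (p_o − p_e)/(1 − p_e); and per stage
  *s* with TP = C_ss, PPA = TP/ref_s, NPA = (N − ref_s − test_s + TP)/(N −
  ref_s), PPV = TP/test_s. Zero-denominator ratios propagate as missing,
  never as 0.
- **Direct machine-vs-panel comparison**: the machine's average agreement
  with each technician (machine always the test scorer) minus the
  technicians' average agreement among themselves (all ordered pairs — six
  for three raters, since agreement of A referenced on B differs from B
  referenced on A), evaluated on *all* co-staged epochs so that hard
  non-consensus epochs are not discarded.
- **Macrostructure indices** per hypnogram — TST, sleep latency, REM
  latency, sleep efficiency, WASO and per-stage times — with between-scorer
  reliability measured by the absolute-agreement intraclass correlation
  ICC(A,1) = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)), interpreted on
  the conventional bands (< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good,
  > 0.9 excellent).
- **Recording-level (cluster) bootstrap** for all of the above: whole
  recordings are resampled with replacement (10,000 resamples by default),
  the median of the resample distribution is the point estimate, the
  2.5th/97.5th percentiles form the 95% CI, and a difference is significant
  when both CI bounds share a sign. Differences are paired — one resample
  drives both statistics.
- **A synthetic cohort generator** (Markov truth model + per-rater confusion
  noise, U injection and end-of-recording truncation) so the whole pipeline
  is testable without access to clinical recordings.

## Worked example

Generate a synthetic 10-recording study (three technicians, one clinical
scorer, one automatic scorer) and run the full validation:

```bash
$ hypnoval simulate --out-dir demo/study --recordings 10 --seed 7 --resamples 2000
wrote demo/study/manifest.yaml

$ hypnoval validate --manifest demo/study/manifest.yaml --out-dir demo/report
10 recordings, 8868 panel epochs (full 75.47%, partial 23.29%, non-consensus 1.24%)
report written to demo/report
```

75.47% of epochs were staged identically by all three technicians, 23.29%
by exactly two, and 1.24% had no consensus — the level of three-rater
agreement expected from experienced scorers. `demo/report/` now contains
CSV tables (pooled confusion matrix, agreement statistics with bootstrap
CIs, machine-vs-panel differences with significance flags, ICC tables) plus
`report.json` and a per-recording `run.log`.

Single-pair statistics are available directly:

```bash
$ hypnoval agreement demo/study/hypnograms/rec001_tech1.csv \
                     demo/study/hypnograms/rec001_machine.csv
epochs compared: 850
OPA   = 82.59%
kappa = 0.7744
  W: PPA 87.20%  NPA 96.21%  PPV 84.62%
 N1: PPA 75.00%  NPA 95.61%  PPV 62.64%
...
```

Here the machine agrees with technician 1 on 82.59% of the 850 co-staged
epochs of this recording; κ = 0.77 is that agreement corrected for chance.
An excerpt of the ICC table from the full report:

```
index    machine_vs_panel_median  within_panel_median  difference_median  significant
tst      0.9899                   0.9863               0.0038             none
se       0.9774                   0.9644               0.0125             positive
time_n1  0.8424                   0.9263              -0.0806             negative
```

Total sleep time is scored with excellent machine-technician reliability
(ICC 0.99), indistinguishable from technician-technician reliability; for
time in N1 — the hardest stage — the machine is significantly less reliable
than the human panel on this cohort (both CI bounds below 0).

The same functionality is available as a library
(`hypnoval.run_validation_study`, `hypnoval.agreement`, `hypnoval.icc`, …);
see the module docstrings and `docs/methods.md` for the statistical
conventions.

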