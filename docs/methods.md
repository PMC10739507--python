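# Methods

This note records the statistical conventions, model assumptions and design
choices behind `hypnoval`, in the order the pipeline applies them.

## Epoch retention and alignment

Staging is per 30-s epoch (hard-coded: all index arithmetic converts counts
to minutes at 0.5 min/epoch). Scorers blinded to lights-on times may stop
staging a recording a few epochs apart, so alignment truncates sequences at
the *end only*, to the shortest scorer. Epochs any scorer marked U
(unclassifiable) are then removed. Retention is recomputed independently per
analysis: the machine-vs-clinical analysis may retain epochs the
machine-vs-panel analysis dropped, because each analysis conditions only on
the scorers it uses. A recording whose retained set is empty is skipped with
a logged note rather than failing the study.

## Consensus

With three raters, a consensus epoch is one where at least two agree; full
agreement (all three), partial agreement (exactly two) and non-consensus
(all different) are tallied and reported as percentages of the aligned
epochs. For panels of four or more raters a tie for the top vote count is
treated as non-consensus — the conservative generalisation of the
two-of-three rule. Consensus sequences export in the hypnogram CSV dialect
with `U` marking non-consensus epochs.

## Agreement statistics

All epoch-level statistics derive from pooled confusion matrices (epochs
pooled across recordings — the micro-average; reference scorer in rows).
Cohen's κ uses the standard marginal-product chance correction and is
undefined (NaN, flagged) when expected agreement is 1, i.e. both scorers
constant on the same stage — never silently 0. Per-stage PPA/NPA/PPV are
undefined when their denominator is 0; panel averages skip undefined
contributors and report how many were skipped, because imputing 0 would
bias the averages downward.

Directionality: PPA/NPA/PPV are not symmetric in scorer order, so the
within-panel average runs over all *ordered* technician pairs (six values
for three technicians), which makes the within-panel average PPA equal the
average PPV stage by stage. The machine enters only as the test scorer with
each technician as reference (three values), reflecting that the question
is how well the machine reproduces human staging, not the reverse.

## Macrostructure indices

Sleep onset is the first epoch of any sleep stage (N1/N2/N3/R). TST is time
in sleep stages; SL is lights-off to onset; REML is onset to the first R
epoch; SE = 100·TST/TIB; WASO is all non-sleep time from onset to lights-on,
terminal wake included. U epochs count toward TIB, toward the latency region
before onset and toward WASO after onset, never toward TST; under these
rules SL + TST + WASO = TIB exactly whenever SL is defined, and the suite
asserts that identity on 10,000 random sequences. Recordings with no sleep
epoch have SL/REML/WASO *missing*, not zero — a zero latency on a no-sleep
recording would fabricate agreement in the downstream ICCs, which instead
drop incomplete pairs with a reported count.

## ICC(A,1)

Reliability of each macrostructure index between two scorers uses the
two-way, single-measure, absolute-agreement intraclass correlation
(McGraw–Wong A,1), computed from the ANOVA mean squares without
replication: ICC = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)). The
absolute-agreement form penalises systematic between-scorer offsets, which
a consistency ICC would ignore. Only pairwise (k = 2) ICCs are computed and
averaged — machine×technician pairs versus technician×technician pairs —
because the study design compares scorer pairs, not a single pooled
multi-rater reliability; ICC is symmetric in column order, so the three
unordered technician pairs suffice. Interpretation bands: < 0.5 poor,
[0.5, 0.75) moderate, [0.75, 0.9) good, [0.9, 1] excellent; exact boundary
values are assigned to the upper band and flagged in the result object.
Degenerate tables (zero denominator, e.g. all ratings equal) yield an
undefined ICC, skipped from averages with a report. ICC confidence
intervals come from the cluster bootstrap, not from F-distribution theory.

## Cluster bootstrap

Epochs within a recording are strongly autocorrelated, so resampling
resamples *whole recordings* with replacement (the recording is the
exchangeable unit). Defaults follow the standard design: 10,000 resamples,
point estimate = median of the resample distribution, 95% CI = 2.5th and
97.5th percentiles with linear interpolation (the median of an even-length
distribution is the midpoint of the central order statistics). A difference
statistic is evaluated *paired* — the same resample feeds both terms — so
the CI-sign significance rule (significant iff both bounds share a sign) is
meaningful; independent resampling would inflate the difference variance.
Resamples where a statistic is undefined (a stage absent from every
resampled recording, an ICC with < 2 complete pairs) are dropped from that
statistic's distribution with the retained count reported. All randomness
derives from one seed via spawned seed sequences; a run is byte-identical
under the same manifest and seed.

For performance, the pipeline reduces each recording once to sufficient
statistics (per-pair confusion matrices and a scorer×index macro table) and
each bootstrap statistic returns a whole vector of table cells, so one
resample pass fills an entire report table. A full 40-recording study with
10,000 resamples through all six analyses completes in well under a minute
on one CPU.

## Synthetic cohorts

The generator emulates the structure the statistics assume, not sleep
physiology in detail:

- **Truth model**: first-order Markov chain over the five stages with
  self-transition 0.85 and off-diagonal mass proportional to a fixed stage
  mix (21% W, 8% N1, 40% N2, 17% N3, 14% R — typical of clinical cohorts),
  which is exactly its stationary distribution. Recordings start awake
  (initial mass 0.95 W / 0.05 N1) and draw 780–1020 epochs (6.5–8.5 h in
  bed) with a jittered lights-off clock around 22:20.
- **Rater model**: independent per-epoch mis-scoring through a row-stochastic
  confusion matrix, optional U injection, and a random number of trailing
  epochs left unstaged. Defaults: technicians use symmetric error ε = 0.09 —
  chosen because it gives pairwise technician agreement (1−ε)² + 4(ε/4)² ≈
  0.83 and three-rater full consensus (1−ε)³ + 4(ε/4)³ ≈ 0.75, the levels
  reported for experienced scorers — with 0–3 truncated epochs each; the
  automatic scorer uses ε = 0.10 (slightly noisier than one technician, no
  truncation); the clinical staging uses ε = 0.11 with a 10⁻⁴ U rate.

What the generator does **not** reproduce, and hence what passing tests do
not show about real data: ultradian REM cycling and stage-bout dwell times
(a semi-Markov structure — under the Markov model REM can occur near onset,
so REM latency and sleep latency have little between-subject variance and
their synthetic ICCs are unstably low); stage-dependent rater confusion
(real scorers confuse W↔N1 far more than W↔N3, so synthetic per-stage PPAs
are more uniform than clinical ones); and correlated rater errors (raters
trained in the same laboratory agree more with each other than independence
predicts). The generator exercises every code path and statistical property;
it does not predict clinical effect sizes.

## Numerical conventions

Undefined values are NaN throughout and never compare equal to a number;
report tables round percentages to 2 decimals and κ/ICC to 4. The ANOVA
residual sum of squares is clipped at 0 against floating-point cancellation.
Percentile and median computations delegate to numpy's nan-aware routines.
Report files contain no timestamps so re-runs are byte-comparable.

## Problem sizes used in the checks

The acceptance checks run the default study conditions — 40 recordings,
five scorers, 10,000 resamples — end to end. Supporting property checks use
sizes chosen for statistical resolution: confusion-matrix recovery at
50,000 epochs (±0.01 per cell), ICC variance-components recovery at 5,000
subjects (±0.02), CI coverage over 500 simulated 15-recording cohorts with
1,000 resamples each (coverage within [92%, 98%] for a nominal 95% CI), and
exhaustive enumeration wherever the space is small (all 125 three-rater
vote patterns; all 27 resamples of a three-recording bootstrap).
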