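# turntimes

Tools for studying why turns in conversation follow each other so quickly —
and in particular how **competition for the turn** shrinks recorded
turn-transition times in multi-party conversation, purely as a sampling
effect: when several interlocutors plan a response but only the fastest one
gets the floor, a corpus records the *minimum* of several latent response
times, not all of them.

The package is aimed at psycholinguists and conversation-analysis
researchers who work with response-time experiments or annotated
conversation corpora. It implements two complementary computations:

1. **Winner-takes-the-turn simulation** (`turntimes.winner`). Given
   trial-level response times for a panel of participants, form all
   k-member sets, draw one response time per member per simulated trial,
   and record the winning (minimum) time. For k members with iid latencies
   the recorded time is the first order statistic `X(1) = min(X_1..X_k)`;
   e.g. for two iid Normal(μ, σ) responders, `E[X(1)] = μ − σ/√π`, so the
   mean drops by `σ/√π` (≈ 100 ms at σ = 177 ms) without any change in
   behavior. Medians move less than means because the minimum discards the
   slow tail first. Sweeping k shows the gain plateauing once the fast edge
   of the pool is exhausted.

2. **Turn-transition pipeline** (`turntimes.transitions`,
   `turntimes.stats`). Offset-to-onset transition times between
   consecutive turns of different speakers (negative = overlap, positive =
   gap), question–response (QR) vs non-QR typing from annotation labels,
   exclusion categories (backchannels, interrupted turns, extended
   silences, unclear overlap, laughter starts), grouped 1.5 × IQR outlier
   filtering, and two mixed models:

   * transition time:
     `transition_ms ~ 1 + overlap/(group_size × type) + (1 + overlap + type | responder)`
     fitted by ML, with sum-to-zero contrasts (dyad = +0.5, QR = +0.5)
     nested within each overlap level;
   * overlap probability (binomial, logit link):
     `overlap ~ 1 + group_size × type + (1 + type | responder)`
     fitted by ML with a Laplace approximation, decomposed into the
     group-size effect within each transition type via marginal contrasts.

Synthetic generators (`turntimes.synthetic`) produce response-time datasets
(ex-Gaussian and bimodal-mixture conditions) and conversation corpora with
known injected effects, so every step of both studies runs — and is tested
for parameter recovery — without any proprietary corpus.

## Worked example

Simulate a 20-participant picture-question answering experiment and ask how
much the mean response time drops if, per trial, only the faster of two
participants were recorded:

```bash
$ turntimes gen-rt --seed 1 --out rt.csv
$ turntimes simulate-winners --rt-csv rt.csv --k 2 --seed 1 --out winners
filtered 99 of 2560 records (3.87%)
   display    response  observed_mean  winner_mean  gain_mean  gain_median
monochrome affirmative          218.5         77.4      141.1        210.5
monochrome    negative          191.6         48.6      143.0        244.3
multicolor affirmative          331.5        250.8       80.7         71.2
multicolor    negative          403.0        321.1       81.9         62.3
```

Records flagged incorrect and responses beyond ±2.5 SD of their condition
mean are filtered first. In the unimodal right-skewed (multi-color)
conditions the pairwise winner is ~81 ms faster on average, and the median
gain is smaller than the mean gain — the minimum trims the slow tail first.
In the bimodal monochrome conditions (where responses may start before the
question ends) the winner distribution shifts onto the early mode, so gains
are larger.

Then extract and model transitions from a synthetic dyad/triad corpus:

```bash
$ turntimes gen-corpus --seed 1 --out corpus.csv
$ turntimes extract-transitions --corpus corpus.csv --out transitions.tsv
1661 transitions measured; 377 excluded; 0 outliers (0.00%); 1284 kept
$ turntimes fit-models --transitions transitions.tsv --model glmm --out fits
            estimate        se       stat             p
const      -0.747939  0.066250 -11.289559  1.477769e-29
group_size -0.053590  0.132501  -0.404449  6.858822e-01
type_qr     0.353421  0.130348   2.711367  6.700637e-03
gs_x_qr     0.697213  0.260696   2.674433  7.485562e-03
group_size within QR: estimate=0.295 se=0.215 z=1.37 p=0.1706
group_size within nonQR: estimate=-0.402 se=0.151 z=-2.67 p=0.007663
```

With dyads coded +0.5, the negative within-nonQR contrast says overlap is
significantly more probable for triads than dyads in non-QR transitions,
while the QR contrast is null — the generator's default overlap
probabilities encode exactly that asymmetry, and the model recovers it.

`turntimes run --mode both --seed 1 --out results_dir` runs the whole
pipeline (generation → filtering → simulation/extraction → models) and
writes a JSON report whose stage counts reconcile exactly.

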