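# eegfsel

Filter + wrapper feature selection for EEG band-power features, built around a
supervised fuzzy-rule classifier with a learn / prune / vote protocol.

The package targets the precomputed-feature format of the BCI Competition III
Data Set V three-class motor-imagery task: 96 PSD features per analysis window
(8 channels × 12 bands, 8–30 Hz at 2 Hz resolution, channel-major order),
16 feature vectors per second, task labels {2, 3, 7}.  It reduces the
96-dimensional vector to a handful of features in three stages:

1. **Discriminant criteria** (`eegfsel.criteria`) — per-feature separability
   scores.  *Statistical route*: class-prior-weighted normalized within-class
   variances with an entropy-form and a product-form criterion (the product
   form is bounded by (1/C)^C, attained only by non-discriminant features).
   *Fuzzy route*: pairwise overlap (∫min/∫max) of per-class prototype fuzzy
   sets taken from an intermediate one-rule-per-class summary of the
   classifier.
2. **Score / order / candidate selection** (`eegfsel.selection`) — each
   criterion run awards 10..1 points to its ten most discriminant features
   (3 statistical runs, one per learning session; 6 fuzzy runs, one per
   (learn, prune) session pair); accumulated scores are cut at the smallest
   head whose cumulative score fraction strictly exceeds ρ (default 0.85).
3. **Wrapper selection** (`eegfsel.selection`) — *Order Selection* evaluates
   every score-ordered prefix of the candidate list; *GMDH selection* grows a
   subset greedily, accepting the best single-feature extension only while
   the Regularity Criterion (RC — mean held-out vote accuracy over the six
   (learn, prune, test) permutations of the three learning sessions) strictly
   improves.

Supporting modules: `eegfsel.classifier` (trapezoidal fuzzy-rule classifier:
one-pass vigilance-gated learning, error-vs-success rule pruning, six-model
construction, 48-vote decisions every half second), `eegfsel.preprocessing`
(Hjorth surface Laplacian + sliding-window Welch/periodogram band powers:
1 s windows, 32-sample hop at 512 Hz → 93.75% overlap, 16 vectors/s),
`eegfsel.session` (session/report I/O and the channel-band index layout),
`eegfsel.synthetic` (labeled session generator with injected discriminant
structure for testing without the competition download), and
`eegfsel.benchmark` (published reference selections used for cross-user
unified-model set algebra).

## CLI

```sh
# generate synthetic sessions with 4 injected informative features
eegfsel simulate --n-sessions 3 --informative 2,14,38,61 --effect-size 3 \
    --session-minutes 1 --seed 1 --outdir scratch/sessions

# full three-stage selection (criterion: statistic|fuzzy, wrapper: order|gmdh)
eegfsel select scratch/sessions/session*.txt \
    --criterion statistic --wrapper gmdh --rho 0.85 --out scratch/report.json

# per-feature criterion table, RC of an explicit subset, unified model
eegfsel criteria scratch/sessions/session1.txt
eegfsel evaluate scratch/sessions/session*.txt --features 2,14,38
eegfsel unified selections.json

# raw-signal entry point: Laplacian + sliding-window PSD from a plain matrix
eegfsel preprocess raw.txt --channels C3,Cz,C4,CP1,CP2,P3,Pz,P4 --out sess.txt
```

Session files are plain text: `competition_ascii` (one window per line,
whitespace-separated features + integer label) or `csv` with an
`f1..fN,label` header.  Selection reports are JSON and embed the resolved
configuration and seed.

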