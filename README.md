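# icmdlm

Tools for asking *what makes a long dependency costly*: the number of words
between a head and its dependent (**dependency length**, DL), or the number
of those words that are themselves syntactic heads (**intervener
complexity**, IC)?

`icmdlm` is a corpus-analysis pipeline for dependency treebanks (CoNLL-U).
It compares real dependency trees against six families of random baseline
trees — uniform random tree structures and random linear arrangements
(RLAs), plain or additionally constrained to reproduce the real tree's
multiset of per-edge DL or IC values, all matched on sentence length and
crossing count — and fits by-language linear mixed-effects interaction
models to test whether DL or IC grows more slowly with sentence length in
real trees than in the baselines.  The matched families make the tests
*independence* tests: IC-minimization measured with DL clamped, and vice
versa.

Intended users: computational/quantitative linguists and cognitive
scientists running word-order minimization analyses on Universal
Dependencies-style treebanks (SUD or UD), or stress-testing such analyses
on synthetic corpora with planted ordering pressures.

## The model

For sentence *i* of language *j*, with response *y* the per-sentence mean
IC or mean DL, sentence length *S*, and *R* = 1 for a real tree, 0 for its
baseline partner:

```
y_ij = (β0 + u0j) + (β1 + u1j)·S_ij + (β2 + u2j)·R_ij + (β3 + u3j)·S_ij·R_ij + ε
```

fit by REML with by-language random intercepts and slopes.  The quantity of
interest is the interaction **β3**: significantly negative (|t| > 2) means
the response grows more slowly with length in real trees than in the
matched baseline — evidence for minimization; the main effect β2 is
reported alongside.

## Worked example

Generate a synthetic 4-language corpus whose word order is produced by a
dependency-length-minimizing heuristic, then test it against the
random-structures baseline:

```python
from icmdlm import (BaselineSpec, ExperimentConfig, SynthCorpusSpec,
                    gen_corpus, run_experiment, summarize_fit)

corpus = gen_corpus(SynthCorpusSpec(n_languages=4, sentences_per_language=120,
                                    ordering_policy="dlm_greedy", seed=42))
cfg = ExperimentConfig(
    baselines=[BaselineSpec(kind="random_structures", seed=7, max_attempts=60_000)],
    responses=("ic", "dl"), seed=42)
result = run_experiment(cfg, corpus)
print(result.verdicts.to_string(index=False))
```

```
 hypothesis          baseline response     beta3         t3    beta2       t2   verdict  n_pairs
        ICM random_structures       ic -0.060805 -10.959902 0.174807 5.039150 supported      480
exploratory random_structures       dl -0.070588  -6.470046 0.032063 0.469805 supported      480
```

Both responses grow significantly more slowly with sentence length in the
ordered corpus than in its length- and crossing-matched random baselines
(β3 < 0, |t| > 2): the planted minimization pressure is detected, on all
480 surviving real/baseline pairs.  The full estimates table for one fit:

```python
print(summarize_fit(result.fits[("random_structures", "ic")]).to_string(index=False))
```

```
         term  estimate       se          t sig
    Intercept -0.264044 0.024521 -10.767860   *
     S.length  0.089690 0.004092  21.918990   *
         Real  0.174807 0.034690   5.039150   *
S.length:Real -0.060805 0.005548 -10.959902   *
```

The same pipeline runs from the shell on real treebanks:

```
icmdlm filter --max-len 11 --min-len 3 in.conllu short.conllu
icmdlm metrics short.conllu -o metrics.tsv --per-edge edges.tsv
icmdlm baseline short.conllu --kind ic_matched_rla --seed 7 -o baseline.conllu --report report.tsv
icmdlm fit --response dl --real short.conllu --baseline baseline.conllu -o estimates.tsv
icmdlm run config.yaml        # the whole experiment from a YAML config
```

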