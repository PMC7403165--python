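# gpcmix

Estimation and description of how beginning readers pronounce pseudowords:
mixture weights over grapheme–phoneme correspondence (GPC) types, entropy
statistics of response variability, orthographic-cluster consistency, and
test–retest overlap.

## The scientific problem

When a child reads aloud a pseudoword like *wact* or *kalt*, the vowel can be
pronounced according to the **simple GPC** (*a* → /æ/) or according to
**context-sensitive GPCs**: an onset context rule (*[w]a* → /ɔ/, `CS_O`) or a
body context rule (*a[l][C]* → /o:/, `CS_B`). In German the analogous contrast
is between the default short-vowel reading, the vowel-length **super-rule**
(one body consonant signals a long vowel, `SR`) and the body rule. A child's
responses across a four-condition design (context rules supporting or
contradicting the simple GPC) carry information about how strongly they weight
each rule type.

`gpcmix` models the probability of each vowel response as a convex combination
of the rule types' corpus conditional probabilities:

```
P(category | condition) = Σ_j β_j · P(category | rule_j, condition)
```

with β_j ∈ [0, 1] and Σ β_j = 1, estimated per participant by constrained
least squares over all (condition, category) cells (a relaxed variant drops
the constraints entirely). Around this core the package provides:

- **response_data** — validated trial-level tables, error-rate filters
  (participants > 50 %, items > 60 %, strict inequalities), condition
  summaries;
- **entropy** — item- and participant-level Shannon entropy of response
  distributions in bits, with design-appropriate error exclusions;
- **lexicon** — cluster frequency / consistency / pronunciation-entropy
  statistics from pronounced wordlists, and derivation of the corpus
  probability tables from any wordlist;
- **reliability** — two-session response-overlap coding and per-child overlap
  proportions;
- **simulate** — a seeded generator of mixture-plus-lapse responders (sample
  a rule type from β, then a response from its conditional distribution, then
  lapse uniformly with probability λ) used to validate the whole pipeline;
- **pipeline / CLI** — `gpcmix run` orchestrating
  simulate → filter → fit → entropy → reliability into a table bundle.

## Worked example

```python
import numpy as np
from gpcmix import (SimulationProfile, english_preset, simulate_study,
                    fit_all_participants, model_fit_correlation)

design, probs = english_preset()          # 4 conditions, synthetic corpus table
profile = SimulationProfile(
    n_participants_per_grade={2: 100},
    true_beta=(0.2, 0.7, 0.1),            # simpleGPC, CS_O, CS_B
    lapse_rate=0.0,
    seed=7,
    items_per_condition={c: 50 for c in design.conditions},
)
responses = simulate_study(profile, design, probs)
fits = fit_all_participants(responses, probs, design)
print(np.mean([f.beta for f in fits], axis=0).round(4))
print(model_fit_correlation(fits, responses, probs, design, group_by=None))
```

prints

```
[0.2004 0.6983 0.1013]
{'all': 0.9891932646412964}
```

— the cohort-averaged fitted weights recover the generating weights
(0.2, 0.7, 0.1) to within 0.002, and the pooled observed-vs-predicted
percentages correlate at r ≈ 0.99. Adding response noise (`lapse_rate=0.3`)
degrades the model fit and inflates item entropy; `analysis/` contains the
numbered scripts that run these studies end to end
(`01_simulate_cohorts.py` … `06_parameter_recovery.py`), writing their tables
to `results/`.

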