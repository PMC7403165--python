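#!/usr/bin/env python
"""Simulate the two study cohorts.

Generates an English-style cohort (grades 2-4, onset/body context rules for
the grapheme *a*) and a German-style cohort (vowel-length super-rule, binary
short/long outcome), each 20 children per grade with 16 items per condition,
a 10% lapse rate and a 5% consonant-error rate — response tables with the
statistical structure the downstream analyses assume.  Writes
results/responses_english.csv and results/responses_german.csv.
"""

from pathlib import Path

from gpcmix import SimulationProfile, english_preset, german_preset, simulate_study
from gpcmix.response_data import write_responses

OUT = Path(__file__).resolve().parent.parent / "results"

COHORTS = {
    "english": (english_preset(), {2: (0.2, 0.7, 0.1), 3: (0.1, 0.8, 0.1),
                                   4: (0.2, 0.65, 0.15)}),
    "german": (german_preset(), {2: (0.6, 0.34, 0.06), 3: (0.6, 0.28, 0.12),
                                 4: (0.5, 0.3, 0.2)}),
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for name, ((design, probs), betas) in COHORTS.items():
        profile = SimulationProfile(
            n_participants_per_grade={g: 20 for g in betas},
            true_beta=betas,
            lapse_rate=0.10,
            consonant_error_rate=0.05,
            seed=2024,
        )
        df = simulate_study(profile, design, probs)
        path = OUT / f"responses_{name}.csv"
        write_responses(df, path)
        print(f"{name}: {df['participant_id'].nunique()} participants, "
              f"{len(df)} trials -> {path.name}")


if __name__ == "__main__":
    main()
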