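#!/usr/bin/env python
"""Quantify response variability with item- and participant-level entropy.

For each cohort: per-item entropy of the vowel-response distribution
(consonant-error trials excluded; for the German cohort, error trials
excluded and entropy bounded by 1 bit), summarised by condition and grade,
and per-participant entropy overall and per condition.  Prints the
multiple-comparison note used when the participant-level entropies are
correlated with reading-ability measures.  Writes item_entropy_<cohort>.csv,
entropy_by_condition_<cohort>.csv and participant_entropy_<cohort>.csv.
"""

from pathlib import Path

from gpcmix import english_preset, german_preset
from gpcmix.entropy import (
    condition_entropy_summary,
    item_entropy,
    participant_entropy,
)
from gpcmix.pipeline import multiple_comparison_note
from gpcmix.response_data import apply_filters, read_responses

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for name, (design, _) in [("english", english_preset()),
                              ("german", german_preset())]:
        df = read_responses(OUT / f"responses_{name}.csv", design)
        kept, _ = apply_filters(df)

        items = item_entropy(kept, design, group_by="grade")
        items.to_csv(OUT / f"item_entropy_{name}.csv", index=False)
        by_cond = condition_entropy_summary(items)
        by_cond.to_csv(OUT / f"entropy_by_condition_{name}.csv", index=False)
        print(f"\n=== {name} cohort: mean item entropy (bits) ===")
        pivot = by_cond.pivot(index="condition", columns="grade", values="mean")
        print(pivot.round(3).to_string())

        per = participant_entropy(kept, design, per_condition=True)
        per.to_csv(OUT / f"participant_entropy_{name}.csv", index=False)
        overall = participant_entropy(kept, design)
        print(f"participant-level entropy: mean {overall['entropy_bits'].mean():.3f}"
              f" (SD {overall['entropy_bits'].std(ddof=1):.3f})")
    print("\n" + multiple_comparison_note())


if __name__ == "__main__":
    main()
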