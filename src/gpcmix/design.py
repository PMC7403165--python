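"""Study designs and corpus conditional-probability tables.

A pseudoword reading-aloud study is described by a :class:`StudyDesign`
(conditions, modeled response categories, grapheme-phoneme rule types) and a
:class:`CorpusProbabilityTable` holding, for every condition and rule type,
the conditional probability of each modeled response category given that the
reader applies that rule in that condition's orthographic context.

Two preset designs ship with the package:

* an English-style design crossing an onset context rule (CS_O, e.g.
  ``[w]a`` -> /ɔ/) with a body context rule (CS_B, e.g. ``a[l][C]`` -> /o:/)
  against the context-free simple correspondence ``a`` -> /æ/;
* a German-style design crossing the vowel-length super-rule (SR: one body
  consonant signals a long vowel) with a body rule, with a binary
  short/long outcome.

The preset probability tables are synthetic fixtures with the qualitative
structure of corpus statistics; they are not derived from any lexical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

ENGLISH_STYLE = "english_style"
GERMAN_STYLE = "german_style"

#: response label used for transcribed vowels outside the modeled set (English)
OTHER_VOWEL = "other_vowel"
#: response label for consonant errors / non-responses
CONSONANT_ERROR = "consonant_error"
#: response label for German trials scored as incorrect (consonant or vowel error)
ERROR = "error"


@dataclass(frozen=True)
class StudyDesign:
    """A four-condition, three-rule reading-aloud design.

    Parameters
    ----------
    language_mode:
        ``"english_style"`` (multi-category vowel outcome, consonant errors
        and non-responses are the error trials) or ``"german_style"``
        (binary short/long outcome, consonant *and* vowel errors are error
        trials).
    conditions:
        The four condition labels.
    response_categories:
        The modeled response categories, in a fixed order (exactly two for
        ``german_style``).
    rule_types:
        The three rule-type labels, in the order used for weight vectors.
    items_per_condition:
        Number of items per condition.
    """

    language_mode: str
    conditions: tuple[str, ...]
    response_categories: tuple[str, ...]
    rule_types: tuple[str, ...]
    items_per_condition: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.language_mode not in (ENGLISH_STYLE, GERMAN_STYLE):
            raise ValueError(f"unknown language_mode {self.language_mode!r}")
        if len(self.conditions) != 4:
            raise ValueError("a design has exactly 4 conditions")
        if len(self.rule_types) != 3:
            raise ValueError("a design has exactly 3 rule types")
        if self.language_mode == GERMAN_STYLE and len(self.response_categories) != 2:
            raise ValueError("german_style designs model exactly 2 response categories")
        object.__setattr__(
            self, "conditions", tuple(self.conditions)
        )
        object.__setattr__(
            self, "response_categories", tuple(self.response_categories)
        )
        object.__setattr__(self, "rule_types", tuple(self.rule_types))
        ipc = dict(self.items_per_condition) or {c: 16 for c in self.conditions}
        missing = set(self.conditions) - set(ipc)
        if missing:
            raise ValueError(f"items_per_condition missing conditions: {sorted(missing)}")
        object.__setattr__(self, "items_per_condition", ipc)

    @property
    def error_categories(self) -> tuple[str, ...]:
        """Labels that mark a trial as an error for this design."""
        if self.language_mode == ENGLISH_STYLE:
            return (CONSONANT_ERROR,)
        return (ERROR,)

    @property
    def valid_categories(self) -> tuple[str, ...]:
        """All response labels a record may carry."""
        extra = (OTHER_VOWEL,) if self.language_mode == ENGLISH_STYLE else ()
        return self.response_categories + extra + self.error_categories

    @property
    def lapse_categories(self) -> tuple[str, ...]:
        """Categories an unsystematic (lapse) response is drawn from."""
        if self.language_mode == ENGLISH_STYLE:
            return self.response_categories + (OTHER_VOWEL,)
        return self.response_categories

    def to_dict(self) -> dict:
        return {
            "language_mode": self.language_mode,
            "conditions": list(self.conditions),
            "response_categories": list(self.response_categories),
            "rule_types": list(self.rule_types),
            "items_per_condition": dict(self.items_per_condition),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyDesign":
        return cls(
            language_mode=d["language_mode"],
            conditions=tuple(d["conditions"]),
            response_categories=tuple(d["response_categories"]),
            rule_types=tuple(d["rule_types"]),
            items_per_condition=d.get("items_per_condition", {}),
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class CorpusProbabilityTable:
    """P(response category | rule type, condition).

    ``entries`` is a nested mapping ``condition -> rule_type -> category ->
    probability``.  For English-style designs the probabilities over modeled
    categories may sum to less than 1 within a (condition, rule type) cell —
    the residual mass stands for vowel responses outside the modeled set.
    German-style (binary) cells must sum to 1.
    """

    entries: dict

    def probability(self, condition: str, rule_type: str, category: str) -> float:
        try:
            cell = self.entries[condition][rule_type]
        except KeyError:
            raise KeyError(
                f"no corpus probabilities for condition {condition!r}, "
                f"rule type {rule_type!r}"
            ) from None
        return float(cell.get(category, 0.0))

    def rule_matrix(self, design: StudyDesign, condition: str) -> np.ndarray:
        """Matrix of shape (n_categories, 3): column j is rule j's
        conditional distribution over the modeled categories in *condition*."""
        cols = []
        for rule in design.rule_types:
            cols.append(
                [self.probability(condition, rule, cat) for cat in design.response_categories]
            )
        return np.array(cols, dtype=float).T

    def validate(self, design: StudyDesign) -> None:
        for cond in design.conditions:
            for rule in design.rule_types:
                cell = {
                    cat: self.probability(cond, rule, cat)
                    for cat in design.response_categories
                }
                for cat, p in cell.items():
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(
                            f"P({cat}|{rule},{cond}) = {p} outside [0, 1]"
                        )
                total = sum(cell.values())
                if total > 1.0 + 1e-9:
                    raise ValueError(
                        f"probabilities for ({cond}, {rule}) sum to {total} > 1"
                    )
                if design.language_mode == GERMAN_STYLE and abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"binary-outcome cell ({cond}, {rule}) must sum to 1, got {total}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "CorpusProbabilityTable":
        with open(path) as fh:
            return cls(entries=yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.entries, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Preset designs with synthetic fixture probability tables.

def english_preset() -> tuple[StudyDesign, CorpusProbabilityTable]:
    """English-style design (onset and body context rules for grapheme *a*).

    Conditions follow the convention ``CS_O±CS_B±``: ``+`` means the context
    rule agrees with the simple correspondence, ``-`` that it contradicts it
    (onset ``w``/``qu`` pulls toward /ɔ/, body ``al+C`` toward /o:/).
    The probability table is a synthetic fixture, not corpus-derived.
    """
    design = StudyDesign(
        language_mode=ENGLISH_STYLE,
        conditions=("CS_O+CS_B+", "CS_O-CS_B+", "CS_O+CS_B-", "CS_O-CS_B-"),
        response_categories=("ae", "open_o", "long_o"),
        rule_types=("simpleGPC", "CS_O", "CS_B"),
        items_per_condition={
            "CS_O+CS_B+": 16,
            "CS_O-CS_B+": 16,
            "CS_O+CS_B-": 16,
            "CS_O-CS_B-": 16,
        },
    )
    simple = {"ae": 0.88, "open_o": 0.05, "long_o": 0.03}
    cs_o_plus = {"ae": 0.82, "open_o": 0.08, "long_o": 0.04}
    cs_o_minus = {"ae": 0.12, "open_o": 0.76, "long_o": 0.06}
    cs_b_plus = {"ae": 0.86, "open_o": 0.06, "long_o": 0.03}
    cs_b_minus = {"ae": 0.10, "open_o": 0.14, "long_o": 0.70}
    entries = {
        "CS_O+CS_B+": {"simpleGPC": simple, "CS_O": cs_o_plus, "CS_B": cs_b_plus},
        "CS_O-CS_B+": {"simpleGPC": simple, "CS_O": cs_o_minus, "CS_B": cs_b_plus},
        "CS_O+CS_B-": {"simpleGPC": simple, "CS_O": cs_o_plus, "CS_B": cs_b_minus},
        "CS_O-CS_B-": {"simpleGPC": simple, "CS_O": cs_o_minus, "CS_B": cs_b_minus},
    }
    return design, CorpusProbabilityTable(entries=entries)


def german_preset() -> tuple[StudyDesign, CorpusProbabilityTable]:
    """German-style design (vowel-length super-rule and body rule), binary
    short/long outcome.  Probability fixture, not corpus-derived."""
    design = StudyDesign(
        language_mode=GERMAN_STYLE,
        conditions=("SR+CS_B+", "SR-CS_B+", "SR+CS_B-", "SR-CS_B-"),
        response_categories=("short", "long"),
        rule_types=("simpleGPC", "SR", "CS_B"),
        items_per_condition={
            "SR+CS_B+": 16,
            "SR-CS_B+": 16,
            "SR+CS_B-": 16,
            "SR-CS_B-": 16,
        },
    )
    simple = {"short": 0.80, "long": 0.20}
    sr_plus = {"short": 0.95, "long": 0.05}
    sr_minus = {"short": 0.10, "long": 0.90}
    cs_b_plus = {"short": 0.93, "long": 0.07}
    cs_b_minus = {"short": 0.08, "long": 0.92}
    entries = {
        "SR+CS_B+": {"simpleGPC": simple, "SR": sr_plus, "CS_B": cs_b_plus},
        "SR-CS_B+": {"simpleGPC": simple, "SR": sr_minus, "CS_B": cs_b_plus},
        "SR+CS_B-": {"simpleGPC": simple, "SR": sr_plus, "CS_B": cs_b_minus},
        "SR-CS_B-": {"simpleGPC": simple, "SR": sr_minus, "CS_B": cs_b_minus},
    }
    return design, CorpusProbabilityTable(entries=entries)
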