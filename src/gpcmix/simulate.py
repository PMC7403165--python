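"""Synthetic reading-aloud responders.

The generator implements the mechanism the analyses assume: on each trial a
simulated child first samples which rule type to apply from their weight
vector (the probability of relying on the simple correspondence versus each
context-sensitive rule), then samples a response from that rule's corpus
conditional distribution for the item's condition; a lapse process replaces
the response, with probability ``lapse_rate``, by a uniform draw over the
plausible response categories — an unsystematic error term.  Independently,
each trial may be a consonant error / non-response with probability
``consonant_error_rate``.

Randomness is fully reproducible: a single root seed plus deterministic
per-participant streams, so adding participants (or a second session) never
perturbs the trials of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import (
    CONSONANT_ERROR,
    ENGLISH_STYLE,
    ERROR,
    OTHER_VOWEL,
    CorpusProbabilityTable,
    StudyDesign,
    english_preset,
    german_preset,
)


@dataclass
class SimulationProfile:
    """Study-level parameters of a simulated cohort.

    ``true_beta`` is either a single length-3 simplex vector shared by every
    grade or a mapping grade -> vector.  ``dirichlet_concentration``, when
    set, draws each participant's personal weights from a Dirichlet centred
    on the grade vector (larger = less individual variation); the default is
    no heterogeneity, which parameter-recovery checks rely on.
    """

    n_participants_per_grade: Mapping[int, int]
    true_beta: Mapping[int, tuple] | tuple = (1.0, 0.0, 0.0)
    lapse_rate: float = 0.0
    consonant_error_rate: float = 0.0
    n_sessions: int = 1
    seed: int = 0
    dirichlet_concentration: float | None = None
    items_per_condition: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        for rate in (self.lapse_rate, self.consonant_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.n_sessions not in (1, 2):
            raise ValueError("n_sessions must be 1 or 2")
        for beta in self._betas().values():
            b = np.asarray(beta, dtype=float)
            if b.shape != (3,) or (b < 0).any() or abs(b.sum() - 1.0) > 1e-9:
                raise ValueError(f"true_beta {beta} is not on the 3-simplex")

    def _betas(self) -> dict[int, tuple]:
        if isinstance(self.true_beta, Mapping):
            return {g: tuple(self.true_beta[g]) for g in self.n_participants_per_grade}
        return {g: tuple(self.true_beta) for g in self.n_participants_per_grade}


def _participant_rng(seed: int, grade: int, index: int) -> np.random.Generator:
    # deterministic per-participant stream; keyed so that growing the cohort
    # leaves existing participants' draws untouched
    return np.random.default_rng(np.random.SeedSequence([seed, grade, index]))


def simulate_study(
    profile: SimulationProfile,
    design: StudyDesign,
    probs: CorpusProbabilityTable,
) -> pd.DataFrame:
    """Generate a trial-level response table under the mixture-plus-lapse
    mechanism; fully reproducible given ``profile.seed``."""
    probs.validate(design)
    for cond in design.conditions:
        for rule in design.rule_types:
            cats = probs.entries.get(cond, {}).get(rule, {})
            unknown = set(cats) - set(design.response_categories)
            if unknown:
                raise ValueError(
                    f"probability table has categories {sorted(unknown)} "
                    f"not in the design ({cond}, {rule})"
                )

    english = design.language_mode == ENGLISH_STYLE
    error_label = CONSONANT_ERROR if english else ERROR
    lapse_cats = list(design.lapse_categories)
    ipc = dict(profile.items_per_condition or design.items_per_condition)
    betas = profile._betas()

    # per-condition sampling machinery: full category list incl. residual mass
    draw_cats: dict[str, list[str]] = {}
    rule_dists: dict[str, np.ndarray] = {}
    for cond in design.conditions:
        mat = probs.rule_matrix(design, cond)  # (n_cats, 3)
        cats = list(design.response_categories)
        if english:
            residual = 1.0 - mat.sum(axis=0)
            mat = np.vstack([mat, np.clip(residual, 0.0, 1.0)])
            cats = cats + [OTHER_VOWEL]
        draw_cats[cond] = cats
        rule_dists[cond] = mat / mat.sum(axis=0, keepdims=True)

    rows = []
    for grade in sorted(profile.n_participants_per_grade):
        grade_beta = np.asarray(betas[grade], dtype=float)
        for idx in range(profile.n_participants_per_grade[grade]):
            rng = _participant_rng(profile.seed, grade, idx)
            pid = f"g{grade}_p{idx:03d}"
            if profile.dirichlet_concentration is not None:
                alpha = np.maximum(grade_beta * profile.dirichlet_concentration, 1e-6)
                beta = rng.dirichlet(alpha)
            else:
                beta = grade_beta
            for session in range(1, profile.n_sessions + 1):
                for cond in design.conditions:
                    for item in range(ipc[cond]):
                        item_id = f"{cond}_i{item:02d}"
                        if rng.random() < profile.consonant_error_rate:
                            rows.append(
                                (pid, grade, item_id, cond, session,
                                 error_label, False, True)
                            )
                            continue
                        rule = rng.choice(3, p=beta)
                        cat_idx = rng.choice(
                            len(draw_cats[cond]), p=rule_dists[cond][:, rule]
                        )
                        category = draw_cats[cond][cat_idx]
                        if profile.lapse_rate and rng.random() < profile.lapse_rate:
                            category = lapse_cats[rng.integers(len(lapse_cats))]
                        rows.append(
                            (pid, grade, item_id, cond, session, category, True, False)
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "grade", "item_id", "condition", "session",
            "response_category", "consonant_correct", "is_error",
        ],
    )


def preset_designs() -> tuple[
    tuple[StudyDesign, CorpusProbabilityTable],
    tuple[StudyDesign, CorpusProbabilityTable],
]:
    """The bundled (design, probability fixture) pairs: English-style first,
    German-style second."""
    return english_preset(), german_preset()
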