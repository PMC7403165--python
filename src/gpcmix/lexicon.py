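"""Orthographic-cluster statistics from a pronounced wordlist.

For each letter cluster (e.g. the body ``al+C`` or the onset context ``wa``)
three descriptive statistics are computed over the words containing it:

* frequency — how many words contain the cluster;
* consistency — the proportion of occurrences carrying the modal (most
  frequent) pronunciation;
* pronunciation entropy — Shannon entropy (bits) of the pronunciation
  distribution, which unlike consistency reflects more than two variants.

Entropy comes in a type-based variant (each word counts once) and a
token-weighted variant (words weighted by token frequency).  The same
machinery derives corpus conditional-probability tables
P(category | rule type, condition) from a user-supplied wordlist.

The package also bundles a small reference table of critical ``a``-context
clusters (``critical_clusters()``) with printed frequency / consistency /
entropy values and a grouping into clusters shared between two developmental
reading studies versus those unique to the earlier one.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .design import CorpusProbabilityTable, StudyDesign
from .entropy import shannon_entropy

LEXICON_COLUMNS = ("orthography", "cluster", "pronunciation")  # + optional token_frequency


@dataclass
class ClusterStats:
    cluster: str
    frequency: int
    consistency: float
    modal_pronunciation: str
    modal_tie: bool
    entropy_type: float
    entropy_token: float | None = None

    def as_dict(self) -> dict:
        return {
            "cluster": self.cluster,
            "frequency": self.frequency,
            "consistency": self.consistency,
            "modal_pronunciation": self.modal_pronunciation,
            "modal_tie": self.modal_tie,
            "entropy": self.entropy_type,
            "entropy_token": self.entropy_token,
        }


def read_lexicon(path) -> pd.DataFrame:
    """Read a wordlist (CSV/TSV by extension) with columns orthography,
    cluster, pronunciation and optional token_frequency."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in LEXICON_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lexicon missing columns: {missing}")
    if "token_frequency" in df.columns and (df["token_frequency"] < 0).any():
        raise ValueError("token_frequency must be nonnegative")
    return df


def cluster_statistics(lexicon: pd.DataFrame, cluster: str) -> ClusterStats:
    """Frequency, consistency and pronunciation entropy of one cluster.

    Consistency ties are broken lexicographically and flagged in the result.
    Token-weighted entropy is computed only when the lexicon carries token
    frequencies.
    """
    sub = lexicon[lexicon["cluster"] == cluster]
    if sub.empty:
        raise ValueError(f"cluster {cluster!r} not present in lexicon")
    counts = sub["pronunciation"].value_counts()
    top = counts[counts == counts.max()]
    modal = sorted(top.index)[0]
    freq = int(counts.sum())
    stats = ClusterStats(
        cluster=cluster,
        frequency=freq,
        consistency=float(counts.max()) / freq,
        modal_pronunciation=modal,
        modal_tie=len(top) > 1,
        entropy_type=shannon_entropy(counts.to_dict()),
    )
    if "token_frequency" in sub.columns and sub["token_frequency"].notna().all():
        mass = sub.groupby("pronunciation")["token_frequency"].sum()
        if mass.sum() > 0:
            stats.entropy_token = shannon_entropy(mass.to_dict())
    return stats


def all_cluster_statistics(lexicon: pd.DataFrame) -> pd.DataFrame:
    """Cluster statistics for every cluster in the lexicon, as a table."""
    rows = [
        cluster_statistics(lexicon, c).as_dict()
        for c in sorted(lexicon["cluster"].unique())
    ]
    return pd.DataFrame(rows)


def group_averages(
    stats: pd.DataFrame, grouping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Unweighted arithmetic means of frequency, consistency and entropy per
    cluster group.

    ``stats`` needs columns cluster, frequency, consistency, entropy (the
    shape produced by :func:`all_cluster_statistics`, or any table of printed
    values).  ``grouping`` maps cluster to group label; if omitted, a
    ``group`` column in ``stats`` is used.
    """
    work = stats.copy()
    if grouping is not None:
        unassigned = set(work["cluster"]) - set(grouping)
        if unassigned:
            raise ValueError(f"clusters without a group: {sorted(unassigned)}")
        work["group"] = work["cluster"].map(grouping)
    elif "group" not in work.columns:
        raise ValueError("need a grouping mapping or a 'group' column")
    agg = work.groupby("group")[["frequency", "consistency", "entropy"]].mean()
    agg.columns = ["mean_frequency", "mean_consistency", "mean_entropy"]
    agg["n_clusters"] = work.groupby("group").size()
    return agg.reset_index()


def critical_clusters() -> pd.DataFrame:
    """The bundled reference table of critical letter clusters: printed
    frequency, consistency and entropy with study-membership grouping."""
    with resources.files("gpcmix.data").joinpath("critical_clusters.csv").open() as fh:
        return pd.read_csv(fh)


def derive_corpus_probabilities(
    lexicon: pd.DataFrame,
    design: StudyDesign,
    context_definitions: Mapping[tuple[str, str], Callable[[str], bool]],
    token_weighted: bool = False,
) -> CorpusProbabilityTable:
    """Build P(category | rule type, condition) from a wordlist.

    ``context_definitions`` maps every (condition, rule_type) pair to a
    predicate over cluster keys selecting the words that exemplify that
    rule's orthographic context in that condition.  Probabilities are
    relative frequencies (type counts, or token-frequency mass with
    ``token_weighted=True``) of each modeled category among the matching
    words; pronunciations outside the modeled set leave residual mass.
    """
    entries: dict = {}
    for cond in design.conditions:
        entries[cond] = {}
        for rule in design.rule_types:
            try:
                predicate = context_definitions[(cond, rule)]
            except KeyError:
                raise ValueError(
                    f"no context definition for condition {cond!r}, rule {rule!r}"
                ) from None
            sub = lexicon[lexicon["cluster"].map(predicate)]
            if sub.empty:
                raise ValueError(
                    f"context predicate for ({cond!r}, {rule!r}) matches no words"
                )
            if token_weighted:
                if "token_frequency" not in sub.columns:
                    raise ValueError("token_weighted requires a token_frequency column")
                mass = sub.groupby("pronunciation")["token_frequency"].sum()
            else:
                mass = sub["pronunciation"].value_counts()
            total = float(mass.sum())
            entries[cond][rule] = {
                cat: float(mass.get(cat, 0.0)) / total
                for cat in design.response_categories
            }
    table = CorpusProbabilityTable(entries=entries)
    if design.language_mode != "german_style":
        table.validate(design)
    return table
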