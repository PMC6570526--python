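"""Phrase-transition statistics of song syntax.

Canary song is a sequence of *phrases* — runs of repeated syllables of
one type.  Collapsing each bout's typed syllable sequence by run-length
gives a phrase sequence; the ordered pairs of adjacent phrase types
within bouts define a transition probability distribution from which
four syntax summaries are computed:

* percent of possible transitions used: observed distinct ordered pairs
  over k(k-1) for a repertoire of k types (self-transitions are
  impossible after collapsing);
* linearity: number of syllable types / number of transition types;
* consistency: probability mass of "common" transitions (those carrying
  at least 5% of all transitions);
* entropy: S = -sum_i T_i log2 T_i of the transition distribution, in
  bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import UNTYPED

__all__ = [
    "PhraseSequence",
    "TransitionDistribution",
    "collapse_phrases",
    "phrase_sequences",
    "transition_distribution",
    "percent_transitions_used",
    "linearity",
    "consistency",
    "transition_entropy",
    "syntax_summary",
]


@dataclass(frozen=True)
class PhraseSequence:
    """Run-length-collapsed phrase types of one bout."""

    bout_id: str
    phrases: tuple[str, ...]

    def __post_init__(self):
        for a, b in zip(self.phrases, self.phrases[1:]):
            if a == b:
                raise ValueError("adjacent phrases of one type must be merged")


@dataclass(frozen=True)
class TransitionDistribution:
    """Probabilities over ordered phrase-type pairs."""

    probabilities: dict[tuple[str, str], float]
    total_count: int
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        if self.total_count > 0:
            s = sum(self.probabilities.values())
            if abs(s - 1.0) > 1e-12:
                raise ValueError(f"probabilities sum to {s}, not 1")
        if any(a == b for a, b in self.probabilities):
            raise ValueError("self-transitions are impossible after collapsing")

    @property
    def n_transition_types(self) -> int:
        return len(self.probabilities)


def collapse_phrases(types: list[str], bout_id: str = "") -> PhraseSequence:
    """Run-length collapse a bout's ordered syllable types into phrases."""
    if any(t == UNTYPED for t in types):
        raise ValueError(
            "untyped syllables cannot be collapsed into phrases; assign "
            "syllable_type labels (typing config) first"
        )
    phrases = [t for k, t in enumerate(types) if k == 0 or t != types[k - 1]]
    return PhraseSequence(bout_id=bout_id, phrases=tuple(phrases))


def phrase_sequences(records: pd.DataFrame) -> list[PhraseSequence]:
    """Collapse every bout of a syllable record table."""
    rec = records.sort_values(["experiment_day", "bout_id", "bout_position"],
                              kind="stable")
    out = []
    for bout_id, grp in rec.groupby("bout_id", sort=False):
        out.append(collapse_phrases(list(grp["syllable_type"]),
                                    bout_id=str(bout_id)))
    return out


def transition_distribution(
    sequences: list[PhraseSequence],
) -> TransitionDistribution:
    """Normalized counts of within-bout adjacent ordered phrase pairs.

    Bout boundaries contribute no transition.  All-singleton input yields
    an (explicitly flagged) empty distribution.
    """
    counts: dict[tuple[str, str], int] = {}
    for seq in sequences:
        for a, b in zip(seq.phrases, seq.phrases[1:]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    total = sum(counts.values())
    if total == 0:
        return TransitionDistribution(probabilities={}, total_count=0,
                                      counts={})
    probs = {k: v / total for k, v in counts.items()}
    return TransitionDistribution(probabilities=probs, total_count=total,
                                  counts=counts)


def percent_transitions_used(
    dist: TransitionDistribution, repertoire_size: int
) -> float:
    """100 x (distinct observed ordered pairs) / k(k-1)."""
    if repertoire_size < 2:
        raise ValueError("a repertoire of >= 2 types is needed")
    possible = repertoire_size * (repertoire_size - 1)
    return 100.0 * dist.n_transition_types / possible


def linearity(n_types: int, n_transition_types: int) -> float:
    """Number of syllable types divided by number of transition types."""
    if n_transition_types < 1:
        raise ValueError("linearity needs >= 1 transition type")
    return n_types / n_transition_types


def consistency(dist: TransitionDistribution, threshold: float = 0.05) -> float:
    """Mass of common transitions (probability >= ``threshold``)."""
    if dist.total_count == 0:
        raise ValueError("consistency of an empty distribution is undefined")
    return float(sum(p for p in dist.probabilities.values() if p >= threshold))


def transition_entropy(dist: TransitionDistribution) -> float:
    """S = -sum T_i log2 T_i bits, with 0 log 0 = 0."""
    if dist.total_count == 0:
        raise ValueError("entropy of an empty distribution is undefined")
    p = np.array([v for v in dist.probabilities.values() if v > 0])
    return float(-(p * np.log2(p)).sum())


def syntax_summary(
    records: pd.DataFrame,
    repertoire_size: int | None = None,
) -> dict:
    """All four syntax metrics for one bird x period record table."""
    seqs = phrase_sequences(records)
    dist = transition_distribution(seqs)
    types = {p for s in seqs for p in s.phrases}
    k = repertoire_size if repertoire_size is not None else len(types)
    return {
        "n_transitions": dist.total_count,
        "n_transition_types": dist.n_transition_types,
        "pct_used": percent_transitions_used(dist, k) if k >= 2 else float("nan"),
        "linearity": linearity(len(types), dist.n_transition_types)
        if dist.n_transition_types else float("nan"),
        "consistency": consistency(dist) if dist.total_count else float("nan"),
        "entropy_bits": transition_entropy(dist) if dist.total_count
        else float("nan"),
    }
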