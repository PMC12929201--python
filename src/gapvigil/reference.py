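"""Bundled reference constants for the maternal-pediatric literature corpus.

A manually labeled corpus of PubMed abstracts underlies the study-type
classifiers: each abstract is marked relevant/non-relevant to maternal or
pediatric pharmacotherapy, and relevant abstracts carry study-type labels
drawn from {PK, PE, CT} with PE and CT mutually exclusive (PK may co-occur
with either).  The composition below is used as the default study-type
mixture of the synthetic corpus generator.
"""

from __future__ import annotations

#: counts of mutually exclusive label combinations among relevant abstracts
LABELED_CORPUS_COMPOSITION: dict[frozenset, int] = {
    frozenset({"PE"}): 1363,
    frozenset({"CT"}): 512,
    frozenset({"PK"}): 269,
    frozenset({"PK", "PE"}): 588,
    frozenset({"PK", "CT"}): 46,
}

#: abstracts judged not relevant to maternal/pediatric pharmacotherapy
NON_RELEVANT_COUNT: int = 2067

#: observed double-annotation agreement rate before adjudication
DOUBLE_ANNOTATION_AGREEMENT: float = 0.7216

#: per-paper classifier recall used in the miss-probability bound
CLASSIFIER_RECALL: float = 0.93


def relevant_total() -> int:
    """Number of relevant abstracts (sum over label combinations)."""
    return sum(LABELED_CORPUS_COMPOSITION.values())


def corpus_total() -> int:
    """Total labeled-corpus size: relevant plus non-relevant abstracts."""
    return relevant_total() + NON_RELEVANT_COUNT
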