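"""Transcription scoring and listener reliability.

A listener's transcription of an utterance is scored by counting target
words recovered: tokens are lowercased, stripped of punctuation, and matched
as multisets (order-free), so "a big dog" scores 2 of 3 against "the big
dog".  A child's intelligibility at an utterance length is the summed
words-correct over summed target words per listener, averaged across the
(by default two) listeners.

Listener agreement is quantified with the intraclass correlation for the
one-way random-effects, average-measures model: each child is heard by a
different pair of listeners, so the listener is nested in the child and the
only separable variance components are between-child and residual.  From
the one-way ANOVA, ICC = (MSB - MSW) / MSB, with a confidence interval from
the exact F distribution with (n - 1) and n (k - 1) degrees of freedom.
"""

from __future__ import annotations

import string
from collections import Counter
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementResult",
    "normalize_token",
    "score_utterance",
    "child_intelligibility",
    "icc_oneway_average",
]

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def normalize_token(token: str) -> str:
    return token.lower().translate(_PUNCT_TABLE)


def _tokens(words, normalizer: Callable[[str], str]) -> list[str]:
    if isinstance(words, str):
        words = words.split()
    return [t for t in (normalizer(w) for w in words) if t]


def score_utterance(target_words, transcribed_words,
                    normalizer: Callable[[str], str] = normalize_token) -> int:
    """Number of target words credited to a transcription.

    Credit is the multiset intersection of normalized target and
    transcription tokens; never exceeds the target length.  The normalizer
    is pluggable (e.g. to credit homophones); the default lowercases and
    strips punctuation only.
    """
    target = _tokens(target_words, normalizer)
    if not target:
        raise ValueError("target_words must contain at least one word")
    transcribed = _tokens(transcribed_words, normalizer)
    return sum((Counter(target) & Counter(transcribed)).values())


def child_intelligibility(records: pd.DataFrame, n_listeners: int = 2,
                          normalizer: Callable[[str], str] = normalize_token) -> dict[int, float]:
    """Per-length intelligibility proportions for one child's transcripts.

    ``records`` columns: ``listener_id, length, target, transcription``.
    Every utterance must be transcribed by the same set of listeners
    (``n_listeners`` of them); per length the proportion is computed per
    listener as sum(words correct) / sum(target words), then averaged.
    """
    listeners = sorted(records["listener_id"].unique())
    if len(listeners) != n_listeners:
        raise ValueError(f"expected {n_listeners} listeners, found {len(listeners)}: {listeners}")
    if "utterance_id" in records.columns:
        per_utt = records.groupby("utterance_id")["listener_id"].nunique()
        if (per_utt != n_listeners).any():
            raise ValueError("every utterance must be transcribed by the same set of listeners")
    out: dict[int, float] = {}
    for length, grp in records.groupby("length"):
        props = []
        for _, lgrp in grp.groupby("listener_id"):
            correct = sum(score_utterance(t, h, normalizer)
                          for t, h in zip(lgrp["target"], lgrp["transcription"]))
            total = sum(len(_tokens(t, normalizer)) for t in lgrp["target"])
            props.append(correct / total)
        out[int(length)] = float(np.mean(props))
    return out


@dataclass(frozen=True)
class AgreementResult:
    icc_estimate: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int


def icc_oneway_average(score_matrix, level: float = 0.95) -> AgreementResult:
    """One-way random-effects, average-measures, agreement ICC.

    ``score_matrix`` is subjects x raters, complete.  The estimate is
    (MSB - MSW)/MSB from the one-way ANOVA; the CI endpoints are
    1 - 1/F_L and 1 - 1/F_U with F_L, F_U the exact F-interval for MSB/MSW.
    """
    M = np.asarray(score_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("score_matrix must be 2-D with at least 2 subjects and 2 raters")
    if not np.isfinite(M).all():
        raise ValueError("score_matrix must be complete (no missing entries)")
    n, k = M.shape
    subj_means = M.mean(axis=1)
    grand = M.mean()
    ssb = k * np.sum((subj_means - grand) ** 2)
    ssw = np.sum((M - subj_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msb <= 0:
        raise ValueError("no between-subject variance; ICC undefined")
    icc = (msb - msw) / msb
    alpha = 1.0 - level
    if msw == 0.0:
        return AgreementResult(1.0, 1.0, 1.0, n, k)
    F = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    FL = F / stats.f.ppf(1 - alpha / 2, df1, df2)
    FU = F * stats.f.ppf(1 - alpha / 2, df2, df1)
    return AgreementResult(float(icc), float(1 - 1 / FL), float(1 - 1 / FU), n, k)
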