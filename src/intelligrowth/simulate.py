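"""Seeded synthetic cohorts of child speech-intelligibility data.

Emulates the structure of a cross-sectional intelligibility study: each
child (30-119 months) repeats 38 single words and blocks of 10 sentences at
each length from two to seven words, the sentence protocol stopping at the
first length the child cannot complete (the "ceiling").  Two naive adult
listeners transcribe each child; a child's score at a length is the average
of the two listeners' proportions of words heard correctly.

Generative law
--------------
* The median multiword curve is a four-parameter logistic in age on the
  proportion scale (floor 0.25, ceiling 0.99, midpoint 40 months,
  rate 0.09/month).
* Single words carry a -0.35 logit offset from 48 months on, reproducing
  the constant few-point multiword advantage seen in older children.
* Between-child heterogeneity is normal on the logit scale with an
  age-declining standard deviation (logistic from 0.85 to 0.50 logits,
  midpoint 60 months) — the "funnel" of narrowing variability with age.
* The ceiling is governed by per-length logistic completion probabilities
  increasing in age and in the child's latent ability, which induces the
  selection effect: children reaching long utterances young are the more
  intelligible ones.
* Listener transcription noise is binomial over the words at each length
  (38 single words; 10 x L words at sentence length L).

All randomness flows from the config seed; identical configs give
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

__all__ = [
    "TrueGrowthLaw",
    "CeilingLaw",
    "SimulationConfig",
    "simulate_cohort",
    "true_quantile_curve",
    "words_at_length",
]

#: children per 6-month age band from 30-35 to 114-119 months in the study
#: design the generator emulates (younger children deliberately oversampled)
OVERSAMPLE_BAND_COUNTS = (57, 50, 58, 53, 59, 51, 52, 44, 57, 9, 14, 7, 9, 7, 11)
_BAND_STARTS = tuple(range(30, 120, 6))

MULTIWORD_LENGTHS = tuple(range(2, 8))


@dataclass(frozen=True)
class TrueGrowthLaw:
    """Generative median curve and dispersion law.

    ``median(age) = floor + (ceiling - floor) / (1 + exp(-k (age - t0)))``;
    per-length logit offsets apply from ``offset_onset_age`` on (by default a
    single-word deficit of 0.35 logits, other lengths unshifted); the
    between-child SD on the logit scale is ``ability_sd * s(age)`` with
    ``s`` a declining logistic given by ``scale_law = (s_start, s_end,
    s_midpoint, s_rate)``.
    """

    median_floor: float = 0.25
    median_ceiling: float = 0.99
    midpoint_t0: float = 40.0
    rate_k: float = 0.09
    length_offsets: dict = field(default_factory=lambda: {1: -0.35})
    offset_onset_age: float = 48.0
    scale_law: tuple = (0.85, 0.50, 60.0, 0.08)
    ability_sd: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.median_floor < self.median_ceiling <= 1.0:
            raise ValueError("median_floor/median_ceiling must satisfy 0 < floor < ceiling <= 1")
        if self.rate_k <= 0:
            raise ValueError("rate_k must be positive")
        if self.ability_sd < 0:
            raise ValueError("ability_sd must be nonnegative")
        s0, s1, _, _ = self.scale_law
        if not (0.0 < s0 < 1.0 and 0.0 < s1 < 1.0):
            raise ValueError("scale_law start/end values must lie in (0, 1)")

    def median(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        span = self.median_ceiling - self.median_floor
        return self.median_floor + span * expit(self.rate_k * (age - self.midpoint_t0))

    def offset(self, length: int, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        off = self.length_offsets.get(int(length), 0.0)
        return np.where(age >= self.offset_onset_age, off, 0.0)

    def logit_sd(self, age) -> np.ndarray:
        s0, s1, mid, rate = self.scale_law
        age = np.asarray(age, dtype=float)
        return self.ability_sd * (s1 + (s0 - s1) * expit(-rate * (age - mid)))

    def success_prob(self, length: int, age, u) -> np.ndarray:
        """True per-word transcription probability given ability deviate u."""
        return expit(logit(self.median(age)) + self.offset(length, age) + u)


@dataclass(frozen=True)
class CeilingLaw:
    """Per-length completion model for the stop-at-first-failure protocol.

    P(child completes all sentences of length L) =
    ``expit(intercept_L + age_slope (age - ref_age) + ability_slope z)``
    with ``z`` the child's standardized ability.  Nondecreasing in age and
    ability by the sign constraints on the slopes.
    """

    intercepts: dict = field(
        default_factory=lambda: {2: 3.3, 3: 2.2, 4: 1.1, 5: 0.0, 6: -1.3, 7: -2.6}
    )
    age_slope: float = 0.13
    ability_slope: float = 1.0
    ref_age: float = 36.0

    def __post_init__(self):
        if self.age_slope < 0 or self.ability_slope < 0:
            raise ValueError("age_slope and ability_slope must be nonnegative (completion nondecreasing)")
        if set(self.intercepts) != set(MULTIWORD_LENGTHS):
            raise ValueError("intercepts must cover lengths 2..7")

    @classmethod
    def none(cls) -> "CeilingLaw":
        """A degenerate law under which every child completes every length."""
        return cls(intercepts={L: 50.0 for L in MULTIWORD_LENGTHS}, age_slope=0.0, ability_slope=0.0)

    def completion_prob(self, length: int, age, z) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return expit(self.intercepts[int(length)] + self.age_slope * (age - self.ref_age)
                     + self.ability_slope * np.asarray(z, dtype=float))


@dataclass(frozen=True)
class SimulationConfig:
    n_children: int = 538
    age_low: int = 30
    age_high: int = 119
    age_sampling: str = "oversample_young"
    seed: int = 0
    listeners_per_child: int = 2
    words_single: int = 38
    sentences_per_length: int = 10
    lengths: tuple = MULTIWORD_LENGTHS
    true_growth: TrueGrowthLaw = field(default_factory=TrueGrowthLaw)
    ceiling: CeilingLaw = field(default_factory=CeilingLaw)

    def __post_init__(self):
        for name in ("n_children", "listeners_per_child", "words_single", "sentences_per_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a strictly positive count")
        if self.age_low < 30:
            raise ValueError("age_low must be >= 30 months")
        if self.age_high > 119:
            raise ValueError("age_high must be <= 119 months")
        if not self.age_low < self.age_high:
            raise ValueError("age_low must be strictly below age_high")
        if self.age_sampling not in ("uniform", "oversample_young"):
            raise ValueError(f"age_sampling must be 'uniform' or 'oversample_young', got {self.age_sampling!r}")
        if tuple(self.lengths) != MULTIWORD_LENGTHS:
            raise ValueError("lengths must be the contiguous range 2..7")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lengths"] = list(self.lengths)
        d["true_growth"]["scale_law"] = list(self.true_growth.scale_law)
        return d


def words_at_length(config: SimulationConfig, length: int) -> int:
    """Words a listener scores at a given utterance length (38, 20, 30, ... 70)."""
    if length == 1:
        return config.words_single
    return config.sentences_per_length * length


def _draw_ages(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.age_sampling == "uniform":
        return rng.integers(config.age_low, config.age_high + 1, size=config.n_children)
    # band probabilities proportional to the study design counts, restricted
    # to bands overlapping the configured age range
    starts, weights = [], []
    for s, w in zip(_BAND_STARTS, OVERSAMPLE_BAND_COUNTS):
        lo, hi = max(s, config.age_low), min(s + 5, config.age_high)
        if lo <= hi:
            starts.append((lo, hi))
            weights.append(w)
    p = np.asarray(weights, dtype=float)
    p /= p.sum()
    bands = rng.choice(len(starts), size=config.n_children, p=p)
    lows = np.asarray([starts[b][0] for b in bands])
    highs = np.asarray([starts[b][1] for b in bands])
    return lows + rng.integers(0, highs - lows + 1)


def simulate_cohort(config: SimulationConfig, return_listener_level: bool = False):
    """Generate one synthetic cohort.

    Returns a child-level DataFrame (one row per child with columns
    ``child_id, age_months, sex, longest_length, score_len1..score_len7``;
    scores are NaN above the child's ceiling).  With
    ``return_listener_level=True`` also returns the long listener-level
    table (one row per child x length x listener with word counts).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_children
    ages = _draw_ages(config, rng).astype(int)
    sex = np.where(rng.random(n) < 282.0 / 538.0, "F", "M")
    z = rng.standard_normal(n)
    u = config.true_growth.logit_sd(ages) * z

    # sequential ceiling: longest completed length, stopping at first failure
    longest = np.ones(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    for L in MULTIWORD_LENGTHS:
        pc = config.ceiling.completion_prob(L, ages, z)
        success = rng.random(n) < pc
        alive &= success
        longest[alive] = L

    child_scores = {L: np.full(n, np.nan) for L in range(1, 8)}
    listener_rows = []
    for L in range(1, 8):
        produced = longest >= L if L > 1 else np.ones(n, dtype=bool)
        if not produced.any():
            continue
        idx = np.flatnonzero(produced)
        m = words_at_length(config, L)
        p = config.true_growth.success_prob(L, ages[idx], u[idx])
        per_listener = np.empty((len(idx), config.listeners_per_child))
        for j in range(config.listeners_per_child):
            counts = rng.binomial(m, p)
            per_listener[:, j] = counts / m
            if return_listener_level:
                listener_rows.append(pd.DataFrame({
                    "child_id": idx,
                    "listener": j + 1,
                    "length": L,
                    "words": m,
                    "words_correct": counts,
                    "score": counts / m,
                }))
        child_scores[L][idx] = per_listener.mean(axis=1)

    children = pd.DataFrame({
        "child_id": np.arange(n),
        "age_months": ages,
        "sex": sex,
        "longest_length": longest,
        **{f"score_len{L}": child_scores[L] for L in range(1, 8)},
    })
    if return_listener_level:
        listeners = pd.concat(listener_rows, ignore_index=True)
        listeners = listeners.sort_values(["child_id", "length", "listener"], kind="stable").reset_index(drop=True)
        return children, listeners
    return children


def _outcome_lengths(outcome) -> tuple:
    if outcome == "single_word":
        return (1,)
    if outcome == "multiword":
        return MULTIWORD_LENGTHS
    if isinstance(outcome, int) and 1 <= outcome <= 7:
        return (int(outcome),)
    raise ValueError(f"outcome must be 'single_word', 'multiword', or a length 1..7, got {outcome!r}")


def true_quantile_curve(config: SimulationConfig, percentile: float, ages,
                        outcome="multiword", gh_points: int = 61) -> np.ndarray:
    """Exact quantile of the generative score distribution at each age.

    The score given ability is the equal-weight mean over the outcome's
    lengths of averaged-binomial proportions, treated as normal with the
    matching mean and variance; the ability mixture is integrated by
    Gauss-Hermite quadrature and the quantile recovered by root finding.
    Serves as the ground-truth oracle for parameter-recovery tests (for the
    multiword outcome it describes the no-ceiling, equal-weight composite).
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie strictly in (0, 1)")
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    lengths = _outcome_lengths(outcome)
    law = config.true_growth
    nodes, wts = np.polynomial.hermite.hermgauss(gh_points)
    wts = wts / np.sqrt(np.pi)
    k = config.listeners_per_child
    out = np.empty(len(ages))
    for i, t in enumerate(ages):
        sd_u = float(law.logit_sd(t))
        u = np.sqrt(2.0) * sd_u * nodes
        probs = np.stack([law.success_prob(L, t, u) for L in lengths])   # (nL, gh)
        mean_u = probs.mean(axis=0)
        var_u = sum(probs[j] * (1.0 - probs[j]) / (k * words_at_length(config, L))
                    for j, L in enumerate(lengths)) / len(lengths) ** 2
        sd_score = np.sqrt(np.maximum(var_u, 1e-16))

        def cdf(yv: float) -> float:
            from scipy.stats import norm
            return float(np.sum(wts * norm.cdf((yv - mean_u) / sd_score)))

        out[i] = optimize.brentq(lambda yv: cdf(yv) - percentile, -0.5, 1.5, xtol=1e-10)
    return np.clip(out, 0.0, 1.0)
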