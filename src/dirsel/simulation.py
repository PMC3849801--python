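"""Worked-example fixture and synthetic replacement generators.

:func:`sage1_fixture` returns the 15 replacements of the Pan/Homo SAGE1
pairwise comparison used as the reference worked example throughout the test
suite.  The null generator draws ordered residue pairs uniformly over the
380 distinct ordered pairs of standard amino acids — the simplest null
consistent with "no net property change" — and the biased generator tilts
acceptance toward positive deltas under a chosen scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .property_table import AA_ORDER, TO_MINUS_FROM, PropertyScale, delta
from .replacement_io import Replacement, ReplacementList

__all__ = [
    "ORDERED_PAIRS",
    "NullModel",
    "BiasedModel",
    "sage1_fixture",
    "sample_null",
    "sample_biased",
    "pair_deltas",
    "calibrate",
]

#: The 380 ordered pairs of distinct standard amino acids.
ORDERED_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a, b in itertools.product(AA_ORDER, repeat=2) if a != b
)

# Pan/Homo SAGE1: 15 amino-acid differences, sites 82..805 in an
# 805-residue frame.
_SAGE1_ROWS = (
    (82, "C", "R"),
    (92, "V", "A"),
    (160, "R", "H"),
    (450, "Q", "R"),
    (507, "D", "V"),
    (523, "S", "T"),
    (563, "V", "A"),
    (582, "V", "D"),
    (605, "F", "L"),
    (672, "A", "T"),
    (675, "S", "N"),
    (694, "T", "A"),
    (754, "C", "R"),
    (802, "V", "A"),
    (805, "L", "S"),
)

SAGE1_LENGTH = 805


def sage1_fixture() -> ReplacementList:
    """The Pan vs Homo SAGE1 replacement list (15 sites, 82..805)."""
    reps = tuple(Replacement(site, a, b) for site, a, b in _SAGE1_ROWS)
    return ReplacementList(reps, SAGE1_LENGTH, labels=("Pan_SAGE1", "Homo_SAGE1"))


@dataclass(frozen=True)
class NullModel:
    """Uniform-replacement null: n replacements at distinct random sites.

    Residue pairs are drawn uniformly over :data:`ORDERED_PAIRS`; by
    antisymmetry of deltas the exact enumeration mean of any scale's delta
    under this law is zero.
    """

    n: int
    sequence_length: int = SAGE1_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.n > self.sequence_length:
            raise ValueError(
                f"cannot place {self.n} replacements at distinct sites in a "
                f"sequence of length {self.sequence_length}"
            )


@dataclass(frozen=True)
class BiasedModel(NullModel):
    """Null model plus an acceptance weight increasing in the delta.

    A proposed pair with delta ``x`` (under the sampling scale) is accepted
    with probability ``sigmoid(bias * x / scale_spread)``; ``bias = 0``
    reduces exactly to the null.
    """

    bias: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.bias < 0:
            raise ValueError("bias must be >= 0")


def pair_deltas(scale: PropertyScale, convention: str = TO_MINUS_FROM) -> np.ndarray:
    """Deltas of all 380 ordered pairs under a scale, in ORDERED_PAIRS order."""
    return np.array(
        [delta(scale, a, b, convention) for a, b in ORDERED_PAIRS], dtype=float
    )


def _build(model: NullModel, pair_idx: np.ndarray, rng: np.random.Generator) -> ReplacementList:
    sites = np.sort(
        rng.choice(model.sequence_length, size=model.n, replace=False) + 1
    )
    reps = tuple(
        Replacement(int(s), *ORDERED_PAIRS[int(i)]) for s, i in zip(sites, pair_idx)
    )
    return ReplacementList(reps, model.sequence_length, labels=("null_a", "null_b"))


def sample_null(model: NullModel, rng: np.random.Generator | None = None) -> ReplacementList:
    """One draw from the null model; reproducible from (model fields, seed)."""
    rng = rng if rng is not None else np.random.default_rng(model.seed)
    idx = rng.integers(0, len(ORDERED_PAIRS), size=model.n)
    return _build(model, idx, rng)


def sample_biased(
    model: BiasedModel,
    scale: PropertyScale,
    convention: str = TO_MINUS_FROM,
    rng: np.random.Generator | None = None,
) -> ReplacementList:
    """One draw from the biased model via acceptance-rejection sampling."""
    rng = rng if rng is not None else np.random.default_rng(model.seed)
    deltas = pair_deltas(scale, convention)
    spread = float(np.std(deltas)) or 1.0
    accepted: list[int] = []
    while len(accepted) < model.n:
        k = max(4 * (model.n - len(accepted)), 16)
        proposals = rng.integers(0, len(ORDERED_PAIRS), size=k)
        u = rng.random(k)
        w = expit(model.bias * deltas[proposals] / spread)
        accepted.extend(int(i) for i in proposals[u < w])
    idx = np.array(accepted[: model.n])
    return _build(model, idx, rng)


def calibrate(
    scale: PropertyScale,
    n: int = 15,
    trials: int = 1000,
    seed: int = 0,
    biases: tuple[float, ...] = (0.0,),
    tiers: tuple[float, ...] = (0.1, 0.05, 0.01),
    sequence_length: int = SAGE1_LENGTH,
    convention: str = TO_MINUS_FROM,
) -> dict:
    """Monte-Carlo rejection rates of the directional test per bias level.

    Runs ``trials`` draws per bias level through the package's own test path
    and tallies two-tailed rejections at each tier.  Deterministic for fixed
    (arguments, seed).
    """
    from .directional_test import deltas_for, t_test

    out: dict = {"n": n, "trials": trials, "seed": seed, "scale": scale.symbol, "levels": []}
    for bias in biases:
        rng = np.random.default_rng(seed)
        model = BiasedModel(n=n, sequence_length=sequence_length, seed=seed, bias=bias)
        rejections = {tier: 0 for tier in tiers}
        mean_sum = 0.0
        for _ in range(trials):
            reps = (
                sample_null(model, rng=rng)
                if bias == 0.0
                else sample_biased(model, scale, convention, rng=rng)
            )
            res = t_test(deltas_for(reps, scale, convention))
            mean_sum += res.mean
            for tier in tiers:
                if res.p_two_tailed < tier:
                    rejections[tier] += 1
        out["levels"].append(
            {
                "bias": bias,
                "mean_delta": mean_sum / trials,
                "rejection_rate": {str(t): c / trials for t, c in rejections.items()},
            }
        )
    return out
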