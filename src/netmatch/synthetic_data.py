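"""Synthetic stimulus networks and simulated cohorts.

Generates everything the analysis pipeline consumes — a 25-node scale-free
stimulus graph, two-choice records from participants whose sensitivity L is
drawn from a truncated Gaussian, and five-trait personality scores with a
tunable extraversion–L correlation — so every stage is testable without the
original behavioural dataset.  Ground-truth L values are written to a
separate file that pipeline-facing readers treat as optional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cohort_stats import TRAITS, PersonalityRecord
from .inference import ChoiceRecord
from .netgrow import (
    AttachmentPolicy,
    Graph,
    GrowthConfig,
    grow_network,
    read_edgelist,
    write_edgelist,
    write_graphml,
)

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "make_stimulus",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 600
    L_mean: float = 0.68
    L_sd: float = 3.1
    L_truncation: tuple[float, float] = (-10.0, 10.0)
    extraversion_target_r: float = 0.17
    trait_scale: tuple[float, float] = (1.0, 5.0)
    round_to_half_points: bool = False
    stimulus_seed: int = 0
    cohort_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        if not abs(self.extraversion_target_r) < 1:
            raise ValueError("|extraversion_target_r| must be below 1")
        if self.L_sd < 0:
            raise ValueError("L_sd must be non-negative")
        lo, hi = self.L_truncation
        if not lo < hi:
            raise ValueError("L_truncation bounds must be ordered")


@dataclass
class SyntheticCohort:
    stimulus: Graph
    records: list[ChoiceRecord]
    personality: list[PersonalityRecord]
    true_L: np.ndarray


def make_stimulus(seed: int = 0) -> Graph:
    """The 25-node scale-free stimulus: growth with fixed L = 1 and m = 3."""
    config = GrowthConfig(m=3, n_final=25, policy=AttachmentPolicy.fixed(1.0), seed=seed)
    return grow_network(config)


def _trait_scores(latent: np.ndarray, scale: tuple[float, float],
                  round_half: bool) -> np.ndarray:
    """Map standard-normal-ish latents onto the instrument's response scale."""
    lo, hi = scale
    mid = 0.5 * (lo + hi)
    spread = 0.1875 * (hi - lo)  # ~0.75 on the default 1-5 scale
    scores = np.clip(mid + spread * latent, lo, hi)
    if round_half:
        scores = np.round(scores * 2) / 2
    return scores


def generate_cohort(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> SyntheticCohort:
    """Simulate a cohort of two-choice participants on a fresh stimulus.

    Each participant's true L is drawn from Normal(L_mean, L_sd) truncated to
    the configured bounds; the first choice is a degree-softmax draw over all
    stimulus nodes and the second over the remaining nodes.  Extraversion is
    constructed from standardised true L plus independent noise so that its
    population correlation with true L is ``extraversion_target_r``; the
    other four traits are independent of L.
    """
    if rng is None:
        rng = np.random.default_rng(config.cohort_seed)
    stimulus = make_stimulus(config.stimulus_seed)
    n = config.n_participants
    lo, hi = config.L_truncation

    if config.L_sd == 0:
        true_L = np.full(n, float(config.L_mean))
    else:
        a = (lo - config.L_mean) / config.L_sd
        b = (hi - config.L_mean) / config.L_sd
        true_L = truncnorm.ppf(
            rng.uniform(size=n), a, b, loc=config.L_mean, scale=config.L_sd
        )

    # vectorised two-stage categorical sampling from the degree softmax
    logd = np.log(stimulus.degrees().astype(float))
    W = true_L[:, None] * logd[None, :]
    W -= W.max(axis=1, keepdims=True)
    P = np.exp(W)
    P /= P.sum(axis=1, keepdims=True)
    first = (P.cumsum(axis=1) < rng.uniform(size=(n, 1))).sum(axis=1)
    P2 = P.copy()
    P2[np.arange(n), first] = 0.0
    P2 /= P2.sum(axis=1, keepdims=True)
    second = (P2.cumsum(axis=1) < rng.uniform(size=(n, 1))).sum(axis=1)

    records = [
        ChoiceRecord(f"p{i:04d}", int(first[i]), int(second[i])) for i in range(n)
    ]

    r = config.extraversion_target_r
    if true_L.std() > 0:
        z = (true_L - true_L.mean()) / true_L.std()
    else:
        z = np.zeros(n)
    extraversion_latent = r * z + np.sqrt(1 - r**2) * rng.normal(size=n)
    latents = {
        "extraversion": extraversion_latent,
        **{t: rng.normal(size=n) for t in TRAITS if t != "extraversion"},
    }
    scores = {
        t: _trait_scores(latents[t], config.trait_scale, config.round_to_half_points)
        for t in TRAITS
    }
    personality = [
        PersonalityRecord(f"p{i:04d}", *(float(scores[t][i]) for t in TRAITS))
        for i in range(n)
    ]
    return SyntheticCohort(stimulus, records, personality, true_L)


# ---------------------------------------------------------------------------
# On-disk layout: stimulus.edgelist/.graphml, choices.csv, personality.csv,
# truth.csv (ground truth, optional on read), manifest.json.


def write_cohort(cohort: SyntheticCohort, directory,
                 config: CohortConfig | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_edgelist(cohort.stimulus, directory / "stimulus.edgelist")
    write_graphml(cohort.stimulus, directory / "stimulus.graphml")
    pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in cohort.records],
            "first_choice": [r.first_choice for r in cohort.records],
            "second_choice": [r.second_choice for r in cohort.records],
        }
    ).to_csv(directory / "choices.csv", index=False)
    pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in cohort.personality],
            **{t: [p.trait(t) for p in cohort.personality] for t in TRAITS},
        }
    ).to_csv(directory / "personality.csv", index=False)
    if len(cohort.true_L):
        pd.DataFrame(
            {
                "participant_id": [r.participant_id for r in cohort.records],
                "true_L": cohort.true_L,
            }
        ).to_csv(directory / "truth.csv", index=False)
    manifest = {"format": "netmatch-cohort-v1"}
    if config is not None:
        manifest["config"] = asdict(config)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_cohort(directory) -> SyntheticCohort:
    """Load a cohort directory; the ground-truth file is optional."""
    directory = Path(directory)
    stim_path = directory / "stimulus.edgelist"
    if not stim_path.exists():
        raise FileNotFoundError(f"missing stimulus file: {stim_path}")
    stimulus = read_edgelist(stim_path)

    choices_path = directory / "choices.csv"
    if not choices_path.exists():
        raise FileNotFoundError(f"missing choices file: {choices_path}")
    cdf = pd.read_csv(choices_path, dtype={"participant_id": str})
    records = [
        ChoiceRecord(row.participant_id, int(row.first_choice), int(row.second_choice))
        for row in cdf.itertuples()
    ]

    pers_path = directory / "personality.csv"
    if not pers_path.exists():
        raise FileNotFoundError(f"missing personality file: {pers_path}")
    pdf = pd.read_csv(pers_path, dtype={"participant_id": str})
    personality = [
        PersonalityRecord(row.participant_id, *(getattr(row, t) for t in TRAITS))
        for row in pdf.itertuples()
    ]

    truth_path = directory / "truth.csv"
    if truth_path.exists():
        true_L = pd.read_csv(truth_path)["true_L"].to_numpy()
    else:
        true_L = np.array([])
    return SyntheticCohort(stimulus, records, personality, true_L)
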