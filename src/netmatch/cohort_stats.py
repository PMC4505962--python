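"""Cohort-level correlational statistics with percentile-bootstrap intervals."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PersonalityRecord",
    "CorrelationResult",
    "TRAITS",
    "pearson_r",
    "bootstrap_ci",
    "correlation_with_ci",
    "first_second_consistency",
    "trait_correlations",
]

TRAITS = ("openness", "conscientiousness", "extraversion", "agreeableness", "neuroticism")


@dataclass(frozen=True)
class PersonalityRecord:
    participant_id: str
    openness: float
    conscientiousness: float
    extraversion: float
    agreeableness: float
    neuroticism: float

    def __post_init__(self) -> None:
        for t in TRAITS:
            v = getattr(self, t)
            if not np.isfinite(v):
                raise ValueError(f"{t} score must be finite")

    def trait(self, name: str) -> float:
        if name not in TRAITS:
            raise KeyError(f"unknown trait {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n_boot: int
    n: int


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in input")
    # guard against |r| exceeding 1 by a rounding ulp
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def _bootstrap_pearson(
    x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator,
    max_retries: int = 100, chunk: int = 20000,
) -> np.ndarray:
    """Vectorised bootstrap of Pearson's r; zero-variance resamples redrawn."""
    n = x.size
    out = np.empty(n_boot)
    done = 0
    while done < n_boot:
        k = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(k, n))
        xs = x[idx]
        ys = y[idx]
        xs = xs - xs.mean(axis=1, keepdims=True)
        ys = ys - ys.mean(axis=1, keepdims=True)
        sx = np.sqrt((xs**2).sum(axis=1))
        sy = np.sqrt((ys**2).sum(axis=1))
        bad = (sx == 0) | (sy == 0)
        retries = 0
        while bad.any():
            retries += 1
            if retries > max_retries:
                raise RuntimeError("statistic undefined on resamples after retries")
            idx_bad = rng.integers(0, n, size=(int(bad.sum()), n))
            xb = x[idx_bad] - x[idx_bad].mean(axis=1, keepdims=True)
            yb = y[idx_bad] - y[idx_bad].mean(axis=1, keepdims=True)
            xs[bad] = xb
            ys[bad] = yb
            sx[bad] = np.sqrt((xb**2).sum(axis=1))
            sy[bad] = np.sqrt((yb**2).sum(axis=1))
            bad = (sx == 0) | (sy == 0)
        out[done : done + k] = np.clip((xs * ys).sum(axis=1) / (sx * sy), -1.0, 1.0)
        done += k
    return out


def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    data: tuple[Sequence[float], Sequence[float]],
    n_boot: int = 1_000_000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
    max_retries: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a paired-row statistic.

    Rows are resampled with replacement; resamples on which the statistic is
    undefined (zero variance) are redrawn, with a capped retry count.  A fast
    vectorised path is used when ``statistic is pearson_r``.
    """
    x = np.asarray(data[0], dtype=float)
    y = np.asarray(data[1], dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("paired data of length >= 3 required")
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    if rng is None:
        rng = np.random.default_rng()

    if statistic is pearson_r:
        stats = _bootstrap_pearson(x, y, n_boot, rng, max_retries)
    else:
        stats = np.empty(n_boot)
        n = x.size
        for i in range(n_boot):
            for attempt in range(max_retries + 1):
                idx = rng.integers(0, n, size=n)
                try:
                    stats[i] = statistic(x[idx], y[idx])
                    break
                except ValueError:
                    if attempt == max_retries:
                        raise RuntimeError(
                            "statistic undefined on resamples after retries"
                        )
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(stats, alpha)),
        float(np.quantile(stats, 1.0 - alpha)),
    )


def correlation_with_ci(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1_000_000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = pearson_r(x, y)
    lo, hi = bootstrap_ci(pearson_r, (x, y), n_boot=n_boot, level=level, rng=rng)
    return CorrelationResult(r=r, ci_low=lo, ci_high=hi, n_boot=n_boot, n=x.size)


def first_second_consistency(
    fits: Sequence[tuple[float, float]],
    n_boot: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> CorrelationResult:
    """Correlation between first-choice and second-choice L estimates."""
    first = [f for f, _ in fits]
    second = [s for _, s in fits]
    return correlation_with_ci(first, second, n_boot=n_boot, rng=rng)


def trait_correlations(
    L_map: Sequence[float],
    personality: Sequence[PersonalityRecord],
    n_boot: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> dict[str, CorrelationResult]:
    """Correlation of best-fit L with each of the five personality traits.

    Raw intervals per trait; no multiple-comparison adjustment.
    """
    L = np.asarray(L_map, dtype=float)
    if L.size != len(personality):
        raise ValueError("one L value per personality record required")
    out = {}
    for t in TRAITS:
        scores = np.array([p.trait(t) for p in personality])
        out[t] = correlation_with_ci(L, scores, n_boot=n_boot, rng=rng)
    return out
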