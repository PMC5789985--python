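"""Method-of-moments mixture estimator of the truly-damaging mutation fraction.

Model
-----
For mutations of one class within essential genes, the per-mutation HOM
proportions ``p_i`` (HOM G3 mice / all G3 mice from HET-dam litters) are
assumed to come from a three-subgroup mixture:

* a fraction ``rho`` of mutations are truly damaging in *totally* essential
  genes — no homozygote survives, so ``p_i = 0``;
* a fraction ``partial_ratio * rho`` (0.39·rho by default) are truly damaging
  in *partially* essential genes — surviving HOM proportions scatter around
  ``theta`` (default 0.125);
* the remainder do not damage the protein — ``p_i`` scatters around the
  Mendelian 0.25.

Equating the sample mean of ``p_i`` with its expectation under the mixture
and solving for the total damaging fraction ``(1 + partial_ratio) * rho``
gives the method-of-moments estimator

    rho_MM = (1 + r) * (1/4 - mean(p)) / (1/4 * (1 + r) - theta * r)

which at the defaults (r = 0.39, theta = 0.125) reduces to
``1.39 * (0.25 - mean(p)) / 0.29875``.  The raw estimate can leave [0, 1]
through sampling noise; a clamped copy is what downstream modules consume.
Confidence intervals are percentile bootstrap over mutations (the mutation,
with its ``p_i``, is the resampling unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .constants import (
    DEFAULT_PARTIAL_RATIO,
    DEFAULT_THETA,
    MENDELIAN_HOM_RATE,
    MISSENSE_CLASSES,
    MUTATION_CLASSES,
)
from .filtering import FilteredMutation


@dataclass(frozen=True)
class MixtureModelParams:
    """Structural parameters of the three-subgroup mixture.

    theta : center of the partial-lethality subgroup, in (0, 0.25).
    partial_ratio : ratio of partially to totally essential damaging
        mutations (default 0.39, i.e. 39:100).
    mendelian_rate : expected HOM proportion without lethality; fixed 0.25.
    """

    theta: float = DEFAULT_THETA
    partial_ratio: float = DEFAULT_PARTIAL_RATIO
    mendelian_rate: float = MENDELIAN_HOM_RATE

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < self.mendelian_rate):
            raise ValueError(
                f"theta must lie in (0, {self.mendelian_rate}); got {self.theta}"
            )
        if self.partial_ratio < 0:
            raise ValueError(f"partial_ratio must be >= 0; got {self.partial_ratio}")

    @property
    def denominator(self) -> float:
        """The estimator denominator 1/4·(1+r) − theta·r (0.29875 at defaults)."""
        return (
            self.mendelian_rate * (1.0 + self.partial_ratio)
            - self.theta * self.partial_ratio
        )


def mm_estimate(
    p_list: Sequence[float] | np.ndarray,
    params: MixtureModelParams | None = None,
) -> tuple[float, float]:
    """Method-of-moments estimate of the truly-damaging fraction.

    Returns ``(rho_raw, rho)`` where ``rho`` is ``rho_raw`` clipped to
    [0, 1].  ``p_list`` must be non-empty HOM proportions in [0, 1].
    """
    params = params or MixtureModelParams()
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("p_list must be non-empty")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("HOM proportions must lie in [0, 1]")
    rho_raw = float(
        (1.0 + params.partial_ratio)
        * (params.mendelian_rate - p.mean())
        / params.denominator
    )
    return rho_raw, float(np.clip(rho_raw, 0.0, 1.0))


def bootstrap_ci(
    p_list: Sequence[float] | np.ndarray,
    params: MixtureModelParams | None = None,
    reps: int = 5000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the clamped estimate.

    Mutations are resampled with replacement ``reps`` times; the clamped
    estimate is recomputed per replicate and the ``level`` central interval
    of the replicate distribution returned.
    """
    params = params or MixtureModelParams()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("p_list must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, p.size, size=(reps, p.size))
    means = p[idx].mean(axis=1)
    rhos = np.clip(
        (1.0 + params.partial_ratio)
        * (params.mendelian_rate - means)
        / params.denominator,
        0.0,
        1.0,
    )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(rhos, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class DamageClassEstimate:
    """Point estimate and bootstrap CI of the damaging fraction for one
    mutation class or score window."""

    label: str
    n: int
    rho_raw: float
    rho: float
    ci_low: float
    ci_high: float
    bootstrap_reps: int


class DamageEstimateResults:
    """Results container for fitted damage-fraction estimates.

    Behaves like a small results object: ``estimates`` holds one
    :class:`DamageClassEstimate` per class/window, ``frame`` a tidy
    DataFrame, and ``summary()`` a printable table.
    """

    def __init__(
        self, estimates: Sequence[DamageClassEstimate], params: MixtureModelParams
    ):
        self.estimates = list(estimates)
        self.params = params

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": e.label,
                    "n": e.n,
                    "rho_raw": e.rho_raw,
                    "rho": e.rho,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "bootstrap_reps": e.bootstrap_reps,
                }
                for e in self.estimates
            ]
        )

    def __getitem__(self, label: str) -> DamageClassEstimate:
        for e in self.estimates:
            if e.label == label:
                return e
        raise KeyError(label)

    def __iter__(self):
        return iter(self.estimates)

    def rho_map(self) -> dict[str, float]:
        return {e.label: e.rho for e in self.estimates}

    def summary(self) -> SimpleTable:
        rows = [
            [
                e.label,
                f"{e.n:d}",
                f"{e.rho_raw:.4f}",
                f"{e.rho:.4f}",
                f"[{e.ci_low:.3f}, {e.ci_high:.3f}]",
            ]
            for e in self.estimates
        ]
        return SimpleTable(
            rows,
            headers=["class/window", "n", "rho_raw", "rho", "95% CI"],
            title=(
                f"Damaging-fraction estimates "
                f"(theta={self.params.theta:g}, r={self.params.partial_ratio:g})"
            ),
        )


class HomFractionMixtureModel:
    """Three-subgroup mixture model of per-mutation HOM proportions.

    Parameters
    ----------
    p_values : HOM proportions, one per mutation, in [0, 1].
    params : structural mixture parameters (theta, partial ratio).
    label : optional name attached to the fitted estimate.
    """

    def __init__(
        self,
        p_values: Sequence[float] | np.ndarray,
        params: MixtureModelParams | None = None,
        label: str = "all",
    ):
        self.p_values = np.asarray(p_values, dtype=float)
        if self.p_values.size == 0:
            raise ValueError("p_values must be non-empty")
        self.params = params or MixtureModelParams()
        self.label = label

    def fit(
        self,
        bootstrap_reps: int = 5000,
        level: float = 0.95,
        seed: int | np.random.Generator | None = None,
    ) -> DamageEstimateResults:
        rho_raw, rho = mm_estimate(self.p_values, self.params)
        lo, hi = bootstrap_ci(
            self.p_values, self.params, reps=bootstrap_reps, level=level, seed=seed
        )
        est = DamageClassEstimate(
            label=self.label,
            n=int(self.p_values.size),
            rho_raw=rho_raw,
            rho=rho,
            ci_low=lo,
            ci_high=hi,
            bootstrap_reps=bootstrap_reps,
        )
        return DamageEstimateResults([est], self.params)


def _defined_p(filtered: Iterable[FilteredMutation]) -> list[FilteredMutation]:
    return [fm for fm in filtered if fm.defined]


def estimate_by_class(
    filtered: Iterable[FilteredMutation],
    params: MixtureModelParams | None = None,
    reps: int = 5000,
    seed: int | None = None,
    level: float = 0.95,
) -> DamageEstimateResults:
    """One damaging-fraction estimate per mutation class present in the input.

    Classes with no mutations are omitted (logged by the caller's filter
    stage); seeds for the per-class bootstraps are spawned from ``seed`` so
    class estimates are independent yet reproducible.
    """
    params = params or MixtureModelParams()
    usable = _defined_p(filtered)
    by_class: dict[str, list[float]] = {}
    for fm in usable:
        by_class.setdefault(fm.mutation_class, []).append(fm.p_hom)
    streams = np.random.SeedSequence(seed).spawn(len(MUTATION_CLASSES))
    estimates = []
    for cls, stream in zip(MUTATION_CLASSES, streams):
        if cls not in by_class:
            continue
        rng = np.random.default_rng(stream)
        model = HomFractionMixtureModel(by_class[cls], params, label=cls)
        estimates.append(model.fit(bootstrap_reps=reps, level=level, seed=rng).estimates[0])
    return DamageEstimateResults(estimates, params)


def estimate_by_score_window(
    filtered: Iterable[FilteredMutation],
    windows: Sequence[tuple[float, float]],
    params: MixtureModelParams | None = None,
    reps: int = 5000,
    seed: int | None = None,
    level: float = 0.95,
) -> DamageEstimateResults:
    """Damaging-fraction estimates for score windows (low, high].

    Only missense mutations carry scores and are binned; windows must be
    disjoint and ordered.  A score exactly on a shared boundary belongs to
    the lower window (whose half-open upper end contains it).  A score of
    exactly 0 falls in the first window if that window starts at 0.
    """
    params = params or MixtureModelParams()
    for (lo1, hi1), (lo2, hi2) in zip(windows, windows[1:]):
        if hi1 > lo2:
            raise ValueError(
                f"windows must be disjoint and ordered: ({lo1},{hi1}] overlaps ({lo2},{hi2}]"
            )
    usable = [
        fm
        for fm in _defined_p(filtered)
        if fm.mutation_class in MISSENSE_CLASSES and fm.record.score is not None
    ]
    bins: dict[int, list[float]] = {}
    first_low = windows[0][0] if windows else 0.0
    for fm in usable:
        s = fm.record.score
        for w, (lo, hi) in enumerate(windows):
            # half-open (lo, hi]; the very first window additionally admits s == lo
            if (lo < s <= hi) or (w == 0 and s == first_low):
                bins.setdefault(w, []).append(fm.p_hom)
                break
    streams = np.random.SeedSequence(seed).spawn(len(windows))
    estimates = []
    for w, (lo, hi) in enumerate(windows):
        if w not in bins:
            continue
        rng = np.random.default_rng(streams[w])
        label = f"({lo:g},{hi:g}]"
        model = HomFractionMixtureModel(bins[w], params, label=label)
        estimates.append(model.fit(bootstrap_reps=reps, level=level, seed=rng).estimates[0])
    return DamageEstimateResults(estimates, params)


def weighted_average_damage(
    estimates: "DamageEstimateResults | Mapping[str, float]",
    counts: Mapping[str, int],
) -> float:
    """Count-weighted average of per-class damaging fractions.

    ``estimates`` may be a fitted results object or a plain class->rho map;
    every class in ``counts`` must have an estimate.
    """
    rho = estimates.rho_map() if isinstance(estimates, DamageEstimateResults) else dict(estimates)
    missing = set(counts) - set(rho)
    if missing:
        raise KeyError(f"no estimate for class(es): {', '.join(sorted(missing))}")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("counts sum to zero")
    return sum(counts[c] * rho[c] for c in counts) / total
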