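"""Domain types for ENU pedigree analysis.

All records validate their closed vocabularies on construction so that
malformed data fails loudly at the boundary rather than deep inside an
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .constants import (
    GENERATIONS,
    GENOTYPES,
    MISSENSE_CLASSES,
    MUTATION_CLASSES,
    PUBLISHED_DAMAGE_PROBABILITIES,
)


class DataValidationError(ValueError):
    """A record violated the schema or a closed vocabulary."""


@dataclass(frozen=True)
class MutationRecord:
    """One annotated coding/splicing mutation.

    ``score`` is the PP2 score in [0, 1]; it is present for the three
    missense classes and absent (None) for the two putative-null classes.
    Positions are 1-based bp on a named chromosome.
    """

    mutation_id: str
    pedigree_id: str
    gene_id: str
    chromosome: str
    position: int
    mutation_class: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.mutation_class not in MUTATION_CLASSES:
            raise DataValidationError(
                f"unknown mutation_class {self.mutation_class!r}; "
                f"permitted: {', '.join(MUTATION_CLASSES)}"
            )
        if self.position < 1:
            raise DataValidationError(
                f"position must be >= 1 (got {self.position} for {self.mutation_id})"
            )
        is_missense = self.mutation_class in MISSENSE_CLASSES
        if is_missense and self.score is None:
            raise DataValidationError(
                f"missense mutation {self.mutation_id} requires a score"
            )
        if not is_missense and self.score is not None:
            raise DataValidationError(
                f"null-class mutation {self.mutation_id} must not carry a score"
            )
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise DataValidationError(
                f"score must lie in [0, 1] (got {self.score} for {self.mutation_id})"
            )


@dataclass
class Mouse:
    """One mouse with its per-mutation genotype calls.

    G3 mice must carry ``dam_id`` and ``litter_id`` so that HOM proportions
    can be computed per heterozygous-dam litter.
    """

    mouse_id: str
    pedigree_id: str
    generation: str
    dam_id: str | None = None
    litter_id: str | None = None
    genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.generation not in GENERATIONS:
            raise DataValidationError(
                f"unknown generation {self.generation!r}; permitted: {', '.join(GENERATIONS)}"
            )
        if self.generation == "G3" and (self.dam_id is None or self.litter_id is None):
            raise DataValidationError(
                f"G3 mouse {self.mouse_id} requires dam_id and litter_id"
            )
        for mut, call in self.genotypes.items():
            if call not in GENOTYPES:
                raise DataValidationError(
                    f"genotype {call!r} for mouse {self.mouse_id} at {mut}; "
                    f"permitted: {', '.join(GENOTYPES)}"
                )


@dataclass(frozen=True)
class EssentialityAnnotation:
    """Gene-level viability annotation.

    ``lethality_mode`` distinguishes totally essential genes (all homozygous
    null mice die pre-weaning) from partially essential ones (only a fraction
    die); it is 'unknown' only for non-essential genes.
    """

    gene_id: str
    essential: bool
    lethality_mode: str = "unknown"

    def __post_init__(self) -> None:
        if self.lethality_mode not in ("totally", "partially", "unknown"):
            raise DataValidationError(
                f"unknown lethality_mode {self.lethality_mode!r} for {self.gene_id}"
            )
        if not self.essential and self.lethality_mode != "unknown":
            raise DataValidationError(
                f"non-essential gene {self.gene_id} cannot carry a lethality_mode"
            )


@dataclass(frozen=True)
class ScreenLinkageRecord:
    """Bonferroni-adjusted linkage P value for one screen/mutation/model triple."""

    mutation_id: str
    screen_id: str
    model: str
    p_value: float

    def __post_init__(self) -> None:
        if self.model not in ("recessive", "additive", "dominant"):
            raise DataValidationError(f"unknown transmission model {self.model!r}")
        if not (0.0 < self.p_value <= 1.0):
            raise DataValidationError(
                f"p_value must lie in (0, 1] (got {self.p_value})"
            )


class DamageProbabilityMap:
    """Per-class probability that a mutation truly damages protein function.

    Every class in the closed vocabulary must be covered; values are
    probabilities in [0, 1].  ``published()`` returns the reference estimates
    shipped with the package.
    """

    def __init__(self, probabilities: Mapping[str, float]):
        missing = set(MUTATION_CLASSES) - set(probabilities)
        if missing:
            raise DataValidationError(
                f"damage map missing classes: {', '.join(sorted(missing))}"
            )
        extra = set(probabilities) - set(MUTATION_CLASSES)
        if extra:
            raise DataValidationError(
                f"damage map has unknown classes: {', '.join(sorted(extra))}"
            )
        for cls, p in probabilities.items():
            if not (0.0 <= p <= 1.0):
                raise DataValidationError(f"damage probability for {cls} not in [0,1]: {p}")
        self._probs = {cls: float(probabilities[cls]) for cls in MUTATION_CLASSES}

    def __getitem__(self, mutation_class: str) -> float:
        try:
            return self._probs[mutation_class]
        except KeyError:
            raise DataValidationError(
                f"no damage probability for class {mutation_class!r}"
            ) from None

    def __iter__(self):
        return iter(self._probs)

    def items(self):
        return self._probs.items()

    def as_dict(self) -> dict[str, float]:
        return dict(self._probs)

    def __eq__(self, other) -> bool:
        return isinstance(other, DamageProbabilityMap) and self._probs == other._probs

    def __repr__(self) -> str:
        body = ", ".join(f"{c}={p:g}" for c, p in self._probs.items())
        return f"DamageProbabilityMap({body})"

    @classmethod
    def published(cls) -> "DamageProbabilityMap":
        """The reference per-class estimates (0.045 ... 0.626)."""
        return cls(PUBLISHED_DAMAGE_PROBABILITIES)
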