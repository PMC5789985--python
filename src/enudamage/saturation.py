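"""Gene-level damage probability and genome-wide saturation.

For a gene ``g`` with mutations ``j = 1..J`` observed homozygous across G3
mice ``k = 1..K`` (pooled over all pedigrees sharing the gene — a
"superpedigree"), the probability that the gene was truly damaged
homozygously in at least ``n`` mice is

    P_g(n) = sum over damaging-status assignments d in {0,1}^J of
             prod_j P(m_j)^d_j (1-P(m_j))^(1-d_j) * I(c(d) >= n)

where ``c(d)`` counts mice HOM for at least one mutation with ``d_j = 1``.
The sum is evaluated exactly for J <= 10 and by Monte Carlo above that.
Genome saturation is the sum of P_g(n) over all mutated genes, optionally
expressed as a percentage of the genome's gene count and accumulated along
a mutation chronology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import DamageProbabilityMap, Mouse, MutationRecord

DEFAULT_ENUM_LIMIT = 10
DEFAULT_MC_SIMS = 1000


class EnumerationLimitError(ValueError):
    """J exceeds the exact-enumeration limit; use the Monte Carlo path."""


@dataclass
class HomMatrix:
    """Homozygosity matrix for one gene's (super)pedigree.

    ``m[j, k] == 1`` iff mouse ``k`` is HOM for mutation ``j``; ``probs[j]``
    is the damage probability of mutation ``j``.
    """

    gene_id: str
    mutation_ids: list[str]
    mouse_ids: list[str]
    m: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.int8)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.m.ndim != 2:
            raise ValueError("m must be a J x K matrix")
        j, k = self.m.shape
        if j < 1 or k < 1:
            raise ValueError("HomMatrix requires J >= 1 and K >= 1")
        if len(self.mutation_ids) != j or len(self.mouse_ids) != k:
            raise ValueError("mutation_ids/mouse_ids lengths must match m")
        if not np.isin(self.m, (0, 1)).all():
            raise ValueError("m entries must be 0 or 1")
        if self.probs.shape != (j,):
            raise ValueError("probs must have length J")
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("probs must lie in [0, 1]")

    @property
    def n_mutations(self) -> int:
        return self.m.shape[0]

    @property
    def n_mice(self) -> int:
        return self.m.shape[1]

    def restricted(self, mutation_ids: Iterable[str]) -> "HomMatrix | None":
        """Submatrix over the given mutation ids (None if none present)."""
        wanted = set(mutation_ids)
        rows = [j for j, mid in enumerate(self.mutation_ids) if mid in wanted]
        if not rows:
            return None
        return HomMatrix(
            gene_id=self.gene_id,
            mutation_ids=[self.mutation_ids[j] for j in rows],
            mouse_ids=list(self.mouse_ids),
            m=self.m[rows, :],
            probs=self.probs[rows],
        )


def build_superpedigrees(
    mutations: Sequence[MutationRecord],
    mice: Sequence[Mouse],
    damage_map: DamageProbabilityMap | None = None,
    prob_overrides: Mapping[str, float] | None = None,
) -> dict[str, HomMatrix]:
    """Pool each gene's mutations across pedigrees into one HomMatrix.

    Every G3 mouse genotyped for at least one of the gene's mutations
    contributes a column; damage probabilities come from ``damage_map`` by
    class, overridable per mutation id via ``prob_overrides``.
    """
    damage_map = damage_map or DamageProbabilityMap.published()
    prob_overrides = prob_overrides or {}
    by_gene: dict[str, list[MutationRecord]] = {}
    for rec in mutations:
        by_gene.setdefault(rec.gene_id, []).append(rec)

    g3 = [m for m in mice if m.generation == "G3"]
    out: dict[str, HomMatrix] = {}
    for gene_id, recs in by_gene.items():
        mut_ids = [r.mutation_id for r in recs]
        cols = [
            m for m in g3 if any(mid in m.genotypes for mid in mut_ids)
        ]
        if not cols:
            continue
        matrix = np.zeros((len(recs), len(cols)), dtype=np.int8)
        for j, mid in enumerate(mut_ids):
            for k, mouse in enumerate(cols):
                if mouse.genotypes.get(mid) == "HOM":
                    matrix[j, k] = 1
        probs = np.array(
            [
                prob_overrides.get(r.mutation_id, damage_map[r.mutation_class])
                for r in recs
            ]
        )
        out[gene_id] = HomMatrix(
            gene_id=gene_id,
            mutation_ids=mut_ids,
            mouse_ids=[m.mouse_id for m in cols],
            m=matrix,
            probs=probs,
        )
    return out


def damage_prob_exact(
    hm: HomMatrix, n: int, enum_limit: int = DEFAULT_ENUM_LIMIT
) -> float:
    """Exact P_g(n) by enumerating all 2^J damaging-status assignments."""
    j = hm.n_mutations
    if j > enum_limit:
        raise EnumerationLimitError(
            f"J={j} exceeds enumeration limit {enum_limit}; use damage_prob_mc"
        )
    if n < 1:
        return 1.0
    # all assignments as a (2^J, J) 0/1 matrix
    codes = np.arange(2**j, dtype=np.int64)
    assign = (codes[:, None] >> np.arange(j)[None, :]) & 1
    # c per assignment: mice HOM for >= 1 damaging mutation
    hit = (assign @ hm.m) > 0  # (2^J, K)
    c = hit.sum(axis=1)
    weights = np.prod(np.where(assign == 1, hm.probs, 1.0 - hm.probs), axis=1)
    return float(weights[c >= n].sum())


def damage_prob_mc(
    hm: HomMatrix,
    n: int,
    sims: int = DEFAULT_MC_SIMS,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte Carlo P_g(n): sample damaging statuses, count qualifying runs.

    A simulation qualifies when ``c >= n`` mice carry at least one truly
    damaging homozygous mutation, matching the exact-enumeration definition.
    """
    if sims < 1:
        raise ValueError("sims must be >= 1")
    if n < 1:
        return 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    damaging = rng.random((sims, hm.n_mutations)) < hm.probs[None, :]
    hit = (damaging @ hm.m) > 0  # (sims, K)
    c = hit.sum(axis=1)
    return float((c >= n).mean())


def gene_damage_report(
    hm: HomMatrix,
    max_n: int,
    enum_limit: int = DEFAULT_ENUM_LIMIT,
    sims: int = DEFAULT_MC_SIMS,
    seed: int | np.random.Generator | None = None,
) -> list[tuple[int, float]]:
    """P_g(n) for n = 1..max_n, via exact enumeration when J permits."""
    use_exact = hm.n_mutations <= enum_limit
    rng = None
    if not use_exact:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for n in range(1, max_n + 1):
        if use_exact:
            p = damage_prob_exact(hm, n, enum_limit=enum_limit)
        else:
            p = damage_prob_mc(hm, n, sims=sims, seed=rng)
        out.append((n, p))
    return out


def _gene_prob(
    hm: HomMatrix,
    n: int,
    enum_limit: int,
    sims: int,
    rng: np.random.Generator,
) -> float:
    if hm.n_mutations <= enum_limit:
        return damage_prob_exact(hm, n, enum_limit=enum_limit)
    return damage_prob_mc(hm, n, sims=sims, seed=rng)


@dataclass
class SaturationCurve:
    """Cumulative expected damaged-gene count along a mutation chronology.

    ``points`` holds (cumulative mutation count, S) pairs where S is the
    expected number of genes damaged homozygously in >= n_cutoff mice.
    ``genome_size`` of 0 means "report S, not a percentage".
    """

    n_cutoff: int
    points: list[tuple[int, float]]
    genome_size: int = 0

    def as_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.points, columns=["n_mutations", "expected_damaged_genes"])
        if self.genome_size > 0:
            frame["saturation_pct"] = (
                frame["expected_damaged_genes"] / self.genome_size * 100.0
            )
        return frame

    @property
    def final_s(self) -> float:
        return self.points[-1][1] if self.points else 0.0

    def plot(self, ax=None):
        """Cumulative saturation vs. mutation number (matplotlib Axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.as_frame()
        y = (
            frame["saturation_pct"]
            if self.genome_size > 0
            else frame["expected_damaged_genes"]
        )
        ax.plot(frame["n_mutations"], y, drawstyle="steps-post")
        ax.set_xlabel("cumulative mutation count")
        ax.set_ylabel(
            "genome saturation (%)" if self.genome_size > 0 else "expected damaged genes"
        )
        ax.set_title(f"n >= {self.n_cutoff} HOM mice")
        return ax


def genome_saturation(
    matrices: Mapping[str, HomMatrix],
    n: int,
    genome_size: int = 0,
    order: Sequence[str] | None = None,
    enum_limit: int = DEFAULT_ENUM_LIMIT,
    sims: int = DEFAULT_MC_SIMS,
    seed: int | None = None,
) -> SaturationCurve:
    """Cumulative saturation S = sum_g P_g(n) along a mutation chronology.

    ``order`` is the mutation accrual order (defaults to the order mutations
    appear across the matrices).  After each added mutation, the P_g(n) of
    its gene is recomputed over the mutations seen so far and the running
    sum updated.
    """
    rng = np.random.default_rng(seed)
    gene_of_mutation: dict[str, str] = {}
    for gene_id, hm in matrices.items():
        for mid in hm.mutation_ids:
            gene_of_mutation[mid] = gene_id
    if order is None:
        order = list(gene_of_mutation)

    seen: list[str] = []
    gene_p: dict[str, float] = {}
    s = 0.0
    points: list[tuple[int, float]] = []
    for t, mid in enumerate(order, start=1):
        seen.append(mid)
        gene_id = gene_of_mutation.get(mid)
        if gene_id is not None:
            sub = matrices[gene_id].restricted(seen)
            if sub is not None:
                new_p = _gene_prob(sub, n, enum_limit, sims, rng)
                s += new_p - gene_p.get(gene_id, 0.0)
                gene_p[gene_id] = new_p
        points.append((t, s))
    return SaturationCurve(n_cutoff=n, points=points, genome_size=genome_size)
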