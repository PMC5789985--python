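"""In-silico breeding of virtual G3 mice and the essential-fraction scan.

The scan estimates the fraction of genes that are essential by re-breeding
each pedigree's G3 generation in silico at its *neutral* size (the size
predicted by a pedigree-size regression with all mutation-count covariates
zeroed, i.e. assuming no mutation is lethal), assigning an "essential"
quality to a varying fraction of genes, marking mutations truly damaging
with their class-specific probabilities, culling homozygous-damaged pups
(always in totally essential genes, at 50% in partially essential ones),
and regressing the resulting count of genes with a surviving homozygote on
the essential fraction.  The fraction at which the fitted line crosses the
observed count is the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from statsmodels.iolib.table import SimpleTable

from .constants import MUTATION_CLASSES
from .types import DamageProbabilityMap, Mouse, MutationRecord

_CODE = {"REF": 0, "HET": 1, "HOM": 2}


@dataclass
class SimScenario:
    """Study conditions for the essential-fraction scan."""

    essential_fraction_grid: Sequence[float]
    partial_ratio: float = 0.39
    partial_cull_rate: float = 0.5
    replicates: int = 5
    damage_map: DamageProbabilityMap = field(default_factory=DamageProbabilityMap.published)
    seed: int | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.essential_fraction_grid, dtype=float)
        if grid.size and (grid.min() < 0 or grid.max() > 1):
            raise ValueError("essential_fraction_grid values must lie in [0, 1]")
        if not (0.0 <= self.partial_cull_rate <= 1.0):
            raise ValueError("partial_cull_rate must lie in [0, 1]")
        if self.partial_ratio < 0:
            raise ValueError("partial_ratio must be >= 0")

    @property
    def partial_given_essential(self) -> float:
        """P(partially | essential) under a partial:total ratio r:1."""
        return self.partial_ratio / (1.0 + self.partial_ratio)


@dataclass(frozen=True)
class SimResult:
    """One simulated cohort at one essential fraction."""

    essential_fraction: float
    replicate: int
    genes_with_hom: int
    virtual_g3_count: int


@dataclass
class SimPedigree:
    """One pedigree's breeding inputs for the simulation.

    Genotypes are integer codes (0=REF, 1=HET, 2=HOM) per locus; ``dams``
    holds one code array per G2 dam, ``sire`` the (shared) G1 sire codes.
    ``locus_idx`` indexes the pedigree's loci into the dataset-level
    mutation arrays.  ``litter_dam_idx``/``litter_sizes`` record, per
    observed litter, which dam produced it and how many G3 mice survived.
    """

    pedigree_id: str
    locus_idx: np.ndarray
    dams: list[np.ndarray]
    sire: np.ndarray
    observed_g3: int
    pedigree_type: str = "standard"
    litter_dam_idx: list[int] = field(default_factory=list)
    litter_sizes: list[int] = field(default_factory=list)

    @property
    def n_litters(self) -> int:
        return max(len(self.litter_sizes), 1)


@dataclass
class BreedingDataset:
    """Dataset-level arrays for the scan: mutations, genes, pedigrees."""

    gene_ids: list[str]
    mutation_ids: list[str]
    mutation_gene_idx: np.ndarray
    mutation_class_idx: np.ndarray
    pedigrees: list[SimPedigree]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_mutations(self) -> int:
        return len(self.mutation_ids)

    def covariate_frame(self) -> pd.DataFrame:
        """Per-pedigree covariates for the size regression: observed G3
        count, pedigree type, litters, and HET-dam mutation counts per class."""
        rows = []
        for ped in self.pedigrees:
            counts = dict.fromkeys(MUTATION_CLASSES, 0)
            cls = self.mutation_class_idx[ped.locus_idx]
            for dam in ped.dams:
                het = dam == 1
                for ci, cname in enumerate(MUTATION_CLASSES):
                    counts[cname] += int(np.sum(het & (cls == ci)))
            rows.append(
                {
                    "pedigree_id": ped.pedigree_id,
                    "g3_count": ped.observed_g3,
                    "pedigree_type": ped.pedigree_type,
                    "n_litters": ped.n_litters,
                    **{f"n_{c}": counts[c] for c in MUTATION_CLASSES},
                }
            )
        return pd.DataFrame(rows)

    def litter_frame(self) -> pd.DataFrame:
        """Per-litter covariates: surviving litter size, pedigree type and the
        producing dam's per-class HET mutation counts.

        At litter granularity lethality is additive in the dam's mutation
        counts (each damaging HET mutation removes on average a fixed number
        of that litter's pups), so zeroing the counts recovers the unculled
        litter size without the litters-coefficient confounding that affects
        a whole-pedigree regression.
        """
        rows = []
        for ped in self.pedigrees:
            cls = self.mutation_class_idx[ped.locus_idx]
            dam_counts = []
            for dam in ped.dams:
                het = dam == 1
                dam_counts.append(
                    {f"n_{c}": int(np.sum(het & (cls == ci)))
                     for ci, c in enumerate(MUTATION_CLASSES)}
                )
            for dam_i, size in zip(ped.litter_dam_idx, ped.litter_sizes):
                rows.append(
                    {
                        "pedigree_id": ped.pedigree_id,
                        "g3_count": size,
                        "pedigree_type": ped.pedigree_type,
                        **dam_counts[dam_i],
                    }
                )
        return pd.DataFrame(rows)

    @property
    def has_litters(self) -> bool:
        return any(ped.litter_sizes for ped in self.pedigrees)


class CollinearityError(ValueError):
    """The size-regression design matrix is rank deficient."""


_MUT_COUNT_COLS = tuple(f"n_{c}" for c in MUTATION_CLASSES)


class PedigreeSizeModel:
    """OLS model of pedigree G3 counts on breeding covariates.

    The neutral prediction — pedigree size had every mutation been neutral —
    is obtained by zeroing the per-class mutation-count covariates, then
    rounding to the nearest nonnegative integer.
    """

    def __init__(self):
        self._results = None
        self._columns: list[str] = []
        self._type_levels: list[str] = []

    @property
    def fitted(self) -> bool:
        return self._results is not None

    @property
    def params(self) -> pd.Series:
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        return self._results.params

    def _design(self, table: pd.DataFrame) -> pd.DataFrame:
        x = pd.DataFrame(index=table.index)
        x["const"] = 1.0
        if "pedigree_type" in table.columns:
            for level in self._type_levels:
                x[f"type_{level}"] = (table["pedigree_type"] == level).astype(float)
        if "n_litters" in table.columns:
            x["n_litters"] = table["n_litters"].astype(float)
        for col in _MUT_COUNT_COLS:
            if col in table.columns:
                x[col] = table[col].astype(float)
        return x

    def fit(self, table: pd.DataFrame) -> "PedigreeSizeModel":
        if "g3_count" not in table.columns:
            raise ValueError("table must have a g3_count column")
        if "pedigree_type" in table.columns:
            levels = sorted(table["pedigree_type"].astype(str).unique())
            self._type_levels = levels[1:]  # first level absorbed by intercept
        x = self._design(table)
        arr = x.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(arr)
        if rank < arr.shape[1]:
            _, _, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
            collinear = [x.columns[i] for i in piv[rank:]]
            raise CollinearityError(
                f"rank-deficient design; collinear column(s): {', '.join(collinear)}"
            )
        y = table["g3_count"].astype(float)
        self._results = sm.OLS(y, x).fit()
        self._columns = list(x.columns)
        return self

    def predict_raw(self, table: pd.DataFrame) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        x = self._design(table)
        x = x.reindex(columns=self._columns, fill_value=0.0)
        return np.asarray(self._results.predict(x))

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return np.maximum(0, np.rint(self.predict_raw(table))).astype(int)

    def predict_neutral(self, table: pd.DataFrame) -> np.ndarray:
        """Predicted sizes with all mutation-count covariates zeroed."""
        neutral = table.copy()
        for col in _MUT_COUNT_COLS:
            if col in neutral.columns:
                neutral[col] = 0
        return self.predict(neutral)

    def predict_neutral_raw(self, table: pd.DataFrame) -> np.ndarray:
        neutral = table.copy()
        for col in _MUT_COUNT_COLS:
            if col in neutral.columns:
                neutral[col] = 0
        return self.predict_raw(neutral)


def fit_pedigree_size_model(table: pd.DataFrame) -> PedigreeSizeModel:
    """Fit the pedigree-size OLS model (see :class:`PedigreeSizeModel`)."""
    return PedigreeSizeModel().fit(table)


def neutral_pedigree_sizes(dataset: "BreedingDataset") -> np.ndarray:
    """Per-pedigree G3 counts predicted under the no-lethality assumption.

    When litter records are available the size model is fitted per litter
    (see :meth:`BreedingDataset.litter_frame`) and the neutral pedigree size
    is the rounded sum of its litters' neutral predictions; otherwise the
    pedigree-level regression with the litters covariate is used directly.
    """
    if dataset.has_litters:
        litters = dataset.litter_frame()
        model = fit_pedigree_size_model(litters)
        litters = litters.assign(_neutral=model.predict_neutral_raw(litters))
        per_ped = litters.groupby("pedigree_id")["_neutral"].sum()
        sizes = np.array(
            [per_ped.get(ped.pedigree_id, 0.0) for ped in dataset.pedigrees]
        )
        return np.maximum(0, np.rint(sizes)).astype(int)
    table = dataset.covariate_frame()
    model = fit_pedigree_size_model(table)
    return model.predict_neutral(table)


def _as_codes(genotypes: Sequence[str] | np.ndarray) -> np.ndarray:
    arr = np.asarray(genotypes)
    if arr.dtype.kind in "iu":
        codes = arr.astype(np.int8)
        if codes.size and (codes.min() < 0 or codes.max() > 2):
            raise ValueError("genotype codes must be 0 (REF), 1 (HET) or 2 (HOM)")
        return codes
    try:
        return np.array([_CODE[g] for g in arr], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unknown parental genotype {exc.args[0]!r}") from None


def breed_virtual_g3(
    dam_genotypes: Sequence[str] | np.ndarray,
    sire_genotypes: Sequence[str] | np.ndarray,
    n_pups: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Breed ``n_pups`` virtual G3 mice from one dam and the G1 sire.

    Each pup draws one allele from each parent independently per locus
    (HET transmits the variant with probability 1/2, HOM with 1, REF with
    0); loci are treated as unlinked.  Returns an (n_pups, n_loci) matrix
    of genotype codes 0/1/2.
    """
    dam = _as_codes(dam_genotypes)
    sire = _as_codes(sire_genotypes)
    if dam.shape != sire.shape:
        raise ValueError("dam and sire genotype vectors must have equal length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = (n_pups, dam.size)
    from_dam = (rng.random(shape) < dam[None, :] / 2.0).astype(np.int8)
    from_sire = (rng.random(shape) < sire[None, :] / 2.0).astype(np.int8)
    return from_dam + from_sire


def assign_essentiality_and_damage(
    n_genes: int,
    mutation_gene_idx: np.ndarray,
    mutation_class_idx: np.ndarray,
    essential_fraction: float,
    scenario: SimScenario,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly label genes essential and mutations truly damaging.

    Returns ``(gene_labels, damaging)``: per-gene labels 0 = non-essential,
    1 = partially essential, 2 = totally essential (partial:total split at
    the scenario's 39:100 ratio), and a per-mutation boolean of true damage
    drawn with the class probability from the scenario's damage map.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    essential = rng.random(n_genes) < essential_fraction
    partial = rng.random(n_genes) < scenario.partial_given_essential
    gene_labels = np.where(essential, np.where(partial, 1, 2), 0).astype(np.int8)
    class_probs = np.array([scenario.damage_map[c] for c in MUTATION_CLASSES])
    damaging = rng.random(mutation_gene_idx.size) < class_probs[mutation_class_idx]
    return gene_labels, damaging


def cull(
    pup_genotypes: np.ndarray,
    damaging: np.ndarray,
    gene_labels_per_locus: np.ndarray,
    partial_cull_rate: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Survival mask for virtual pups.

    A pup dies deterministically if HOM for a damaging mutation in a totally
    essential gene, and with probability ``partial_cull_rate`` (independently
    per mutation) if HOM for a damaging mutation in a partially essential
    gene; the total rule dominates when both apply.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hom = pup_genotypes == 2
    lethal_total = damaging & (gene_labels_per_locus == 2)
    lethal_partial = damaging & (gene_labels_per_locus == 1)
    dead = (hom & lethal_total[None, :]).any(axis=1)
    if lethal_partial.any():
        coin = rng.random(pup_genotypes.shape) < partial_cull_rate
        dead |= (hom & lethal_partial[None, :] & coin).any(axis=1)
    return ~dead


def observed_genes_with_hom(
    mutations: Sequence[MutationRecord], mice: Iterable[Mouse]
) -> int:
    """Number of genes with any mutation homozygous in >= 1 surviving G3 mouse."""
    gene_of = {r.mutation_id: r.gene_id for r in mutations}
    genes: set[str] = set()
    for mouse in mice:
        if mouse.generation != "G3":
            continue
        for mid, call in mouse.genotypes.items():
            if call == "HOM" and mid in gene_of:
                genes.add(gene_of[mid])
    return len(genes)


def simulate_replicate(
    dataset: BreedingDataset,
    neutral_sizes: np.ndarray,
    essential_fraction: float,
    scenario: SimScenario,
    seed: int | np.random.SeedSequence,
    replicate: int = 0,
) -> SimResult:
    """Simulate one virtual cohort and count genes with a surviving homozygote.

    Randomness is split into independent label / breeding / culling streams
    so that a run at essential fraction 0 breeds exactly the same pups as a
    lethality-free Mendelian simulation with the same seed.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_labels, ss_breed, ss_cull = ss.spawn(3)
    rng_labels = np.random.default_rng(ss_labels)
    rng_breed = np.random.default_rng(ss_breed)
    rng_cull = np.random.default_rng(ss_cull)

    gene_labels, damaging = assign_essentiality_and_damage(
        dataset.n_genes,
        dataset.mutation_gene_idx,
        dataset.mutation_class_idx,
        essential_fraction,
        scenario,
        rng_labels,
    )

    genes_hit = np.zeros(dataset.n_genes, dtype=bool)
    n_virtual = 0
    for ped, size in zip(dataset.pedigrees, neutral_sizes):
        size = int(size)
        if size <= 0 or not ped.dams:
            continue
        locus_genes = dataset.mutation_gene_idx[ped.locus_idx]
        locus_damaging = damaging[ped.locus_idx]
        locus_labels = gene_labels[locus_genes]
        counts = rng_breed.multinomial(size, np.full(len(ped.dams), 1.0 / len(ped.dams)))
        for dam, c in zip(ped.dams, counts):
            if c == 0:
                continue
            pups = breed_virtual_g3(dam, ped.sire, int(c), rng_breed)
            alive = cull(
                pups, locus_damaging, locus_labels, scenario.partial_cull_rate, rng_cull
            )
            n_virtual += int(alive.sum())
            if alive.any():
                hom_any = (pups[alive] == 2).any(axis=0)
                genes_hit[locus_genes[hom_any]] = True
    return SimResult(
        essential_fraction=float(essential_fraction),
        replicate=replicate,
        genes_with_hom=int(genes_hit.sum()),
        virtual_g3_count=n_virtual,
    )


class ScanResult:
    """Fitted essential-fraction scan: regression line and solved fraction."""

    def __init__(
        self,
        estimated_fraction: float,
        slope: float,
        intercept: float,
        results: pd.DataFrame,
        observed_stat: int,
    ):
        self.estimated_fraction = estimated_fraction
        self.slope = slope
        self.intercept = intercept
        self.results = results
        self.observed_stat = observed_stat

    def summary(self) -> SimpleTable:
        rows = [
            ["estimated essential fraction", f"{self.estimated_fraction:.4f}"],
            ["regression slope", f"{self.slope:.2f}"],
            ["regression intercept", f"{self.intercept:.2f}"],
            ["observed genes with HOM mouse", f"{self.observed_stat:d}"],
            ["simulated cohorts", f"{len(self.results):d}"],
        ]
        return SimpleTable(rows, title="Essential-fraction scan")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(
            self.results["essential_fraction"],
            self.results["genes_with_hom"],
            s=12,
            alpha=0.6,
            label="simulated",
        )
        grid = np.linspace(self.results["essential_fraction"].min(),
                           self.results["essential_fraction"].max(), 50)
        ax.plot(grid, self.intercept + self.slope * grid, color="k", label="fit")
        ax.axhline(self.observed_stat, color="tab:blue", ls="--", label="observed")
        ax.axvline(self.estimated_fraction, color="tab:red", ls=":")
        ax.set_xlabel("essential gene fraction")
        ax.set_ylabel("genes with >= 1 HOM G3 mouse")
        ax.legend()
        return ax


class EssentialFractionScan:
    """Model object scanning essential-gene fractions against observed data.

    ``fit(observed_stat)`` simulates ``scenario.replicates`` cohorts at every
    grid fraction, fits a joint linear regression of the
    genes-with-homozygote count on the fraction (all replicate points, not
    per-fraction means), and solves the line for the fraction reproducing
    ``observed_stat``.
    """

    def __init__(
        self,
        dataset: BreedingDataset,
        scenario: SimScenario,
        neutral_sizes: np.ndarray | None = None,
    ):
        self.dataset = dataset
        self.scenario = scenario
        grid = np.asarray(scenario.essential_fraction_grid, dtype=float)
        if np.unique(grid).size < 2:
            raise ValueError("essential_fraction_grid needs >= 2 distinct points")
        self.grid = grid
        if neutral_sizes is None:
            neutral_sizes = neutral_pedigree_sizes(dataset)
        self.neutral_sizes = np.asarray(neutral_sizes, dtype=int)

    def simulate(self) -> pd.DataFrame:
        root = np.random.SeedSequence(self.scenario.seed)
        cells = root.spawn(self.grid.size * self.scenario.replicates)
        rows = []
        i = 0
        for fraction in self.grid:
            for rep in range(self.scenario.replicates):
                res = simulate_replicate(
                    self.dataset,
                    self.neutral_sizes,
                    fraction,
                    self.scenario,
                    cells[i],
                    replicate=rep,
                )
                rows.append(res)
                i += 1
        return pd.DataFrame(
            [
                {
                    "essential_fraction": r.essential_fraction,
                    "replicate": r.replicate,
                    "genes_with_hom": r.genes_with_hom,
                    "virtual_g3_count": r.virtual_g3_count,
                }
                for r in rows
            ]
        )

    def fit(self, observed_stat: int) -> ScanResult:
        frame = self.simulate()
        x = sm.add_constant(frame["essential_fraction"].to_numpy())
        ols = sm.OLS(frame["genes_with_hom"].to_numpy(), x).fit()
        intercept, slope = float(ols.params[0]), float(ols.params[1])
        if slope >= 0:
            raise ValueError(
                f"fitted slope {slope:.3f} is not negative; the gene count must "
                "decrease with essentiality"
            )
        estimate = float(np.clip((observed_stat - intercept) / slope, 0.0, 1.0))
        return ScanResult(estimate, slope, intercept, frame, int(observed_stat))


def scan_essential_fraction(
    dataset: BreedingDataset,
    scenario: SimScenario,
    observed_stat: int,
    neutral_sizes: np.ndarray | None = None,
) -> ScanResult:
    """Convenience wrapper: build the scan and fit it to ``observed_stat``."""
    return EssentialFractionScan(dataset, scenario, neutral_sizes).fit(observed_stat)
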