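"""Synthetic ENU-cohort generator with known ground truth.

Emulates the statistical structure of a large mutagenesis breeding program:
pedigrees founded by an exome-genotyped G1 male heterozygous for a private
set of coding/splicing mutations, G2 daughters HET or REF per locus with
equal probability, and G3 offspring from the G2 x G1 backcross carrying
mutations to homozygosity.  Defaults target ~30 surviving G3 mice per
pedigree and ~34 carried mutations per G3 mouse, with mutation classes mixed
in the reference cohort's proportions.  Viability is applied at birth:
a pup homozygous for a truly damaging mutation of a totally essential gene
dies; in a partially essential gene it dies with probability
``1 - theta/0.25`` so that surviving HOM proportions center on ``theta``.

Every latent label (gene essentiality, per-mutation true damage, pre-cull
pedigree sizes) is recorded in the truth tables, so all downstream
estimators can be checked against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import (
    COHORT_CLASS_COUNTS,
    DEFAULT_PARTIAL_RATIO,
    DEFAULT_THETA,
    MISSENSE_CLASSES,
    MOUSE_AUTOSOME_LENGTHS_BP,
    MUTATION_CLASSES,
    PUBLISHED_DAMAGE_PROBABILITIES,
    SCORE_RANGES,
)
from .simulation import BreedingDataset, SimPedigree, breed_virtual_g3, cull
from .types import EssentialityAnnotation, Mouse, MutationRecord


def _default_class_mix() -> dict[str, float]:
    counts = COHORT_CLASS_COUNTS["all"]
    total = sum(counts.values())
    return {c: counts[c] / total for c in MUTATION_CLASSES}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    The defaults encode the reference cohort's scale: ~30 G3 mice per
    pedigree, ~34 mutations carried per G3 mouse (achieved with a Poisson(55)
    per-pedigree mutation count, since a G3 pup carries a given mutation with
    probability 5/8 under the backcross), the reference class mix, published
    per-class damage fractions, a 34% essential-gene fraction and a 39:100
    partial:total split.
    """

    n_pedigrees: int = 100
    seed: int = 0
    mean_mutations_per_pedigree: float = 55.0
    mean_dams_per_pedigree: float = 4.0
    extra_litter_prob: float = 0.5
    mean_litter_size: float = 7.0
    class_mix: Mapping[str, float] = field(default_factory=_default_class_mix)
    true_damage_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(PUBLISHED_DAMAGE_PROBABILITIES)
    )
    essential_fraction: float = 0.34
    partial_ratio: float = DEFAULT_PARTIAL_RATIO
    theta: float = DEFAULT_THETA
    gene_collision_rate: float = 0.05
    shared_gene_pool_size: int = 300
    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(MOUSE_AUTOSOME_LENGTHS_BP)
    )
    pedigree_type_probs: Mapping[str, float] = field(
        default_factory=lambda: {"standard": 0.7, "g0prime": 0.3}
    )
    type_litter_effect: Mapping[str, float] = field(
        default_factory=lambda: {"standard": 0.0, "g0prime": 1.0}
    )
    genotype_drop_rate: float = 0.0

    def __post_init__(self) -> None:
        mix_total = sum(self.class_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1 (got {mix_total!r})")
        for cls in MUTATION_CLASSES:
            if cls not in self.class_mix:
                raise ValueError(f"class_mix missing class {cls}")
            frac = self.true_damage_fractions.get(cls)
            if frac is None or not (0.0 <= frac <= 1.0):
                raise ValueError(f"true_damage_fractions[{cls}] must lie in [0, 1]")
        if not (0.0 <= self.essential_fraction <= 1.0):
            raise ValueError("essential_fraction must lie in [0, 1]")
        if not (0.0 < self.theta < 0.25):
            raise ValueError("theta must lie in (0, 0.25)")

    @property
    def partial_death_prob(self) -> float:
        """Per-HOM-pup death probability in partially essential genes,
        chosen so surviving HOM proportions center on theta."""
        return 1.0 - self.theta / 0.25

    def to_dict(self) -> dict:
        return {
            "n_pedigrees": self.n_pedigrees,
            "seed": self.seed,
            "mean_mutations_per_pedigree": self.mean_mutations_per_pedigree,
            "mean_dams_per_pedigree": self.mean_dams_per_pedigree,
            "extra_litter_prob": self.extra_litter_prob,
            "mean_litter_size": self.mean_litter_size,
            "class_mix": dict(self.class_mix),
            "true_damage_fractions": dict(self.true_damage_fractions),
            "essential_fraction": self.essential_fraction,
            "partial_ratio": self.partial_ratio,
            "theta": self.theta,
            "gene_collision_rate": self.gene_collision_rate,
            "shared_gene_pool_size": self.shared_gene_pool_size,
            "genotype_drop_rate": self.genotype_drop_rate,
        }


@dataclass
class SyntheticDataset:
    """Generated cohort: observable tables, truth tables and fast arrays."""

    config: GeneratorConfig
    mutations: pd.DataFrame
    genotypes: pd.DataFrame
    essentiality: pd.DataFrame
    truth_mutations: pd.DataFrame
    truth_litters: pd.DataFrame
    pedigrees: pd.DataFrame
    breeding: BreedingDataset

    def to_records(
        self,
    ) -> tuple[list[MutationRecord], list[Mouse], list[EssentialityAnnotation]]:
        muts = [
            MutationRecord(
                mutation_id=r.mutation_id,
                pedigree_id=r.pedigree_id,
                gene_id=r.gene_id,
                chromosome=str(r.chromosome),
                position=int(r.position),
                mutation_class=r.mutation_class,
                score=None if r.score == "." else float(r.score),
            )
            for r in self.mutations.itertuples(index=False)
        ]
        mice: dict[str, Mouse] = {}
        for r in self.genotypes.itertuples(index=False):
            if r.mouse_id not in mice:
                mice[r.mouse_id] = Mouse(
                    mouse_id=r.mouse_id,
                    pedigree_id=r.pedigree_id,
                    generation=r.generation,
                    dam_id=None if r.dam_id == "." else r.dam_id,
                    litter_id=None if r.litter_id == "." else r.litter_id,
                )
            mice[r.mouse_id].genotypes[r.mutation_id] = r.genotype
        anns = [
            EssentialityAnnotation(
                gene_id=r.gene_id,
                essential=r.essential == "true",
                lethality_mode="unknown" if r.lethality_mode == "." else r.lethality_mode,
            )
            for r in self.essentiality.itertuples(index=False)
        ]
        return muts, list(mice.values()), anns

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in [
            ("mutations", self.mutations),
            ("genotypes", self.genotypes),
            ("essentiality", self.essentiality),
            ("truth_mutations", self.truth_mutations),
            ("truth_litters", self.truth_litters),
            ("pedigrees", self.pedigrees),
        ]:
            path = out / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            paths[name] = path
        prov = out / "provenance.json"
        prov.write_text(json.dumps({"config": self.config.to_dict()}, indent=2) + "\n")
        paths["provenance"] = prov
        return paths


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a full synthetic cohort under ``config``.

    Same config (including seed) yields byte-identical output tables.
    """
    rng = np.random.default_rng(config.seed)
    classes = list(MUTATION_CLASSES)
    class_p = np.array([config.class_mix[c] for c in classes])
    chroms = list(config.chromosome_lengths)
    chrom_lens = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    types = list(config.pedigree_type_probs)
    type_p = np.array([config.pedigree_type_probs[t] for t in types])

    # --- pass 1: pedigree structure and mutation annotations -------------
    ped_ids = [f"P{p:04d}" for p in range(config.n_pedigrees)]
    ped_type = [types[i] for i in rng.choice(len(types), size=config.n_pedigrees, p=type_p)]
    n_loci = np.maximum(1, rng.poisson(config.mean_mutations_per_pedigree, config.n_pedigrees))

    mut_rows = []
    mut_class_idx = []
    mut_gene = []
    loci_of_ped: list[list[int]] = []
    next_gene = 0
    m_global = 0
    for p, ped in enumerate(ped_ids):
        idxs = []
        ci = rng.choice(len(classes), size=n_loci[p], p=class_p)
        chrom_i = rng.choice(len(chroms), size=n_loci[p], p=chrom_p)
        pos_u = rng.random(n_loci[p])
        score_u = rng.random(n_loci[p])
        collide = rng.random(n_loci[p]) < config.gene_collision_rate
        shared = rng.integers(0, config.shared_gene_pool_size, size=n_loci[p])
        for i in range(n_loci[p]):
            cls = classes[ci[i]]
            if collide[i]:
                gene = f"gshare{shared[i]:04d}"
            else:
                gene = f"g{next_gene:06d}"
                next_gene += 1
            if cls in MISSENSE_CLASSES:
                lo, hi = SCORE_RANGES[cls]
                score = f"{lo + score_u[i] * (hi - lo):.4f}"
            else:
                score = "."
            mut_rows.append(
                {
                    "mutation_id": f"mut{p:04d}_{i:03d}",
                    "pedigree_id": ped,
                    "gene_id": gene,
                    "chromosome": chroms[chrom_i[i]],
                    "position": int(pos_u[i] * (chrom_lens[chrom_i[i]] - 1)) + 1,
                    "mutation_class": cls,
                    "score": score,
                }
            )
            mut_class_idx.append(ci[i])
            mut_gene.append(gene)
            idxs.append(m_global)
            m_global += 1
        loci_of_ped.append(idxs)

    mutations = pd.DataFrame(mut_rows)
    mut_class_idx = np.array(mut_class_idx)
    gene_ids = list(dict.fromkeys(mut_gene))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    mut_gene_idx = np.array([gene_index[g] for g in mut_gene])

    # --- latent labels ----------------------------------------------------
    essential = rng.random(len(gene_ids)) < config.essential_fraction
    partial = rng.random(len(gene_ids)) < config.partial_ratio / (1.0 + config.partial_ratio)
    gene_labels = np.where(essential, np.where(partial, 1, 2), 0).astype(np.int8)
    damage_p = np.array([config.true_damage_fractions[c] for c in classes])
    damaging = rng.random(len(mut_rows)) < damage_p[mut_class_idx]

    # --- pass 2: breeding with viability ---------------------------------
    geno_cols = {k: [] for k in (
        "mouse_id", "pedigree_id", "generation", "dam_id", "litter_id",
        "mutation_id", "genotype",
    )}
    call_names = np.array(["REF", "HET", "HOM"])

    def emit(mouse_id, ped, gen, dam_id, litter_id, mut_ids, codes):
        keep = np.ones(len(mut_ids), dtype=bool)
        if config.genotype_drop_rate > 0:
            keep = rng.random(len(mut_ids)) >= config.genotype_drop_rate
        n = int(keep.sum())
        geno_cols["mouse_id"].extend([mouse_id] * n)
        geno_cols["pedigree_id"].extend([ped] * n)
        geno_cols["generation"].extend([gen] * n)
        geno_cols["dam_id"].extend([dam_id] * n)
        geno_cols["litter_id"].extend([litter_id] * n)
        geno_cols["mutation_id"].extend([mut_ids[i] for i in np.flatnonzero(keep)])
        geno_cols["genotype"].extend(call_names[codes[keep]])

    ped_rows = []
    litter_rows = []
    sim_pedigrees = []
    for p, ped in enumerate(ped_ids):
        idxs = np.array(loci_of_ped[p])
        mut_ids = [mut_rows[i]["mutation_id"] for i in idxs]
        n_loc = idxs.size
        sire_codes = np.ones(n_loc, dtype=np.int8)
        emit(f"{ped}_G1", ped, "G1", ".", ".", mut_ids, sire_codes)

        locus_damaging = damaging[idxs]
        locus_labels = gene_labels[mut_gene_idx[idxs]]

        n_dams = 1 + rng.poisson(max(config.mean_dams_per_pedigree - 1.0, 0.0))
        litter_mean = config.mean_litter_size + config.type_litter_effect.get(ped_type[p], 0.0)
        dams = []
        litter_dam_idx: list[int] = []
        litter_sizes: list[int] = []
        n_litters = 0
        n_born = 0
        n_surviving = 0
        for d in range(n_dams):
            dam_id = f"{ped}_G2_{d:02d}"
            dam_codes = (rng.random(n_loc) < 0.5).astype(np.int8)  # HET or REF
            dams.append(dam_codes)
            emit(dam_id, ped, "G2", ".", ".", mut_ids, dam_codes)
            litters = 1 + int(rng.random() < config.extra_litter_prob)
            for li in range(litters):
                n_litters += 1
                size = 1 + rng.poisson(max(litter_mean - 1.0, 0.0))
                n_born += size
                pups = breed_virtual_g3(dam_codes, sire_codes, size, rng)
                alive = cull(
                    pups, locus_damaging, locus_labels,
                    partial_cull_rate=config.partial_death_prob, seed=rng,
                )
                litter_id = f"{dam_id}_L{li}"
                litter_dam_idx.append(d)
                litter_sizes.append(int(alive.sum()))
                litter_rows.append(
                    {
                        "pedigree_id": ped,
                        "dam_id": dam_id,
                        "litter_id": litter_id,
                        "n_born": size,
                        "n_surviving": int(alive.sum()),
                    }
                )
                for q in np.flatnonzero(alive):
                    n_surviving += 1
                    emit(
                        f"{ped}_G3_{n_surviving:04d}", ped, "G3",
                        dam_id, litter_id, mut_ids, pups[q],
                    )
        ped_rows.append(
            {
                "pedigree_id": ped,
                "pedigree_type": ped_type[p],
                "n_dams": n_dams,
                "n_litters": n_litters,
                "n_born": n_born,
                "n_surviving": n_surviving,
            }
        )
        sim_pedigrees.append(
            SimPedigree(
                pedigree_id=ped,
                locus_idx=idxs,
                dams=dams,
                sire=sire_codes,
                observed_g3=n_surviving,
                pedigree_type=ped_type[p],
                litter_dam_idx=litter_dam_idx,
                litter_sizes=litter_sizes,
            )
        )

    genotypes = pd.DataFrame(geno_cols)
    mode_name = np.array(["unknown", "partially", "totally"])
    essentiality = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "essential": np.where(gene_labels > 0, "true", "false"),
            "lethality_mode": np.where(gene_labels > 0, mode_name[gene_labels], "."),
        }
    )
    truth_mutations = pd.DataFrame(
        {
            "mutation_id": mutations["mutation_id"],
            "gene_id": mutations["gene_id"],
            "mutation_class": mutations["mutation_class"],
            "truly_damaging": damaging,
            "gene_label": mode_name[gene_labels[mut_gene_idx]],
            "gene_essential": gene_labels[mut_gene_idx] > 0,
        }
    )
    pedigrees = pd.DataFrame(ped_rows)
    truth_litters = pd.DataFrame(litter_rows)
    breeding = BreedingDataset(
        gene_ids=gene_ids,
        mutation_ids=list(mutations["mutation_id"]),
        mutation_gene_idx=mut_gene_idx,
        mutation_class_idx=mut_class_idx,
        pedigrees=sim_pedigrees,
    )
    return SyntheticDataset(
        config=config,
        mutations=mutations,
        genotypes=genotypes,
        essentiality=essentiality,
        truth_mutations=truth_mutations,
        truth_litters=truth_litters,
        pedigrees=pedigrees,
        breeding=breeding,
    )


def sample_hom_proportions(
    n: int,
    damage_fraction: float,
    theta: float = DEFAULT_THETA,
    partial_ratio: float = DEFAULT_PARTIAL_RATIO,
    mean_denominator: float = 15.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw per-mutation HOM proportions from the three-subgroup mixture.

    Of ``n`` mutations with total damaging fraction ``damage_fraction``,
    a share ``damage_fraction/(1+partial_ratio)`` is totally lethal
    (``p_i = 0``), ``damage_fraction * partial_ratio/(1+partial_ratio)``
    has HOM counts binomial around ``theta``, and the rest binomial around
    the Mendelian 0.25.  Denominators are Poisson with the given mean
    (floored at 1), emulating finite HET-dam litter sizes, so the sampled
    ``p_i`` carry realistic counting noise.
    """
    if not (0.0 <= damage_fraction <= 1.0):
        raise ValueError("damage_fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    denominators = np.maximum(1, rng.poisson(mean_denominator, size=n))
    u = rng.random(n)
    w_total = damage_fraction / (1.0 + partial_ratio)
    w_partial = damage_fraction * partial_ratio / (1.0 + partial_ratio)
    rate = np.where(u < w_total, 0.0, np.where(u < w_total + w_partial, theta, 0.25))
    hom = rng.binomial(denominators, rate)
    return hom / denominators


def generate_screen_table(
    mutations: pd.DataFrame,
    essentiality: pd.DataFrame,
    rates: Mapping[str, float],
    n_screens: int = 296,
    p_threshold: float = 1e-5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic screen/mutation linkage table.

    Each mutation/screen combination is independently significant with the
    rate of the mutation's gene set (``rates`` maps 'essential' /
    'non_essential' to per-combination significance rates); significant
    combinations draw an adjusted P below ``p_threshold``, others above.
    """
    for key, rate in rates.items():
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"rate for {key} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    essential_genes = set(
        essentiality.loc[essentiality["essential"] == "true", "gene_id"]
    )
    models = np.array(["recessive", "additive", "dominant"])
    rows = {k: [] for k in ("mutation_id", "screen_id", "model", "p_value")}
    screen_ids = [f"screen{s:03d}" for s in range(n_screens)]
    for r in mutations.itertuples(index=False):
        gene_set = "essential" if r.gene_id in essential_genes else "non_essential"
        rate = rates[gene_set]
        sig = rng.random(n_screens) < rate
        u = rng.random(n_screens)
        p = np.where(
            sig,
            u * p_threshold * 0.999 + 1e-300,
            p_threshold + u * (1.0 - p_threshold),
        )
        model_i = rng.integers(0, 3, size=n_screens)
        rows["mutation_id"].extend([r.mutation_id] * n_screens)
        rows["screen_id"].extend(screen_ids)
        rows["model"].extend(models[model_i])
        rows["p_value"].extend(p)
    return pd.DataFrame(rows)
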