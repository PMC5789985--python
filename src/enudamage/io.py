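"""Tab-separated readers/writers for the four input tables.

All tables are UTF-8 TSV with a header row; absent values are written as
``"."``.  Readers never silently drop a malformed row: every rejection is
raised as a :class:`TableFormatError` carrying the 1-based file line number
(the header is line 1).
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .constants import GENOTYPES, MUTATION_CLASSES
from .types import (
    DataValidationError,
    EssentialityAnnotation,
    Mouse,
    MutationRecord,
    ScreenLinkageRecord,
)

logger = logging.getLogger("enudamage")

MISSING = "."

MUTATION_COLUMNS = (
    "mutation_id", "pedigree_id", "gene_id", "chromosome",
    "position", "mutation_class", "score",
)
GENOTYPE_COLUMNS = (
    "mouse_id", "pedigree_id", "generation", "dam_id", "litter_id",
    "mutation_id", "genotype",
)
ESSENTIALITY_COLUMNS = ("gene_id", "essential", "lethality_mode")
SCREEN_COLUMNS = ("mutation_id", "screen_id", "model", "p_value")


class TableFormatError(ValueError):
    """A table violated its schema (missing column or malformed row)."""


def configure_logging(level: int = logging.INFO) -> None:
    """Send structured log lines to standard error."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return frame


def _row_error(path, line_no: int, message: str) -> TableFormatError:
    return TableFormatError(f"{path}:{line_no}: {message}")


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a mutation annotation table into :class:`MutationRecord` objects."""
    frame = _read_table(path, MUTATION_COLUMNS)
    records: list[MutationRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line_no = idx + 2
        try:
            position = int(row.position)
        except ValueError:
            raise _row_error(path, line_no, f"non-numeric position {row.position!r}")
        score = None if row.score == MISSING or row.score == "" else None
        if row.score not in (MISSING, ""):
            try:
                score = float(row.score)
            except ValueError:
                raise _row_error(path, line_no, f"non-numeric score {row.score!r}")
        try:
            records.append(
                MutationRecord(
                    mutation_id=row.mutation_id,
                    pedigree_id=row.pedigree_id,
                    gene_id=row.gene_id,
                    chromosome=row.chromosome,
                    position=position,
                    mutation_class=row.mutation_class,
                    score=score,
                )
            )
        except DataValidationError as exc:
            raise _row_error(path, line_no, str(exc)) from exc
    return records


def write_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    rows = [
        {
            "mutation_id": r.mutation_id,
            "pedigree_id": r.pedigree_id,
            "gene_id": r.gene_id,
            "chromosome": r.chromosome,
            "position": r.position,
            "mutation_class": r.mutation_class,
            "score": MISSING if r.score is None else f"{r.score:.6g}",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(MUTATION_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> list[Mouse]:
    """Read a long-format genotype table and assemble per-mouse genotype maps.

    Duplicate (mouse, mutation) rows and genotype calls outside
    {REF, HET, HOM} are rejected with their line numbers.
    """
    frame = _read_table(path, GENOTYPE_COLUMNS)
    mice: dict[str, Mouse] = {}
    seen: set[tuple[str, str]] = set()
    for idx, row in enumerate(frame.itertuples(index=False)):
        line_no = idx + 2
        if row.genotype not in GENOTYPES:
            raise _row_error(
                path, line_no,
                f"genotype {row.genotype!r}; permitted: {', '.join(GENOTYPES)}",
            )
        key = (row.mouse_id, row.mutation_id)
        if key in seen:
            raise _row_error(
                path, line_no,
                f"duplicate genotype record for mouse {row.mouse_id!r} "
                f"at mutation {row.mutation_id!r}",
            )
        seen.add(key)
        dam_id = None if row.dam_id in (MISSING, "") else row.dam_id
        litter_id = None if row.litter_id in (MISSING, "") else row.litter_id
        if row.mouse_id not in mice:
            try:
                mice[row.mouse_id] = Mouse(
                    mouse_id=row.mouse_id,
                    pedigree_id=row.pedigree_id,
                    generation=row.generation,
                    dam_id=dam_id,
                    litter_id=litter_id,
                )
            except DataValidationError as exc:
                raise _row_error(path, line_no, str(exc)) from exc
        mouse = mice[row.mouse_id]
        if mouse.pedigree_id != row.pedigree_id or mouse.generation != row.generation:
            raise _row_error(
                path, line_no,
                f"inconsistent pedigree/generation for mouse {row.mouse_id!r}",
            )
        mouse.genotypes[row.mutation_id] = row.genotype
    return list(mice.values())


def write_genotypes(mice: Iterable[Mouse], path: str | Path) -> None:
    rows = []
    for m in mice:
        for mut_id, call in m.genotypes.items():
            rows.append(
                {
                    "mouse_id": m.mouse_id,
                    "pedigree_id": m.pedigree_id,
                    "generation": m.generation,
                    "dam_id": m.dam_id or MISSING,
                    "litter_id": m.litter_id or MISSING,
                    "mutation_id": mut_id,
                    "genotype": call,
                }
            )
    pd.DataFrame(rows, columns=list(GENOTYPE_COLUMNS)).to_csv(path, sep="\t", index=False)


_BOOL = {"true": True, "false": False, "1": True, "0": False}


def read_essentiality(path: str | Path) -> list[EssentialityAnnotation]:
    """Read gene essentiality annotations, discarding self-conflicting genes.

    A gene listed with contradictory ``essential`` values (or contradictory
    lethality modes) is dropped entirely, and the number of discarded genes
    is logged — mirroring the treatment of conflicting database records.
    Consistent duplicates are collapsed to one annotation.
    """
    frame = _read_table(path, ESSENTIALITY_COLUMNS)
    per_gene: dict[str, list[EssentialityAnnotation]] = {}
    for idx, row in enumerate(frame.itertuples(index=False)):
        line_no = idx + 2
        essential_raw = row.essential.strip().lower()
        if essential_raw not in _BOOL:
            raise _row_error(
                path, line_no,
                f"essential must be true/false (got {row.essential!r})",
            )
        mode = row.lethality_mode
        if mode in (MISSING, ""):
            mode = "unknown"
        try:
            ann = EssentialityAnnotation(
                gene_id=row.gene_id, essential=_BOOL[essential_raw], lethality_mode=mode
            )
        except DataValidationError as exc:
            raise _row_error(path, line_no, str(exc)) from exc
        per_gene.setdefault(row.gene_id, []).append(ann)

    result: list[EssentialityAnnotation] = []
    n_conflicting = 0
    for gene_id, anns in per_gene.items():
        if len({(a.essential, a.lethality_mode) for a in anns}) > 1:
            n_conflicting += 1
            continue
        result.append(anns[0])
    if n_conflicting:
        logger.warning(
            "discarded %d gene(s) with conflicting essentiality records", n_conflicting
        )
    return result


def write_essentiality(annotations: Iterable[EssentialityAnnotation], path: str | Path) -> None:
    rows = [
        {
            "gene_id": a.gene_id,
            "essential": "true" if a.essential else "false",
            "lethality_mode": MISSING if a.lethality_mode == "unknown" else a.lethality_mode,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=list(ESSENTIALITY_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_screen_linkage(path: str | Path) -> list[ScreenLinkageRecord]:
    """Read screen/mutation linkage P values (Bonferroni-adjusted)."""
    frame = _read_table(path, SCREEN_COLUMNS)
    records: list[ScreenLinkageRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line_no = idx + 2
        try:
            p_value = float(row.p_value)
        except ValueError:
            raise _row_error(path, line_no, f"non-numeric p_value {row.p_value!r}")
        try:
            records.append(
                ScreenLinkageRecord(
                    mutation_id=row.mutation_id,
                    screen_id=row.screen_id,
                    model=row.model,
                    p_value=p_value,
                )
            )
        except DataValidationError as exc:
            raise _row_error(path, line_no, str(exc)) from exc
    return records


def write_screen_linkage(records: Iterable[ScreenLinkageRecord], path: str | Path) -> None:
    rows = [
        {
            "mutation_id": r.mutation_id,
            "screen_id": r.screen_id,
            "model": r.model,
            "p_value": f"{r.p_value:.8g}",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(SCREEN_COLUMNS)).to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if config is None:
        return {}
    if not isinstance(config, dict):
        raise TableFormatError(f"{path}: config must be a YAML mapping")
    return config


def class_counts(records: Iterable[MutationRecord]) -> dict[str, int]:
    """Count mutations per class, over the closed class vocabulary."""
    counter = Counter(r.mutation_class for r in records)
    return {cls: counter.get(cls, 0) for cls in MUTATION_CLASSES}
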