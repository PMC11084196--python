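"""Candidate-selection cascade for HSA-binding drug candidates.

A low-molecular-weight ligand (LMWL) enters the screen as a record of six
filterable attributes; the cascade keeps candidates that are plausibly
bioavailable, brain-penetrant and disease-linked:

mass in (100, 900) Da  ->  water solubility > 1 uM  ->  predicted BBB
penetration > 50%  ->  plasma concentration > 0.5 nM  ->  >= 2 literature
references linking the compound to Alzheimer's disease  ->  exclusion of
fatty acids (HSA's native cargo, screened elsewhere).

"Above"/"exceeding"/"less than" thresholds are strict inequalities;
"more than 1 reference" means >= 2. The final survivor set is a conjunction
of independent predicates, hence independent of stage order; the per-stage
survivor counts reported here follow the fixed order above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LigandRecord",
    "FilterThresholds",
    "FilterReport",
    "RecordValidationError",
    "apply_filters",
    "read_ligand_table",
    "write_ligand_table",
    "STAGE_NAMES",
]

#: Fixed stage order used for per-stage survivor counts.
STAGE_NAMES: tuple[str, ...] = (
    "mass",
    "solubility",
    "bbb",
    "plasma",
    "refs",
    "fatty_acid",
)


class RecordValidationError(ValueError):
    """A ligand record is missing or violates a required attribute."""

    def __init__(self, ligand_id: str, field_name: str, message: str):
        self.ligand_id = ligand_id
        self.field_name = field_name
        super().__init__(f"record {ligand_id!r}, field {field_name!r}: {message}")


@dataclass(frozen=True)
class LigandRecord:
    """One drug candidate with the six filterable attributes.

    ``solubility`` stores the precedence-resolved value: experimental
    solubility, where measured, supersedes the predicted one upstream of
    this container.

    Parameters
    ----------
    id : opaque identifier (e.g. a DrugBank-style accession).
    name : human-readable compound name.
    mass : molecular mass, Da.
    solubility : water solubility, uM.
    bbb_penetration : predicted blood-brain-barrier penetration, percent.
    plasma_conc : plasma concentration, nM.
    ad_refs : number of Alzheimer's-disease literature references.
    is_fatty_acid : fatty-acid flag.
    """

    id: str
    name: str
    mass: float
    solubility: float
    bbb_penetration: float
    plasma_conc: float
    ad_refs: int
    is_fatty_acid: bool

    def validate(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) is None:
                raise RecordValidationError(self.id, f.name, "missing value")
        if not self.mass > 0:
            raise RecordValidationError(self.id, "mass", "must be positive")
        if self.solubility < 0:
            raise RecordValidationError(self.id, "solubility", "must be >= 0")
        if not 0.0 <= self.bbb_penetration <= 100.0:
            raise RecordValidationError(
                self.id, "bbb_penetration", "must be in [0, 100]"
            )
        if self.plasma_conc < 0:
            raise RecordValidationError(self.id, "plasma_conc", "must be >= 0")
        if self.ad_refs < 0:
            raise RecordValidationError(self.id, "ad_refs", "must be >= 0")


@dataclass(frozen=True)
class FilterThresholds:
    """Cascade thresholds; strict bounds unless noted.

    ``refs_min`` is inclusive ("more than 1 reference" = at least 2).
    """

    mass_min: float = 100.0  # Da, exclusive
    mass_max: float = 900.0  # Da, exclusive
    solubility_min: float = 1.0  # uM, exclusive
    bbb_min: float = 50.0  # percent, exclusive
    plasma_min: float = 0.5  # nM, exclusive
    refs_min: int = 2  # inclusive
    exclude_fatty_acids: bool = True

    def __post_init__(self) -> None:
        if not self.mass_min < self.mass_max:
            raise ValueError("mass_min must be < mass_max")
        for name in ("mass_min", "solubility_min", "bbb_min", "plasma_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def predicate(self, stage: str):
        """Return the pass predicate for a named stage."""
        preds = {
            "mass": lambda r: self.mass_min < r.mass < self.mass_max,
            "solubility": lambda r: r.solubility > self.solubility_min,
            "bbb": lambda r: r.bbb_penetration > self.bbb_min,
            "plasma": lambda r: r.plasma_conc > self.plasma_min,
            "refs": lambda r: r.ad_refs >= self.refs_min,
            "fatty_acid": lambda r: not (self.exclude_fatty_acids and r.is_fatty_acid),
        }
        return preds[stage]


@dataclass
class FilterReport:
    """Per-stage survivor counts plus the final passing identifiers."""

    stage_names: tuple[str, ...]
    survivors_after_stage: list[int]
    passing_ids: list[str] = field(default_factory=list)
    n_input: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "stage_names": list(self.stage_names),
            "survivors_after_stage": list(self.survivors_after_stage),
            "passing_ids": list(self.passing_ids),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def apply_filters(
    records: Iterable[LigandRecord],
    thr: FilterThresholds | None = None,
    stage_order: Sequence[str] = STAGE_NAMES,
) -> FilterReport:
    """Run the cascade and report survivors after each stage.

    Records are validated first; a missing/invalid attribute raises
    :class:`RecordValidationError` naming the record and field rather than
    being silently dropped (the screen must stay auditable).
    """
    thr = thr if thr is not None else FilterThresholds()
    if sorted(stage_order) != sorted(STAGE_NAMES):
        raise ValueError(f"stage_order must be a permutation of {STAGE_NAMES}")
    survivors = list(records)
    for rec in survivors:
        rec.validate()
    n_input = len(survivors)
    counts: list[int] = []
    for stage in stage_order:
        pred = thr.predicate(stage)
        survivors = [r for r in survivors if pred(r)]
        counts.append(len(survivors))
    return FilterReport(
        stage_names=tuple(stage_order),
        survivors_after_stage=counts,
        passing_ids=[r.id for r in survivors],
        n_input=n_input,
    )


_CSV_COLUMNS = [
    "id",
    "name",
    "mass_da",
    "solubility_uM",
    "bbb_percent",
    "plasma_nM",
    "ad_refs",
    "is_fatty_acid",
]


def write_ligand_table(records: Sequence[LigandRecord], path: str | Path) -> None:
    """Write records as CSV with the documented header (units in names)."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "name": [r.name for r in records],
            "mass_da": [r.mass for r in records],
            "solubility_uM": [r.solubility for r in records],
            "bbb_percent": [r.bbb_penetration for r in records],
            "plasma_nM": [r.plasma_conc for r in records],
            "ad_refs": [r.ad_refs for r in records],
            "is_fatty_acid": [r.is_fatty_acid for r in records],
        },
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_ligand_table(path: str | Path) -> list[LigandRecord]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ligand table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            LigandRecord(
                id=str(row.id),
                name=str(row.name),
                mass=float(row.mass_da),
                solubility=float(row.solubility_uM),
                bbb_penetration=float(row.bbb_percent),
                plasma_conc=float(row.plasma_nM),
                ad_refs=int(row.ad_refs),
                is_fatty_acid=bool(row.is_fatty_acid),
            )
        )
    return out
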