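"""Toxicity data model, CSV I/O and species-level aggregation.

The package works with acute toxicity records (LC50/EC50) for aquatic
species exposed to microplastics.  Concentrations are carried internally in
μg/L; tables recorded in mg/L are converted on load (× 1000).  Species-level
values are geometric means of the per-test concentrations, the conventional
aggregate for skewed toxicity data.

Two curated tables ship with the package:

``table1_measured.csv``
    Eleven measured acute values (one test per species) spanning five phyla:
    cladocerans, an anostracan, a copepod, an amphipod, two fish, two green
    algae, a luminescent bacterium and a sea-urchin.  The printed source
    gives only phylum, family and species; genus, order and class were
    completed from standard taxonomy (WoRMS/ITIS usage) so that full rank
    paths are available for taxonomic-distance work.

``table2_ice_predicted.csv``
    Nineteen toxicity values predicted by surrogate-to-species interspecies
    correlation models (surrogates: *Oncorhynchus mykiss*, *Hyalella
    azteca*, *Daphnia magna*) together with the published model diagnostics
    (cross-validation success %, MSE, R², taxonomic distance).  The values
    are stored exactly as printed and are read as μg/L by default: the
    μg/L reading is the only one consistent with the surrogate seed values
    and with the derived hazardous concentrations, whose HC5 sits just
    below the smallest predicted value.  Genus/order/class ranks were
    likewise completed from standard taxonomy.
"""

from __future__ import annotations

import json
import math
import unicodedata
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError, UnitError, ValidationError

__all__ = [
    "Taxonomy",
    "ToxicityRecord",
    "SpeciesToxicity",
    "load_toxicity_table",
    "geometric_mean_by_species",
    "export_species_csv",
    "export_species_json",
    "table1_path",
    "table2_path",
    "load_table1",
    "load_table2",
]

ENDPOINTS = frozenset({"LC50", "EC50"})
EFFECTS = frozenset({"mortality", "immobility", "respiratory_inhibition"})
#: acute exposure durations (hours): 48 h for daphniids, 96 h for all others
DAPHNIID_DURATION_H = 48.0
DEFAULT_DURATION_H = 96.0

REQUIRED_COLUMNS = (
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "endpoint",
    "effect",
    "duration_h",
    "concentration",
    "source_ref",
)

_UNIT_FACTORS = {"ugL": 1.0, "mgL": 1000.0}


def normalize_name(name: str) -> str:
    """Canonical form used for species matching: trimmed, case-folded,
    internal whitespace collapsed.  No fuzzy resolution is attempted."""
    return " ".join(unicodedata.normalize("NFKC", str(name)).split()).casefold()


@dataclass(frozen=True)
class Taxonomy:
    """Rank path of a species from genus up to phylum.

    Empty strings mark unknown ranks; they are tolerated everywhere except
    in taxonomic-distance computation, which needs the full path.
    """

    species: str
    genus: str = ""
    family: str = ""
    order: str = ""
    class_: str = ""
    phylum: str = ""

    def rank(self, name: str) -> str:
        return getattr(self, "class_" if name == "class" else name)


@dataclass(frozen=True)
class ToxicityRecord:
    """One species × one acute test result, concentration in μg/L."""

    species_name: str
    taxonomy: Taxonomy
    endpoint: str
    effect: str
    duration_h: float
    concentration: float
    source_ref: str = ""

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(
                f"unknown endpoint {self.endpoint!r} for {self.species_name!r}"
            )
        if self.effect not in EFFECTS:
            raise ValidationError(
                f"unknown effect {self.effect!r} for {self.species_name!r}"
            )
        if not (math.isfinite(self.concentration) and self.concentration > 0):
            raise ValidationError(
                f"concentration must be positive and finite, got "
                f"{self.concentration!r} for {self.species_name!r}"
            )


@dataclass(frozen=True)
class SpeciesToxicity:
    """Species-level aggregate: geometric mean of its records, in μg/L."""

    species_name: str
    taxonomy: Taxonomy
    value_ugL: float
    n_records: int = 1
    log10_value: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value_ugL) and self.value_ugL > 0):
            raise ValidationError(
                f"value_ugL must be positive and finite, got {self.value_ugL!r}"
            )
        if self.log10_value is None:
            object.__setattr__(self, "log10_value", math.log10(self.value_ugL))
        elif not math.isclose(self.log10_value, math.log10(self.value_ugL),
                              rel_tol=0, abs_tol=1e-9):
            raise ValidationError(
                f"log10_value {self.log10_value!r} inconsistent with "
                f"value_ugL {self.value_ugL!r}"
            )


def _expected_duration(taxonomy: Taxonomy) -> float:
    if normalize_name(taxonomy.family) == "daphniidae":
        return DAPHNIID_DURATION_H
    return DEFAULT_DURATION_H


def load_toxicity_table(
    path: str | Path,
    unit: str | None = None,
    validate_duration: bool = True,
) -> list[ToxicityRecord]:
    """Read a toxicity table CSV into validated records.

    Parameters
    ----------
    path
        CSV with header columns ``species, genus, family, order, class,
        phylum, endpoint, effect, duration_h, concentration, source_ref``
        and optionally ``unit`` (per-row ``ugL``/``mgL``).
    unit
        ``"ugL"`` or ``"mgL"``.  When given it applies to every row,
        overriding any ``unit`` column; when ``None`` the per-row column is
        used (and must be present).  All output concentrations are in μg/L.
    validate_duration
        Enforce the acute-duration convention (48 h for daphniids, 96 h
        otherwise).

    Returns
    -------
    list of ToxicityRecord, in file row order.
    """
    path = Path(path)
    if unit is not None and unit not in _UNIT_FACTORS:
        raise UnitError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_FACTORS)}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    if unit is None and "unit" not in df.columns:
        raise UnitError(
            f"{path.name}: no 'unit' column and no unit argument given"
        )

    records: list[ToxicityRecord] = []
    for idx, row in enumerate(df.to_dict("records"), start=2):  # header = line 1
        raw = row["concentration"].strip()
        try:
            conc = float(raw)
        except ValueError:
            raise ValidationError(
                f"{path.name} line {idx}: concentration {raw!r} is not numeric"
            ) from None
        if not (math.isfinite(conc) and conc > 0):
            raise ValidationError(
                f"{path.name} line {idx}: concentration must be positive, got {raw!r}"
            )
        row_unit = unit if unit is not None else row.get("unit", "").strip()
        if row_unit not in _UNIT_FACTORS:
            raise UnitError(
                f"{path.name} line {idx}: unknown unit {row_unit!r}"
            )
        conc_ugL = conc * _UNIT_FACTORS[row_unit]
        try:
            duration = float(row["duration_h"])
        except ValueError:
            raise ValidationError(
                f"{path.name} line {idx}: duration_h {row['duration_h']!r} "
                "is not numeric"
            ) from None
        taxonomy = Taxonomy(
            species=row["species"].strip(),
            genus=row["genus"].strip(),
            family=row["family"].strip(),
            order=row["order"].strip(),
            class_=row["class"].strip(),
            phylum=row["phylum"].strip(),
        )
        if validate_duration and duration != _expected_duration(taxonomy):
            raise ValidationError(
                f"{path.name} line {idx}: acute duration for "
                f"{taxonomy.species!r} must be "
                f"{_expected_duration(taxonomy):.0f} h, got {duration:g}"
            )
        try:
            records.append(
                ToxicityRecord(
                    species_name=taxonomy.species,
                    taxonomy=taxonomy,
                    endpoint=row["endpoint"].strip(),
                    effect=row["effect"].strip(),
                    duration_h=duration,
                    concentration=conc_ugL,
                    source_ref=row["source_ref"].strip(),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path.name} line {idx}: {exc}") from None
    return records


def geometric_mean_by_species(
    records: Iterable[ToxicityRecord],
) -> list[SpeciesToxicity]:
    """Aggregate records to one geometric-mean value per species.

    Species are matched by normalized name (trim + case-fold); the display
    name and taxonomy of the first record seen are kept.  Output is sorted
    ascending by value, which is the order SSD construction expects.
    """
    groups: dict[str, list[ToxicityRecord]] = {}
    for rec in records:
        groups.setdefault(normalize_name(rec.species_name), []).append(rec)
    out = []
    for recs in groups.values():
        if len(recs) == 1:  # exact: gmean of one value is that value
            value = recs[0].concentration
        else:
            value = float(np.exp(np.log([r.concentration for r in recs]).mean()))
        out.append(
            SpeciesToxicity(
                species_name=recs[0].species_name,
                taxonomy=recs[0].taxonomy,
                value_ugL=value,
                n_records=len(recs),
            )
        )
    out.sort(key=lambda s: s.value_ugL)
    return out


def _species_frame(species: Sequence[SpeciesToxicity]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [s.species_name for s in species],
            "value_ugL": [s.value_ugL for s in species],
            "log10_value": [s.log10_value for s in species],
            "n_records": [s.n_records for s in species],
        }
    )


def export_species_csv(species: Sequence[SpeciesToxicity], path: str | Path) -> None:
    _species_frame(species).to_csv(path, index=False)


def export_species_json(species: Sequence[SpeciesToxicity], path: str | Path) -> None:
    payload = [{**asdict(s), "taxonomy": asdict(s.taxonomy)} for s in species]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _data_path(name: str) -> Path:
    return Path(resources.files("icessd") / "data" / name)


def table1_path() -> Path:
    """Path of the bundled measured-toxicity table (11 species)."""
    return _data_path("table1_measured.csv")


def table2_path() -> Path:
    """Path of the bundled ICE-predicted table (19 species + diagnostics)."""
    return _data_path("table2_ice_predicted.csv")


def load_table1() -> list[ToxicityRecord]:
    """The 11 measured acute records."""
    return load_toxicity_table(table1_path())


def load_table2(unit: str = "ugL") -> list[ToxicityRecord]:
    """The 19 ICE-predicted records (values read as μg/L by default)."""
    return load_toxicity_table(table2_path(), unit=unit)
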