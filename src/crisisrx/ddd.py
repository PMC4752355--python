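"""Defined-daily-dose (DDD) drug-utilization measures.

Two monthly consumption outcomes are derived from dispensing records:

* ``n_drugs`` — the number of *distinct* active substances dispensed to an
  individual in a calendar month (a proxy for severity of the disorder:
  treatments tried in combination or in succession);
* ``ddd`` — the total defined daily doses dispensed that month (a proxy for
  intensity of treatment), where for each record

      DDD = n_packs x units_per_pack x amount_per_unit / DDD_ATC

  and ``DDD_ATC`` is the WHO ATC index's defined daily dose for the
  substance.  Amounts are in mg on both sides so units cancel.

The panel covers consumers only: (individual, month) pairs with no dispensing
records simply have no row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ANXIOLYTICS",
    "ANTIDEPRESSANTS",
    "PrescriptionRecord",
    "DDDRegistry",
    "load_default_registry",
    "classify",
    "ddd_for_prescription",
    "aggregate_monthly",
    "ClassificationError",
    "RegistryLookupError",
]

#: benzodiazepine anxiolytics covered by the pipeline
ANXIOLYTICS = ("alprazolam", "clorazepate", "clonazepam", "diazepam", "lorazepam")
#: SSRI/SNRI antidepressants covered by the pipeline
ANTIDEPRESSANTS = (
    "citalopram",
    "escitalopram",
    "fluoxetine",
    "paroxetine",
    "sertraline",
    "venlafaxine",
)

_CLASS = {s: "anxiolytic" for s in ANXIOLYTICS}
_CLASS.update({s: "antidepressant" for s in ANTIDEPRESSANTS})


class ClassificationError(KeyError):
    """Substance outside the anxiolytic/antidepressant vocabulary."""


class RegistryLookupError(KeyError):
    """Substance has no entry in the DDD registry."""


@dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensing event: who, when, what and how much."""

    individual_id: int
    month: int
    substance: str
    atc_code: str = ""
    n_packs: int = 1
    units_per_pack: int = 1
    amount_per_unit_mg: float = 1.0

    def __post_init__(self):
        if self.n_packs < 0:
            raise ValueError("n_packs must be >= 0")
        if self.units_per_pack <= 0:
            raise ValueError("units_per_pack must be > 0")
        if self.amount_per_unit_mg <= 0:
            raise ValueError("amount_per_unit_mg must be > 0")


class DDDRegistry:
    """ATC DDD reference registry: substance -> defined daily dose (mg).

    Registry values are configuration inputs loaded from an editable CSV
    (``atc_code, substance, ddd_amount_mg, version``), never hard-coded.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"atc_code", "substance", "ddd_amount_mg", "version"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"registry table missing columns {sorted(missing)}")
        if (table["ddd_amount_mg"] <= 0).any():
            raise ValueError("registry ddd_amount_mg values must be positive")
        self.table = table.reset_index(drop=True)
        self._ddd = dict(zip(table["substance"], table["ddd_amount_mg"].astype(float)))
        self._atc = dict(zip(table["substance"], table["atc_code"]))

    @property
    def version(self) -> str:
        return str(self.table["version"].iloc[0])

    def __contains__(self, substance: str) -> bool:
        return substance in self._ddd

    def ddd_amount(self, substance: str) -> float:
        try:
            return self._ddd[substance]
        except KeyError:
            raise RegistryLookupError(
                f"substance {substance!r} not in DDD registry (version {self.version})"
            ) from None

    def atc_code(self, substance: str) -> str:
        return self._atc[substance]

    @classmethod
    def from_csv(cls, path) -> "DDDRegistry":
        return cls(pd.read_csv(path))


def load_default_registry() -> DDDRegistry:
    """Bundled WHO ATC DDD values for the 11 study substances."""
    with resources.files("crisisrx.data").joinpath("ddd_registry.csv").open() as fh:
        return DDDRegistry(pd.read_csv(fh))


def classify(substance: str) -> str:
    """Return ``'anxiolytic'`` or ``'antidepressant'`` for a study substance."""
    try:
        return _CLASS[substance]
    except KeyError:
        raise ClassificationError(
            f"substance {substance!r} is neither a study anxiolytic nor antidepressant"
        ) from None


def ddd_for_prescription(rx: PrescriptionRecord, registry: DDDRegistry) -> float:
    """DDDs dispensed by a single record: packs x units x mg/unit / DDD_ATC."""
    ddd_amount = registry.ddd_amount(rx.substance)
    return rx.n_packs * rx.units_per_pack * rx.amount_per_unit_mg / ddd_amount


def _ddd_column(prescriptions: pd.DataFrame, registry: DDDRegistry) -> pd.Series:
    unknown = set(prescriptions["substance"]) - set(registry._ddd)
    if unknown:
        raise RegistryLookupError(
            f"substances {sorted(unknown)} not in DDD registry (version {registry.version})"
        )
    denom = prescriptions["substance"].map(registry._ddd)
    return (
        prescriptions["n_packs"]
        * prescriptions["units_per_pack"]
        * prescriptions["amount_per_unit_mg"]
        / denom
    )


def aggregate_monthly(
    prescriptions: pd.DataFrame,
    registry: DDDRegistry | None = None,
    by_class: bool = False,
) -> pd.DataFrame:
    """Aggregate dispensing records to (individual, month) consumption rows.

    Returns a frame with ``individual_id, month, n_drugs, ddd`` (plus
    per-class columns when ``by_class``).  ``n_drugs`` counts distinct
    substances; ``ddd`` sums DDDs over all records of the month.  Months with
    no records are absent.  Exact duplicate records are summed, not
    deduplicated (logged).
    """
    if registry is None:
        registry = load_default_registry()
    cols = ["individual_id", "month", "substance", "n_packs", "units_per_pack", "amount_per_unit_mg"]
    if prescriptions.empty:
        out = pd.DataFrame(columns=["individual_id", "month", "n_drugs", "ddd"])
        if by_class:
            for c in ("anxiolytic", "antidepressant"):
                out[f"n_drugs_{c}"] = []
                out[f"ddd_{c}"] = []
        return out
    rx = prescriptions[cols].copy()
    n_dup = int(rx.duplicated().sum())
    if n_dup:
        logger.warning("aggregate_monthly: %d exact duplicate records summed, not deduplicated", n_dup)
    rx["ddd"] = _ddd_column(rx, registry)
    key = ["individual_id", "month"]
    out = (
        rx.groupby(key)
        .agg(n_drugs=("substance", "nunique"), ddd=("ddd", "sum"))
        .reset_index()
    )
    if by_class:
        rx["drug_class"] = rx["substance"].map(_CLASS)
        per = (
            rx.groupby(key + ["drug_class"])
            .agg(n=("substance", "nunique"), d=("ddd", "sum"))
            .unstack("drug_class")
        )
        for c in ("anxiolytic", "antidepressant"):
            n = per["n"][c] if c in per["n"] else pd.Series(index=per.index, dtype=float)
            d = per["d"][c] if c in per["d"] else pd.Series(index=per.index, dtype=float)
            out = out.merge(
                pd.DataFrame({f"n_drugs_{c}": n.fillna(0).astype(int), f"ddd_{c}": d.fillna(0.0)}),
                left_on=key,
                right_index=True,
                how="left",
            )
    return out.sort_values(key).reset_index(drop=True)
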