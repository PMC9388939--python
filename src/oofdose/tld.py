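"""TLD dose reduction: raw reading -> air kerma -> tissue dose, with
the quadrature uncertainty budget.

The reduction chain for each dosimeter is

    K_air = RD * Ecc * f_Q * f_fad * f_E * f_alpha / RCF

(raw reading times element correction coefficient and the reader
stability / fading / energy / angular correction factors, divided by
the reader calibration factor), followed by, under electronic
equilibrium,

    D_tissue = K_air * (muen/rho)_tissue / (muen/rho)_air

with both mass energy-absorption coefficients taken at 6 MeV.  Fading
and angular corrections default to 1 (readout immediately after
irradiation; no angular dependence at these energies).

The measurement uncertainty budget combines four components in
quadrature at k = 1: element correction coefficient 3.0%, reader
stability 3.8%, reader calibration factor 15.0%, energy dependence
1.4% (a rectangular-distribution component stored already divided by
sqrt(3)), giving 15.8%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .materials import get_material
from .reference import ORGAN_MUEN_6MEV

__all__ = [
    "TLDRecord",
    "UncertaintyBudget",
    "OrganDoseMeasurement",
    "default_uncertainty_budget",
    "kerma_from_reading",
    "tissue_dose",
    "organ_mean",
    "combine_uncertainty",
    "reduce_readings",
    "read_tld_table",
    "write_tld_table",
    "air_muen_6mev",
    "CONVERSION_ENERGY_MEV",
]

CONVERSION_ENERGY_MEV = 6.0


@dataclass(frozen=True)
class TLDRecord:
    """One dosimeter's raw reading and its calibration factors."""

    dosimeter_id: str
    organ: str
    technique: str  # "3DCRT" | "IMRT"
    rd: float  # raw reading, reader units
    ecc: float = 1.0  # element correction coefficient
    f_q: float = 1.0  # reader stability
    f_fad: float = 1.0  # fading (readout immediately after irradiation)
    f_e: float = 1.0  # energy dependence
    f_alpha: float = 1.0  # angular dependence
    rcf: float = 1.0  # reader calibration factor, reader units per mGy

    def __post_init__(self) -> None:
        if self.rd < 0:
            raise ValueError(f"{self.dosimeter_id}: negative raw reading")
        if self.rcf <= 0:
            raise ValueError(f"{self.dosimeter_id}: RCF must be positive")
        for name in ("ecc", "f_q", "f_fad", "f_e", "f_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.dosimeter_id}: {name} must be positive")


@dataclass(frozen=True)
class UncertaintyBudget:
    """Component standard uncertainties (%, k = 1) with distribution tags.

    Components are stored as *standard* uncertainties: a rectangular
    component has already been divided by sqrt(3); its tag documents
    the assumed distribution, it does not change the quadrature.
    """

    components: tuple[tuple[str, float, str], ...]

    def __post_init__(self) -> None:
        for name, u, dist in self.components:
            if u < 0:
                raise ValueError(f"component {name}: negative uncertainty")
            if dist not in ("normal", "rectangular"):
                raise ValueError(f"component {name}: unknown distribution {dist!r}")

    def combined_percent(self) -> float:
        """Quadrature combination, % at k = 1."""
        return combine_uncertainty(self)

    def combined_relative(self, ndigits: int = 1) -> float:
        """Combined uncertainty as a fraction, rounded to the reporting
        precision (0.1% by default, i.e. 15.824% -> 0.158).  This is
        the factor the reported per-organ SD is formed with."""
        return round(self.combined_percent(), ndigits) / 100.0


def default_uncertainty_budget() -> UncertaintyBudget:
    return UncertaintyBudget(
        components=(
            ("element correction coefficient", 3.0, "normal"),
            ("reader stability", 3.8, "normal"),
            ("reader calibration factor", 15.0, "normal"),
            ("energy dependence", 1.4, "rectangular"),
        )
    )


def combine_uncertainty(budget: UncertaintyBudget) -> float:
    """Root-sum-square of the component standard uncertainties, %."""
    if not budget.components:
        raise ValueError("budget has no components")
    return math.sqrt(sum(u * u for _, u, _ in budget.components))


@dataclass(frozen=True)
class OrganDoseMeasurement:
    organ: str
    technique: str
    mean_dose_mgy: float
    sd_mgy: float
    n_dosimeters: int

    def __post_init__(self) -> None:
        if self.n_dosimeters < 1:
            raise ValueError("need at least one dosimeter")
        if self.sd_mgy < 0:
            raise ValueError("negative SD")


def kerma_from_reading(record: TLDRecord) -> float:
    """Air kerma in mGy from a raw TLD reading."""
    return (
        record.rd
        * record.ecc
        * record.f_q
        * record.f_fad
        * record.f_e
        * record.f_alpha
        / record.rcf
    )


def air_muen_6mev() -> float:
    """Packaged air mass energy-absorption coefficient at 6 MeV, cm^2/g."""
    return get_material("air").muen(CONVERSION_ENERGY_MEV)


def tissue_dose(k_air: float, organ: str, coefficient_source=None) -> float:
    """Convert air kerma (mGy) to organ tissue dose (mGy) at 6 MeV.

    ``coefficient_source`` maps organ name -> muen/rho (cm^2/g at
    6 MeV); the default is the measured-campaign organ table
    (soft-tissue organs 0.0179, thyroid 0.0194).
    """
    coeffs = ORGAN_MUEN_6MEV if coefficient_source is None else coefficient_source
    try:
        muen_tissue = coeffs[organ]
    except KeyError:
        raise KeyError(f"no 6 MeV coefficient for organ {organ!r}") from None
    return k_air * muen_tissue / air_muen_6mev()


def organ_mean(
    records: list[TLDRecord],
    budget: UncertaintyBudget | None = None,
    coefficient_source=None,
) -> OrganDoseMeasurement:
    """Average the per-dosimeter tissue doses of one organ/technique.

    The reported SD is ``mean x combined relative uncertainty`` (the
    budget's quadrature at k = 1, at reporting precision), matching the
    convention of the reference campaign's summary table.
    """
    if not records:
        raise ValueError("no records")
    organs = {r.organ for r in records}
    techniques = {r.technique for r in records}
    if len(organs) != 1 or len(techniques) != 1:
        raise ValueError(f"records mix organs/techniques: {organs}, {techniques}")
    budget = budget or default_uncertainty_budget()
    doses = [tissue_dose(kerma_from_reading(r), r.organ, coefficient_source) for r in records]
    mean = float(np.mean(doses))
    return OrganDoseMeasurement(
        organ=organs.pop(),
        technique=techniques.pop(),
        mean_dose_mgy=mean,
        sd_mgy=mean * budget.combined_relative(),
        n_dosimeters=len(records),
    )


def reduce_readings(
    records: list[TLDRecord],
    budget: UncertaintyBudget | None = None,
    coefficient_source=None,
) -> list[OrganDoseMeasurement]:
    """Group records by (technique, organ) and reduce each group."""
    groups: dict[tuple[str, str], list[TLDRecord]] = {}
    for r in records:
        groups.setdefault((r.technique, r.organ), []).append(r)
    return [organ_mean(g, budget, coefficient_source) for g in groups.values()]


_TLD_COLUMNS = ["dosimeter_id", "organ", "technique", "rd", "ecc",
                "f_q", "f_fad", "f_e", "f_alpha", "rcf"]


def read_tld_table(path_or_buffer) -> list[TLDRecord]:
    df = pd.read_csv(path_or_buffer, sep="\t")
    missing = [c for c in _TLD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TLD table missing columns: {missing}")
    return [
        TLDRecord(
            dosimeter_id=str(row["dosimeter_id"]),
            organ=str(row["organ"]),
            technique=str(row["technique"]),
            rd=float(row["rd"]),
            ecc=float(row["ecc"]),
            f_q=float(row["f_q"]),
            f_fad=float(row["f_fad"]),
            f_e=float(row["f_e"]),
            f_alpha=float(row["f_alpha"]),
            rcf=float(row["rcf"]),
        )
        for _, row in df.iterrows()
    ]


def write_tld_table(records: list[TLDRecord], path=None) -> str:
    df = pd.DataFrame(
        [
            {c: getattr(r, c) for c in _TLD_COLUMNS}
            for r in records
        ]
    )
    text = df.to_csv(sep="\t", index=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
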