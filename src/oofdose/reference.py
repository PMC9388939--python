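"""Reference data for the pediatric brain case this package studies.

A 5-year-old anthropomorphic phantom received a 54 Gy course
(1.8 Gy x 30 fractions) to an elliptical PTV in the right hemisphere
of the brain, delivered once with a six-field non-coplanar 3DCRT plan
and once with a seven-field coplanar sliding-window IMRT plan on a
6 MV linac.  Out-of-field organ doses were measured with TLDs placed
in the physical phantom.

This module records the published campaign summary: PTV-to-organ
center distances, the measured per-organ mean doses for both
techniques, the TLD layout (dosimeters per organ) and the 6 MeV mass
energy-absorption coefficients used in the measurement reduction.
These numbers are *inputs* to the synthetic-data generator and the
comparison stage, never outputs of the simulator.
"""

from __future__ import annotations

__all__ = [
    "ORGAN_DISTANCES_CM",
    "OUT_OF_FIELD_ORGANS",
    "MEASURED_MEAN_DOSE_MGY",
    "MEASURED_SD_MGY",
    "TLD_COUNTS",
    "ORGAN_MUEN_6MEV",
    "PRESCRIBED_DOSE_GY",
    "DOSE_PER_FRACTION_GY",
    "N_FRACTIONS",
]

# PTV geometric center to organ geometric center, cm.
ORGAN_DISTANCES_CM: dict[str, float] = {
    "right eye": 6.2,
    "left eye": 8.4,
    "c-spine": 11.1,
    "thyroid": 13.1,
    "right lung": 21.7,
    "heart": 22.2,
    "left lung": 23.3,
}

# Sorted by distance from the PTV center.
OUT_OF_FIELD_ORGANS: tuple[str, ...] = tuple(
    sorted(ORGAN_DISTANCES_CM, key=ORGAN_DISTANCES_CM.get)
)

# Mean organ dose measured by TLDs over the full 54 Gy course, mGy.
MEASURED_MEAN_DOSE_MGY: dict[str, dict[str, float]] = {
    "3DCRT": {
        "right eye": 593.0,
        "left eye": 475.2,
        "c-spine": 180.9,
        "thyroid": 69.7,
        "right lung": 28.0,
        "heart": 25.2,
        "left lung": 19.8,
    },
    "IMRT": {
        "right eye": 13040.6,
        "left eye": 6525.3,
        "c-spine": 182.3,
        "thyroid": 79.4,
        "right lung": 37.4,
        "heart": 30.6,
        "left lung": 27.1,
    },
}

# Reported spread (mGy) accompanying each measured mean; equals the
# mean times the combined relative measurement uncertainty (15.8%).
MEASURED_SD_MGY: dict[str, dict[str, float]] = {
    "3DCRT": {
        "right eye": 93.7,
        "left eye": 75.1,
        "c-spine": 28.6,
        "thyroid": 11.0,
        "right lung": 4.4,
        "heart": 4.0,
        "left lung": 3.1,
    },
    "IMRT": {
        "right eye": 2060.4,
        "left eye": 1031.0,
        "c-spine": 28.8,
        "thyroid": 12.5,
        "right lung": 5.9,
        "heart": 4.8,
        "left lung": 4.3,
    },
}

# TLDs per organ in each technique's group (38 dosimeters per group).
TLD_COUNTS: dict[str, int] = {
    "right eye": 1,
    "left eye": 1,
    "c-spine": 2,
    "thyroid": 4,
    "heart": 2,
    "right lung": 12,
    "left lung": 16,
}

# Mass energy-absorption coefficient used in the kerma-to-tissue-dose
# conversion, cm^2/g at 6 MeV.
ORGAN_MUEN_6MEV: dict[str, float] = {
    "right eye": 0.0179,
    "left eye": 0.0179,
    "c-spine": 0.0179,
    "thyroid": 0.0194,
    "heart": 0.0179,
    "right lung": 0.0179,
    "left lung": 0.0179,
}

PRESCRIBED_DOSE_GY = 54.0
DOSE_PER_FRACTION_GY = 1.8
N_FRACTIONS = int(round(PRESCRIBED_DOSE_GY / DOSE_PER_FRACTION_GY))
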