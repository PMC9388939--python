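"""Comparison statistics between dose sources and between techniques.

Relative differences follow the measurement-as-gold-standard
convention ``|calculation - measurement| / measurement x 100``;
technique comparisons report per-organ IMRT/3DCRT dose ratios together
with their arithmetic mean, both always printed so the averaging
convention behind any headline factor is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import VoxelPhantom, organ_distance, PTV_NAME

__all__ = [
    "ComparisonReport",
    "relative_difference",
    "technique_ratio_table",
    "compare_sources",
    "dose_vs_distance",
    "plot_dose_vs_distance",
]


@dataclass
class ComparisonReport:
    """Per-organ paired doses with relative differences and ratios."""

    label_a: str
    label_b: str
    organs: list[str]
    dose_a: dict[str, float]
    dose_b: dict[str, float]
    relative_difference_pct: dict[str, float]
    ratio: dict[str, float]

    @property
    def mean_relative_difference_pct(self) -> float:
        return float(np.mean([self.relative_difference_pct[o] for o in self.organs]))

    @property
    def mean_ratio(self) -> float:
        return float(np.mean([self.ratio[o] for o in self.organs]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "organ": self.organs,
                self.label_a: [self.dose_a[o] for o in self.organs],
                self.label_b: [self.dose_b[o] for o in self.organs],
                "relative_difference_pct": [self.relative_difference_pct[o] for o in self.organs],
                "ratio": [self.ratio[o] for o in self.organs],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "label_a": self.label_a,
                "label_b": self.label_b,
                "organs": self.organs,
                "dose_a": self.dose_a,
                "dose_b": self.dose_b,
                "relative_difference_pct": self.relative_difference_pct,
                "ratio": self.ratio,
                "mean_relative_difference_pct": self.mean_relative_difference_pct,
                "mean_ratio": self.mean_ratio,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        d = json.loads(text)
        return cls(
            label_a=d["label_a"],
            label_b=d["label_b"],
            organs=d["organs"],
            dose_a=d["dose_a"],
            dose_b=d["dose_b"],
            relative_difference_pct=d["relative_difference_pct"],
            ratio=d["ratio"],
        )


def relative_difference(calculation: float, measurement: float) -> float:
    """``|calculation - measurement| / measurement x 100`` (percent).

    The measurement is the gold standard and must be positive.
    """
    if measurement <= 0:
        raise ValueError("measurement must be positive for a relative difference")
    return abs(calculation - measurement) / measurement * 100.0


def compare_sources(
    doses_a: dict[str, float],
    doses_b: dict[str, float],
    label_a: str = "calculation",
    label_b: str = "measurement",
) -> ComparisonReport:
    """Pair two per-organ dose tables (a = calculation, b = reference)."""
    only_a = sorted(set(doses_a) - set(doses_b))
    only_b = sorted(set(doses_b) - set(doses_a))
    if only_a or only_b:
        raise ValueError(
            f"organ sets differ: only in {label_a}: {only_a}; only in {label_b}: {only_b}"
        )
    organs = list(doses_a)
    return ComparisonReport(
        label_a=label_a,
        label_b=label_b,
        organs=organs,
        dose_a={o: float(doses_a[o]) for o in organs},
        dose_b={o: float(doses_b[o]) for o in organs},
        relative_difference_pct={o: relative_difference(doses_a[o], doses_b[o]) for o in organs},
        ratio={o: doses_a[o] / doses_b[o] for o in organs},
    )


def technique_ratio_table(
    doses_imrt: dict[str, float], doses_3dcrt: dict[str, float]
) -> ComparisonReport:
    """Per-organ IMRT/3DCRT ratios plus the arithmetic mean ratio."""
    return compare_sources(doses_imrt, doses_3dcrt, label_a="IMRT", label_b="3DCRT")


def dose_vs_distance(
    doses: dict[str, float],
    phantom: VoxelPhantom | None = None,
    distances: dict[str, float] | None = None,
    reference_organ: str = PTV_NAME,
) -> pd.DataFrame:
    """Table of (organ, distance cm, dose mGy) sorted by distance.

    Distances come either from a phantom (voxel-centroid distance to
    the reference organ) or from an explicit mapping.  Ties keep the
    input order (stable sort).
    """
    if distances is None:
        if phantom is None:
            raise ValueError("need a phantom or an explicit distance table")
        distances = {o: organ_distance(phantom, reference_organ, o) for o in doses}
    missing = sorted(set(doses) - set(distances))
    if missing:
        raise KeyError(f"no distance for organs: {missing}")
    df = pd.DataFrame(
        {
            "organ": list(doses),
            "distance_cm": [distances[o] for o in doses],
            "dose_mgy": list(doses.values()),
        }
    )
    return df.sort_values("distance_cm", kind="stable", ignore_index=True)


def plot_dose_vs_distance(tables: dict[str, pd.DataFrame], out_path: str) -> None:
    """Dose vs PTV-center distance on a log dose axis, one series per
    labelled table (e.g. measured vs simulated, per technique)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, df in tables.items():
        ax.plot(df["distance_cm"], df["dose_mgy"], "o-", label=label)
    ax.set_yscale("log")
    ax.set_xlabel("distance from PTV center (cm)")
    ax.set_ylabel("organ dose (mGy)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
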