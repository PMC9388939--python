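"""Treatment plans, MLC log files and control-point job lists.

A :class:`TreatmentPlan` holds the deliverable field geometry of a
static (3DCRT) or sliding-window (IMRT) brain plan: per-field gantry /
collimator / couch angles, jaw half-openings at the isocenter plane,
SSD and monitor units.  Dynamic fields additionally carry an MLC leaf
sequence of ~100 control points parsed from a delimited-text log file
dialect (documented below); the IMRT simulation strategy subsamples
every 5th control point of each field, giving 20 static leaf
snapshots per field (140 jobs for a 7-field plan), each assigned an
equal share of the field's MU.

Plan file dialect (tab separated, versioned header line)::

    # oofdose-plan v1\ttechnique=3DCRT\tprescribed_gy=54.0\tfraction_gy=1.8
    field_id\tgantry_deg\t...\tmu
    1\t320.0\t...\t32

MLC log dialect::

    # oofdose-mlc v1\tfield_id=1\tleaf_pairs=60\tcontrol_points=100
    index\tmu_fraction\ta01..a60\tb01..b60

Leaf-tip positions are cm at the isocenter plane on the leaf-travel
(x) axis; bank A tips must not pass bank B tips of the same pair.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BeamField",
    "MLCControlPoint",
    "TreatmentPlan",
    "MLCModel",
    "Aperture",
    "SimJob",
    "default_mlc_model",
    "parse_plan_table",
    "serialize_plan",
    "parse_mlc_log",
    "serialize_mlc_log",
    "subsample_control_points",
    "make_job_list",
    "aperture_at",
]

_PLAN_MAGIC = "# oofdose-plan v1"
_MLC_MAGIC = "# oofdose-mlc v1"
_JAW_TOL = 0.05  # cm, rounding tolerance between Field X/Y and X1+X2 / Y1+Y2

_PLAN_COLUMNS = [
    "field_id", "gantry_deg", "collimator_deg", "couch_deg",
    "field_x_cm", "x1_cm", "x2_cm", "field_y_cm", "y1_cm", "y2_cm",
    "weight", "ssd_cm", "mu",
]


@dataclass(frozen=True)
class BeamField:
    """One treatment field's deliverable geometry."""

    field_id: str
    gantry: float  # deg
    collimator: float  # deg
    couch: float  # deg
    x1: float  # jaw half-opening toward -x, cm at isocenter
    x2: float  # jaw half-opening toward +x
    y1: float  # toward -y
    y2: float  # toward +y
    ssd: float  # cm
    mu: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        for ang in ("gantry", "collimator", "couch"):
            v = getattr(self, ang)
            if not (0.0 <= v < 360.0):
                raise ValueError(f"field {self.field_id}: {ang} angle {v} outside [0, 360)")
        if self.mu < 0:
            raise ValueError(f"field {self.field_id}: negative MU")

    @property
    def field_x(self) -> float:
        return self.x1 + self.x2

    @property
    def field_y(self) -> float:
        return self.y1 + self.y2


@dataclass(frozen=True)
class MLCControlPoint:
    """Snapshot of leaf-bank positions at a cumulative MU fraction."""

    index: int  # 1-based
    mu_fraction: float  # cumulative fraction of the field MU, in [0, 1]
    bank_a: np.ndarray  # (60,) leaf-tip x positions, cm at isocenter
    bank_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.bank_a, dtype=float)
        b = np.asarray(self.bank_b, dtype=float)
        object.__setattr__(self, "bank_a", a)
        object.__setattr__(self, "bank_b", b)
        crossed = np.nonzero(a > b + 1e-9)[0]
        if crossed.size:
            raise ValueError(
                f"control point {self.index}: leaf pair {crossed[0] + 1} crossed "
                f"(bank A {a[crossed[0]]:.3f} > bank B {b[crossed[0]]:.3f})"
            )
        if not (-1e-9 <= self.mu_fraction <= 1 + 1e-9):
            raise ValueError(f"control point {self.index}: mu_fraction outside [0, 1]")


@dataclass
class TreatmentPlan:
    technique: str  # "3DCRT" | "IMRT"
    fields: list[BeamField]
    mlc_sequences: dict[str, list[MLCControlPoint]] = field(default_factory=dict)
    prescribed_gy: float = 54.0
    fraction_gy: float = 1.8
    plan_id: str = "plan"

    @property
    def n_fractions(self) -> int:
        return int(round(self.prescribed_gy / self.fraction_gy))

    @property
    def total_mu(self) -> float:
        return sum(f.mu for f in self.fields)

    def validate(self) -> None:
        if self.technique not in ("3DCRT", "IMRT"):
            raise ValueError(f"unknown technique {self.technique!r}")
        if abs(self.n_fractions * self.fraction_gy - self.prescribed_gy) > 1e-6:
            raise ValueError("prescription is not a whole number of fractions")
        if self.technique == "IMRT":
            missing = [f.field_id for f in self.fields if not self.mlc_sequences.get(f.field_id)]
            if missing:
                raise ValueError(f"IMRT fields without MLC sequence: {missing}")


# ---------------------------------------------------------------------------
# Plan file parsing

def parse_plan_table(path_or_buffer) -> TreatmentPlan:
    """Parse a versioned tab-separated plan file into a TreatmentPlan.

    Jaw consistency is validated row by row: Field X must equal
    X1 + X2 (and Y likewise) within 0.05 cm, else a ``ValueError``
    naming the offending field is raised.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    lines = text.splitlines()
    if not lines or not lines[0].startswith(_PLAN_MAGIC):
        raise ValueError("not an oofdose plan file (missing version header)")
    meta = dict(tok.split("=", 1) for tok in lines[0].split("\t")[1:] if "=" in tok)
    df = pd.read_csv(io.StringIO("\n".join(lines[1:])), sep="\t")
    missing = [c for c in _PLAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plan file missing columns: {missing}")
    df["field_id"] = df["field_id"].astype(str)  # before iterrows upcasts rows

    fields = []
    for _, row in df.iterrows():
        fid = str(row["field_id"])
        if abs(row["field_x_cm"] - (row["x1_cm"] + row["x2_cm"])) > _JAW_TOL:
            raise ValueError(f"field {fid}: Field X != X1 + X2 beyond {_JAW_TOL} cm")
        if abs(row["field_y_cm"] - (row["y1_cm"] + row["y2_cm"])) > _JAW_TOL:
            raise ValueError(f"field {fid}: Field Y != Y1 + Y2 beyond {_JAW_TOL} cm")
        fields.append(
            BeamField(
                field_id=fid,
                gantry=float(row["gantry_deg"]),
                collimator=float(row["collimator_deg"]),
                couch=float(row["couch_deg"]),
                x1=float(row["x1_cm"]),
                x2=float(row["x2_cm"]),
                y1=float(row["y1_cm"]),
                y2=float(row["y2_cm"]),
                ssd=float(row["ssd_cm"]),
                mu=float(row["mu"]),
                weight=float(row["weight"]),
            )
        )
    plan = TreatmentPlan(
        technique=meta.get("technique", "3DCRT"),
        fields=fields,
        prescribed_gy=float(meta.get("prescribed_gy", 54.0)),
        fraction_gy=float(meta.get("fraction_gy", 1.8)),
        plan_id=meta.get("plan_id", "plan"),
    )
    return plan


def serialize_plan(plan: TreatmentPlan, path=None) -> str:
    header = (
        f"{_PLAN_MAGIC}\ttechnique={plan.technique}"
        f"\tprescribed_gy={plan.prescribed_gy}\tfraction_gy={plan.fraction_gy}"
        f"\tplan_id={plan.plan_id}"
    )
    rows = [header, "\t".join(_PLAN_COLUMNS)]
    for f in plan.fields:
        rows.append(
            "\t".join(
                str(v)
                for v in [
                    f.field_id, f.gantry, f.collimator, f.couch,
                    round(f.field_x, 4), f.x1, f.x2,
                    round(f.field_y, 4), f.y1, f.y2,
                    f.weight, f.ssd, f.mu,
                ]
            )
        )
    text = "\n".join(rows) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# MLC log files

def parse_mlc_log(path_or_buffer) -> list[MLCControlPoint]:
    """Parse an MLC log file into ordered control points.

    The cumulative MU fraction must be non-decreasing; it is
    normalized so the final control point sits at exactly 1.0.
    Crossed leaf pairs raise with the pair number.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(_MLC_MAGIC):
        raise ValueError("not an oofdose MLC log (missing version header)")
    meta = dict(tok.split("=", 1) for tok in lines[0].split("\t")[1:] if "=" in tok)
    n_pairs = int(meta.get("leaf_pairs", 60))
    data = np.loadtxt(io.StringIO("\n".join(lines[2:])), ndmin=2)
    if data.shape[1] != 2 + 2 * n_pairs:
        raise ValueError(
            f"MLC log rows must have {2 + 2 * n_pairs} columns, got {data.shape[1]}"
        )
    order = np.argsort(data[:, 0])
    data = data[order]
    mu = data[:, 1]
    if np.any(np.diff(mu) < -1e-9):
        raise ValueError("cumulative MU fraction is not non-decreasing")
    if mu[-1] <= 0:
        raise ValueError("final cumulative MU fraction must be positive")
    mu = mu / mu[-1]
    points = [
        MLCControlPoint(
            index=int(data[i, 0]),
            mu_fraction=float(mu[i]),
            bank_a=data[i, 2 : 2 + n_pairs],
            bank_b=data[i, 2 + n_pairs :],
        )
        for i in range(data.shape[0])
    ]
    return points


def serialize_mlc_log(field_id: str, points: list[MLCControlPoint], path=None) -> str:
    n_pairs = len(points[0].bank_a)
    header = (
        f"{_MLC_MAGIC}\tfield_id={field_id}\tleaf_pairs={n_pairs}"
        f"\tcontrol_points={len(points)}"
    )
    cols = (
        ["index", "mu_fraction"]
        + [f"a{i + 1:02d}" for i in range(n_pairs)]
        + [f"b{i + 1:02d}" for i in range(n_pairs)]
    )
    rows = [header, "\t".join(cols)]
    for p in points:
        vals = [str(p.index), f"{p.mu_fraction:.6f}"]
        vals += [f"{v:.4f}" for v in p.bank_a]
        vals += [f"{v:.4f}" for v in p.bank_b]
        rows.append("\t".join(vals))
    text = "\n".join(rows) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def subsample_control_points(
    sequence: list[MLCControlPoint], step: int = 5
) -> list[MLCControlPoint]:
    """Select every ``step``-th control point (1-based: step, 2*step, ...).

    A 100-point sequence at the default step of 5 yields the 20
    snapshots used per dynamic field.
    """
    if step <= 0:
        raise ValueError("step must be a positive integer")
    if len(sequence) < step:
        raise ValueError(f"sequence of {len(sequence)} control points shorter than step {step}")
    return [sequence[i - 1] for i in range(step, len(sequence) + 1, step)]


@dataclass(frozen=True)
class SimJob:
    """One static simulation job: a field, an optional leaf snapshot
    and the MU share this job delivers."""

    field: BeamField
    control_point: MLCControlPoint | None
    mu: float


def make_job_list(plan: TreatmentPlan, step: int = 5) -> list[SimJob]:
    """Expand a plan into static simulation jobs.

    Static fields give one job each at the full field MU; dynamic
    fields give one job per subsampled control point with equal MU
    weights summing exactly to the field MU.
    """
    jobs: list[SimJob] = []
    for f in plan.fields:
        seq = plan.mlc_sequences.get(f.field_id)
        if plan.technique == "IMRT":
            if not seq:
                raise ValueError(f"IMRT field {f.field_id} has no MLC sequence")
            chosen = subsample_control_points(seq, step)
            share = f.mu / len(chosen)
            jobs.extend(SimJob(f, cp, share) for cp in chosen)
        else:
            jobs.append(SimJob(f, None, f.mu))
    return jobs


# ---------------------------------------------------------------------------
# MLC geometry and apertures

@dataclass(frozen=True)
class MLCModel:
    """Leaf-width model: pair boundaries on the y axis at isocenter."""

    boundaries: np.ndarray  # (n_pairs + 1,) cm, increasing

    @property
    def n_pairs(self) -> int:
        return len(self.boundaries) - 1

    def pair_bounds(self, pair: int) -> tuple[float, float]:
        """(y_low, y_high) of a 1-based leaf pair."""
        return float(self.boundaries[pair - 1]), float(self.boundaries[pair])


def default_mlc_model() -> MLCModel:
    """120-leaf model: 0.5 cm central 40 pairs, 1.0 cm outer 2x10 pairs,
    spanning y in [-20, 20] cm at isocenter."""
    widths = np.concatenate([np.full(10, 1.0), np.full(40, 0.5), np.full(10, 1.0)])
    return MLCModel(boundaries=np.concatenate([[-20.0], -20.0 + np.cumsum(widths)]))


@dataclass(frozen=True)
class Aperture:
    """Open region at the isocenter plane: jaw rectangle intersected
    with the union of per-pair leaf gaps (when leaves are present)."""

    x_interval: tuple[float, float]
    y_interval: tuple[float, float]
    leaf_gaps: np.ndarray | None = None  # (n_pairs, 2) open (lo, hi) per pair
    mlc: MLCModel | None = None

    @property
    def jaw_area(self) -> float:
        return max(0.0, self.x_interval[1] - self.x_interval[0]) * max(
            0.0, self.y_interval[1] - self.y_interval[0]
        )

    def bounding_box(self, margin: float = 0.0) -> tuple[float, float, float, float]:
        return (
            self.x_interval[0] - margin,
            self.x_interval[1] + margin,
            self.y_interval[0] - margin,
            self.y_interval[1] + margin,
        )

    def open_area(self) -> float:
        if self.leaf_gaps is None:
            return self.jaw_area
        area = 0.0
        for p in range(self.mlc.n_pairs):
            ylo, yhi = self.mlc.pair_bounds(p + 1)
            ylo, yhi = max(ylo, self.y_interval[0]), min(yhi, self.y_interval[1])
            if yhi <= ylo:
                continue
            xlo = max(self.leaf_gaps[p, 0], self.x_interval[0])
            xhi = min(self.leaf_gaps[p, 1], self.x_interval[1])
            if xhi > xlo:
                area += (yhi - ylo) * (xhi - xlo)
        return area

    def classify(self, x, y) -> np.ndarray:
        """0 = open, 1 = MLC-blocked (inside jaws), 2 = jaw-blocked."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        in_jaw = (
            (x >= self.x_interval[0])
            & (x <= self.x_interval[1])
            & (y >= self.y_interval[0])
            & (y <= self.y_interval[1])
        )
        out = np.where(in_jaw, 0, 2).astype(np.int8)
        if self.leaf_gaps is not None:
            pair = np.searchsorted(self.mlc.boundaries, y, side="right") - 1
            pair = np.clip(pair, 0, self.mlc.n_pairs - 1)
            open_leaf = (x >= self.leaf_gaps[pair, 0]) & (x <= self.leaf_gaps[pair, 1])
            out = np.where(in_jaw & ~open_leaf, 1, out).astype(np.int8)
        return out


def aperture_at(
    field: BeamField,
    control_point: MLCControlPoint | None = None,
    mlc_model: MLCModel | None = None,
) -> Aperture:
    """Compose the jaw rectangle and (optionally) a leaf snapshot.

    A static field with no control point is the jaw rectangle alone
    (leaves retracted).
    """
    x_int = (-field.x1, field.x2)
    y_int = (-field.y1, field.y2)
    if control_point is None:
        return Aperture(x_interval=x_int, y_interval=y_int)
    mlc = mlc_model or default_mlc_model()
    if len(control_point.bank_a) != mlc.n_pairs:
        raise ValueError(
            f"control point has {len(control_point.bank_a)} pairs, MLC model has {mlc.n_pairs}"
        )
    gaps = np.column_stack([control_point.bank_a, control_point.bank_b])
    return Aperture(x_interval=x_int, y_interval=y_int, leaf_gaps=gaps, mlc=mlc)
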