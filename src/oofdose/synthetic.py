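"""Synthetic inputs for the full pipeline: TLD readings, dynamic MLC
logs and the packaged plan fixtures.

The TLD generator inverts the dose-reduction chain: given a true organ
dose it produces the raw reading that, when reduced with the recorded
calibration factors, returns exactly that dose (noiseless mode), and
multiplies the reading by mean-one log-normal noise at the combined
budget relative sigma (15.8% by default) to emulate measurement
scatter.  A decomposed noise mode instead perturbs the element
correction coefficient, reader stability factor and reader calibration
factor individually with their component sigmas, for budget-validation
studies.

The MLC generator emulates a sliding-window delivery for a coplanar
brain field: a leaf-gap window sweeps from the X1 jaw to the X2 jaw
over ~100 control points, with only leaf pairs 27-34 (the pairs whose
widths cover the field's Y extent) ever moving; all other pairs stay
parked beyond the X1 jaw.  The default gap fraction of 0.65 of the
field X width represents mild fluence modulation, chosen so the
fluence delivered per monitor unit is clinically comparable to the
open static fields of the companion 3DCRT plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from . import plan as plan_mod
from .plan import BeamField, MLCControlPoint, TreatmentPlan, parse_mlc_log, parse_plan_table, serialize_mlc_log
from .reference import MEASURED_MEAN_DOSE_MGY, ORGAN_MUEN_6MEV, TLD_COUNTS
from .tld import TLDRecord, air_muen_6mev, default_uncertainty_budget

__all__ = [
    "GeneratorConfig",
    "generate_tld_readings",
    "generate_mlc_log",
    "fixture_plan_paths",
    "fixture_plans",
    "attach_synthetic_mlc",
    "DEFAULT_MOVING_PAIRS",
]

DEFAULT_MOVING_PAIRS = tuple(range(27, 35))


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the TLD reading generator.

    ``true_doses`` maps organ -> ground-truth mean dose (mGy); the
    default uses the reference campaign's measured means for the
    requested technique.  ``noise_relative`` is the multiplicative
    log-normal relative sigma applied to the raw reading (defaults to
    the combined budget, 0.158); ``noise_mode`` is ``"reading"`` (one
    log-normal factor on RD), ``"decomposed"`` (per-factor
    perturbations at the component sigmas) or ``"none"``.
    """

    true_doses: dict[str, float] | None = None
    n_dosimeters: dict[str, int] | None = None
    noise_relative: float | None = None
    noise_mode: str = "reading"
    ecc_spread: float = 0.02  # manufacturing spread of Ecc around 1
    rcf_nominal: float = 2.5  # reader units per mGy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_mode not in ("reading", "decomposed", "none"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")
        if self.true_doses is not None and any(v < 0 for v in self.true_doses.values()):
            raise ValueError("true doses must be non-negative")


def _lognormal_factor(rng: np.random.Generator, rel_sigma: float, size: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with relative sigma."""
    if rel_sigma <= 0:
        return np.ones(size)
    s = np.sqrt(np.log1p(rel_sigma**2))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def generate_tld_readings(
    config: GeneratorConfig,
    technique: str,
    rng: np.random.Generator | None = None,
) -> list[TLDRecord]:
    """Generate one technique group of TLD records (38 by default).

    Raw readings follow the inverse reduction chain
    ``RD = D_true * (muen_air / muen_tissue) * RCF / (Ecc * f_Q * f_E) * noise``;
    the recorded calibration factors are the ones actually applied, so
    the reduction chain recovers ``D_true`` exactly in noiseless mode.
    """
    if technique not in MEASURED_MEAN_DOSE_MGY:
        raise ValueError(f"unknown technique {technique!r}")
    truths = config.true_doses or MEASURED_MEAN_DOSE_MGY[technique]
    counts = config.n_dosimeters or TLD_COUNTS
    unknown = set(truths) - set(ORGAN_MUEN_6MEV)
    if unknown:
        raise KeyError(f"organs without a 6 MeV coefficient: {sorted(unknown)}")
    rng = rng or np.random.default_rng(config.seed)
    budget_rel = (
        config.noise_relative
        if config.noise_relative is not None
        else default_uncertainty_budget().combined_relative()
    )
    air = air_muen_6mev()

    records: list[TLDRecord] = []
    comp = {name: u / 100.0 for name, u, _ in default_uncertainty_budget().components}
    for organ, d_true in truths.items():
        n = counts.get(organ, 1)
        ecc = 1.0 + rng.normal(0.0, config.ecc_spread, size=n)
        ecc = np.clip(ecc, 0.5, 1.5)
        f_q = np.ones(n)
        f_e = np.ones(n)
        rcf = np.full(n, config.rcf_nominal)
        ratio = air / ORGAN_MUEN_6MEV[organ]
        rd_clean = d_true * ratio * rcf / (ecc * f_q * f_e)
        if config.noise_mode == "reading":
            rd = rd_clean * _lognormal_factor(rng, budget_rel, n)
        elif config.noise_mode == "decomposed":
            # The *applied* factor differs from the recorded one by the
            # component uncertainty, so the reduced dose error combines
            # the components in quadrature.
            f_ecc = _lognormal_factor(rng, comp["element correction coefficient"], n)
            f_stab = _lognormal_factor(rng, comp["reader stability"], n)
            f_rcf = _lognormal_factor(rng, comp["reader calibration factor"], n)
            f_en = _lognormal_factor(rng, comp["energy dependence"], n)
            rd = rd_clean * f_ecc * f_stab * f_en / f_rcf
        else:
            rd = rd_clean
        for i in range(n):
            records.append(
                TLDRecord(
                    dosimeter_id=f"{technique}-{organ}-{i + 1:02d}",
                    organ=organ,
                    technique=technique,
                    rd=float(rd[i]),
                    ecc=float(ecc[i]),
                    f_q=float(f_q[i]),
                    f_e=float(f_e[i]),
                    rcf=float(rcf[i]),
                )
            )
    return records


def replicate_roundtrip(
    organ: str,
    technique: str,
    n_replicates: int = 200,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> tuple[float, float]:
    """Generate-and-reduce round trip repeated over seeded replicates.

    Each replicate generates a fresh technique group of readings with
    the stated noise budget and reduces the requested organ through
    the kerma / tissue-dose / averaging chain.  Returns the grand mean
    of the recovered organ doses (mGy) and its standard error.
    """
    from .tld import organ_mean

    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    means = np.empty(n_replicates)
    for i in range(n_replicates):
        records = generate_tld_readings(config, technique, rng=rng)
        mine = [r for r in records if r.organ == organ]
        means[i] = organ_mean(mine).mean_dose_mgy
    grand = float(means.mean())
    se = float(means.std(ddof=1) / np.sqrt(n_replicates))
    return grand, se


def generate_mlc_log(
    beam_field: BeamField,
    n_control_points: int = 100,
    moving_pairs=DEFAULT_MOVING_PAIRS,
    seed: int = 0,
    gap_fraction: float = 0.65,
    n_pairs: int = 60,
    path=None,
) -> str:
    """Synthesize a sliding-window MLC log for one dynamic field.

    Returns the log text (and writes it to ``path`` when given); the
    output parses cleanly with :func:`oofdose.plan.parse_mlc_log` and
    is byte-identical for a fixed seed.
    """
    moving = sorted(moving_pairs)
    if not moving or moving[0] < 1 or moving[-1] > n_pairs:
        raise ValueError("moving pairs must be a subset of 1..n_pairs")
    rng = np.random.default_rng(seed)
    x_lo, x_hi = -beam_field.x1, beam_field.x2
    width = x_hi - x_lo
    park = x_lo - 0.5  # closed tips parked beyond the X1 jaw

    # Strictly increasing cumulative MU fractions ending at 1.
    incr = rng.uniform(0.5, 1.5, size=n_control_points)
    mu = np.cumsum(incr)
    mu /= mu[-1]

    phases = rng.uniform(0.0, np.pi, size=len(moving))
    depth = rng.uniform(0.1, 0.25, size=len(moving))

    points: list[MLCControlPoint] = []
    for k in range(n_control_points):
        t = k / (n_control_points - 1) if n_control_points > 1 else 0.0
        a = np.full(n_pairs, park)
        b = np.full(n_pairs, park)
        center = x_lo + width * t
        for j, p in enumerate(moving):
            # Half-gap modulated per pair; window clipped at the jaws.
            half = 0.5 * gap_fraction * width * (1.0 - depth[j] * np.sin(np.pi * t + phases[j]) ** 2)
            lo = np.clip(center - half, x_lo, x_hi)
            hi = np.clip(center + half, x_lo, x_hi)
            a[p - 1] = lo
            b[p - 1] = max(hi, lo)
        points.append(MLCControlPoint(index=k + 1, mu_fraction=float(mu[k]), bank_a=a, bank_b=b))
    return serialize_mlc_log(beam_field.field_id, points, path=path)


def fixture_plan_paths() -> tuple[str, str]:
    """Filesystem paths of the packaged 3DCRT and IMRT plan tables."""
    base = resources.files("oofdose").joinpath("data/plans")
    return str(base / "plan_3dcrt.tsv"), str(base / "plan_imrt.tsv")


def attach_synthetic_mlc(
    plan: TreatmentPlan, seed: int = 0, n_control_points: int = 100
) -> TreatmentPlan:
    """Give every field of an IMRT plan a synthetic sliding-window
    sequence (deterministic per field for a fixed seed)."""
    children = np.random.SeedSequence(seed).spawn(len(plan.fields))
    for f, child in zip(plan.fields, children):
        sub = int(child.generate_state(1)[0] % (2**31))
        text = generate_mlc_log(f, n_control_points=n_control_points, seed=sub)
        plan.mlc_sequences[f.field_id] = parse_mlc_log_text(text)
    return plan


def parse_mlc_log_text(text: str) -> list[MLCControlPoint]:
    import io

    return parse_mlc_log(io.StringIO(text))


def fixture_plans(with_mlc: bool = True, seed: int = 0) -> tuple[TreatmentPlan, TreatmentPlan]:
    """The packaged 3DCRT (6 static fields) and IMRT (7 dynamic fields)
    plans; the IMRT plan gets synthetic MLC sequences when requested."""
    p3d_path, pimrt_path = fixture_plan_paths()
    plan_3dcrt = parse_plan_table(p3d_path)
    plan_imrt = parse_plan_table(pimrt_path)
    plan_3dcrt.validate()
    if with_mlc:
        attach_synthetic_mlc(plan_imrt, seed=seed)
        plan_imrt.validate()
    return plan_3dcrt, plan_imrt
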