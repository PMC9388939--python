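"""Field and plan level simulation behaviour: determinism, statistics,
calibration, and the physical ordering of out-of-field organ doses."""

import copy
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import spearmanr

from oofdose.plan import aperture_at
from oofdose.reference import ORGAN_DISTANCES_CM, OUT_OF_FIELD_ORGANS
from oofdose.transport import (
    CollimationModel,
    SourceModel,
    TransportConfig,
    calibrate_cf,
    run_beam,
    simulate_plan,
)

SEED = 777


def test_fixed_seed_reproduces_tallies_exactly(pediatric_phantom, plans, source, collimation):
    f1 = plans[0].fields[0]
    cfg = TransportConfig(n_histories=20_000, seed=SEED)
    a = run_beam(pediatric_phantom, f1, aperture_at(f1), source, collimation, cfg)
    b = run_beam(pediatric_phantom, f1, aperture_at(f1), source, collimation, cfg)
    assert a.dose_per_particle == b.dose_per_particle
    assert a.rel_se == b.rel_se


def test_doubling_histories_shrinks_standard_error(pediatric_phantom, plans, source, collimation):
    f1 = plans[0].fields[0]
    small = run_beam(
        pediatric_phantom, f1, aperture_at(f1), source, collimation,
        TransportConfig(n_histories=100_000, seed=SEED),
    )
    big = run_beam(
        pediatric_phantom, f1, aperture_at(f1), source, collimation,
        TransportConfig(n_histories=400_000, seed=SEED + 1),
    )
    # means stable within 3 sigma of the combined error
    for organ in ("ptv", "brain"):
        d1, d2 = small.dose_per_particle[organ], big.dose_per_particle[organ]
        se = np.hypot(small.rel_se[organ] * d1, big.rel_se[organ] * d2)
        assert abs(d1 - d2) < 3 * se
    # 4x the histories should shrink the PTV SE by about 2
    ratio = small.rel_se["ptv"] / big.rel_se["ptv"]
    assert 1.3 < ratio < 3.0


def test_ptv_receives_more_dose_per_particle_than_any_out_of_field_organ(field1_tally):
    ptv = field1_tally.dose_per_particle["ptv"]
    for organ in OUT_OF_FIELD_ORGANS:
        assert ptv > field1_tally.dose_per_particle[organ]


def test_near_field_tallies_reach_five_percent_precision(field1_tally):
    """With 2e6 histories in 20 batches, the PTV and right-eye tallies
    of the first brain field reach a 1-sigma relative SE of 5% or
    better."""
    assert field1_tally.histories >= 2_000_000
    assert field1_tally.batches == 20
    assert field1_tally.rel_se["ptv"] <= 0.05
    assert field1_tally.rel_se["right eye"] <= 0.05


def test_undefined_standard_error_is_flagged(pediatric_phantom, plans, source):
    """An aperture that blocks everything produces zero tallies whose
    SE is flagged as undefined rather than silently reported."""
    f1 = plans[0].fields[0]
    col = CollimationModel(
        mlc_transmission=0.0, jaw_transmission=0.0, head_leakage_fraction=0.0
    )
    closed = replace(f1, x1=0.0, x2=0.0, y1=0.0, y2=0.0)
    cfg = TransportConfig(n_histories=2_000, seed=SEED)
    tally = run_beam(pediatric_phantom, closed, aperture_at(closed), source, col, cfg)
    flags = tally.se_flags()
    assert all(flags.values())
    assert all(d == 0.0 for d in tally.dose_per_particle.values())


# -- calibration -----------------------------------------------------------

def test_cf_linearity_and_stability(source, collimation):
    cfg = TransportConfig(n_histories=50_000, seed=SEED)
    full = calibrate_cf(source, collimation, cfg, calibration_dose_mgy_per_mu=10.0)
    half = calibrate_cf(source, collimation, cfg, calibration_dose_mgy_per_mu=5.0)
    assert half.cf == pytest.approx(full.cf / 2, rel=1e-12)
    # CF is a normalization: independent of the number of histories
    # up to statistical noise
    more = calibrate_cf(
        source, collimation, TransportConfig(n_histories=150_000, seed=SEED + 1)
    )
    assert more.cf == pytest.approx(full.cf, rel=0.10)


# -- plan simulation -------------------------------------------------------

def test_zero_mu_plan_gives_zero_dose(pediatric_phantom, plans, source, collimation, conversion_factor):
    plan = copy.deepcopy(plans[0])
    plan.fields = [replace(f, mu=0.0) for f in plan.fields]
    rep = simulate_plan(
        pediatric_phantom, plan, source,
        TransportConfig(n_histories=30_000, seed=SEED),
        collimation=collimation, cf=conversion_factor,
    )
    assert all(v == 0.0 for v in rep.organ_dose_mgy.values())


def test_dose_scales_linearly_with_mu(pediatric_phantom, plans, source, collimation, conversion_factor):
    base = copy.deepcopy(plans[0])
    base.fields = base.fields[:1]
    cfg = TransportConfig(n_histories=30_000, seed=SEED)
    rep1 = simulate_plan(pediatric_phantom, base, source, cfg,
                         collimation=collimation, cf=conversion_factor)
    doubled = copy.deepcopy(base)
    doubled.fields = [replace(f, mu=2 * f.mu) for f in doubled.fields]
    rep2 = simulate_plan(pediatric_phantom, doubled, source, cfg,
                         collimation=collimation, cf=conversion_factor)
    for organ, d in rep1.organ_dose_mgy.items():
        assert rep2.organ_dose_mgy[organ] == pytest.approx(2 * d, rel=1e-9)


def test_imrt_plan_without_sequences_is_rejected(pediatric_phantom, source, conversion_factor):
    from oofdose.synthetic import fixture_plans

    _, imrt = fixture_plans(with_mlc=False)
    with pytest.raises(ValueError, match="MLC sequence"):
        simulate_plan(
            pediatric_phantom, imrt, source,
            TransportConfig(n_histories=10_000, seed=SEED), cf=conversion_factor,
        )


def test_imrt_out_of_field_dose_falls_with_distance(imrt_report):
    """Simulated IMRT organ doses rank-order inversely with the
    PTV-to-organ distances (Spearman rho <= -0.8 over 7 organs)."""
    d = [ORGAN_DISTANCES_CM[o] for o in OUT_OF_FIELD_ORGANS]
    v = [imrt_report.organ_dose_mgy[o] for o in OUT_OF_FIELD_ORGANS]
    rho = spearmanr(d, v).statistic
    assert rho <= -0.8


def test_imrt_delivers_at_least_3dcrt_to_the_eyes(imrt_report, crt_report):
    """Direction of effect: the modulated technique's eye doses are at
    least the conformal technique's under the packaged plans."""
    for organ in ("right eye", "left eye"):
        assert imrt_report.organ_dose_mgy[organ] >= crt_report.organ_dose_mgy[organ]


def test_dose_report_round_trip(crt_report):
    from oofdose.transport import DoseReport

    back = DoseReport.from_json(crt_report.to_json())
    assert back.organ_dose_mgy == crt_report.organ_dose_mgy
    assert back.technique == crt_report.technique
    assert back.n_fractions == crt_report.n_fractions
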