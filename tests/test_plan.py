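"""Plan tables, MLC logs, subsampling and apertures."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oofdose.plan import (
    BeamField,
    MLCControlPoint,
    aperture_at,
    default_mlc_model,
    make_job_list,
    parse_mlc_log,
    parse_plan_table,
    serialize_mlc_log,
    serialize_plan,
    subsample_control_points,
)
from oofdose.synthetic import fixture_plan_paths, generate_mlc_log


# -- plan tables -----------------------------------------------------------

def test_packaged_3dcrt_plan(plans):
    p3d = plans[0]
    assert p3d.technique == "3DCRT"
    assert len(p3d.fields) == 6
    assert p3d.total_mu == 269  # hand sum of the MU column
    assert p3d.fields[3].mu == 63
    f1 = p3d.fields[0]
    assert (f1.gantry, f1.x1, f1.x2) == (320.0, 1.6, 1.6)
    assert p3d.n_fractions == 30


def test_packaged_imrt_plan(plans):
    pimrt = plans[1]
    assert pimrt.technique == "IMRT"
    assert len(pimrt.fields) == 7
    assert all(f.couch == 0.0 for f in pimrt.fields)
    assert pimrt.fields[6].ssd == 91.5
    assert all(f.field_x == pytest.approx(5.0) for f in pimrt.fields)


def test_plan_round_trip(tmp_path, plans):
    p3d = plans[0]
    path = tmp_path / "plan.tsv"
    serialize_plan(p3d, path)
    back = parse_plan_table(path)
    assert back.technique == p3d.technique
    assert back.fields == p3d.fields
    assert back.prescribed_gy == p3d.prescribed_gy


def test_jaw_mismatch_rejected():
    text = (
        "# oofdose-plan v1\ttechnique=3DCRT\n"
        "field_id\tgantry_deg\tcollimator_deg\tcouch_deg\tfield_x_cm\tx1_cm\tx2_cm"
        "\tfield_y_cm\ty1_cm\ty2_cm\tweight\tssd_cm\tmu\n"
        "9\t0\t0\t0\t4.0\t1.6\t1.6\t3.2\t1.6\t1.6\t1.0\t95.0\t10\n"
    )
    with pytest.raises(ValueError, match="field 9"):
        parse_plan_table(io.StringIO(text))


def test_missing_header_rejected():
    with pytest.raises(ValueError, match="version header"):
        parse_plan_table(io.StringIO("field_id\tmu\n1\t10\n"))


# -- MLC logs --------------------------------------------------------------

def _demo_field():
    return BeamField(
        field_id="demo", gantry=0.0, collimator=0.0, couch=0.0,
        x1=2.5, x2=2.5, y1=1.8, y2=1.8, ssd=93.5, mu=50.0,
    )


def test_synthetic_log_parses_with_expected_count():
    text = generate_mlc_log(_demo_field(), n_control_points=100, seed=5)
    points = parse_mlc_log(io.StringIO(text))
    assert len(points) == 100
    assert points[-1].mu_fraction == pytest.approx(1.0)
    fracs = [p.mu_fraction for p in points]
    assert all(b > a for a, b in zip(fracs, fracs[1:]))


def test_only_configured_pairs_move():
    text = generate_mlc_log(_demo_field(), n_control_points=60, seed=5)
    points = parse_mlc_log(io.StringIO(text))
    a = np.array([p.bank_a for p in points])
    b = np.array([p.bank_b for p in points])
    moving = set(np.nonzero(np.ptp(a, axis=0) + np.ptp(b, axis=0) > 1e-9)[0] + 1)
    assert moving == set(range(27, 35))


def test_crossed_leaf_pair_rejected():
    with pytest.raises(ValueError, match="pair 3"):
        MLCControlPoint(
            index=1, mu_fraction=0.5,
            bank_a=np.array([0.0, 0.0, 1.0] + [0.0] * 57),
            bank_b=np.array([1.0, 1.0, 0.5] + [0.0] * 57),
        )


def test_non_monotone_mu_fraction_rejected():
    field = _demo_field()
    text = generate_mlc_log(field, n_control_points=10, seed=1)
    lines = text.splitlines()
    # swap the MU fractions of two control points
    r3 = lines[4].split("\t")
    r3[1] = "0.900000"
    lines[4] = "\t".join(r3)
    with pytest.raises(ValueError, match="non-decreasing"):
        parse_mlc_log(io.StringIO("\n".join(lines)))


def test_log_generation_is_deterministic():
    f = _demo_field()
    assert generate_mlc_log(f, seed=9) == generate_mlc_log(f, seed=9)
    assert generate_mlc_log(f, seed=9) != generate_mlc_log(f, seed=10)


def test_log_serialize_round_trip():
    text = generate_mlc_log(_demo_field(), n_control_points=20, seed=2)
    points = parse_mlc_log(io.StringIO(text))
    text2 = serialize_mlc_log("demo", points)
    points2 = parse_mlc_log(io.StringIO(text2))
    for p, q in zip(points, points2):
        assert p.index == q.index
        np.testing.assert_allclose(p.bank_a, q.bank_a)
        np.testing.assert_allclose(p.bank_b, q.bank_b)


# -- subsampling -----------------------------------------------------------

def test_subsample_every_fifth_of_hundred(plans):
    seq = plans[1].mlc_sequences["1"]
    sel = subsample_control_points(seq, step=5)
    assert len(sel) == 20
    assert [p.index for p in sel] == list(range(5, 101, 5))


def test_job_list_length_and_mu_conservation(plans):
    jobs = make_job_list(plans[1], step=5)
    assert len(jobs) == 140  # 7 fields x 20 snapshots
    per_field = {}
    for j in jobs:
        per_field[j.field.field_id] = per_field.get(j.field.field_id, 0.0) + j.mu
    for f in plans[1].fields:
        assert per_field[f.field_id] == pytest.approx(f.mu)


def test_subsample_step_equal_to_length_keeps_last(plans):
    seq = plans[1].mlc_sequences["1"]
    sel = subsample_control_points(seq, step=len(seq))
    assert len(sel) == 1
    assert sel[0].index == seq[-1].index


def test_subsample_invalid_step(plans):
    seq = plans[1].mlc_sequences["1"]
    with pytest.raises(ValueError):
        subsample_control_points(seq, step=0)
    with pytest.raises(ValueError):
        subsample_control_points(seq[:3], step=5)


# -- apertures -------------------------------------------------------------

def test_static_aperture_is_jaw_rectangle(plans):
    f1 = plans[0].fields[0]
    ap = aperture_at(f1, None)
    assert ap.x_interval == (-1.6, 1.6)
    assert ap.y_interval == (-1.6, 1.6)
    assert ap.open_area() == pytest.approx(3.2 * 3.2)


def test_fully_retracted_leaves_equal_jaw_rectangle():
    f = _demo_field()
    mlc = default_mlc_model()
    cp = MLCControlPoint(
        index=1, mu_fraction=1.0,
        bank_a=np.full(60, -20.0), bank_b=np.full(60, 20.0),
    )
    ap = aperture_at(f, cp, mlc)
    assert ap.open_area() == pytest.approx(ap.jaw_area)


def test_single_open_pair_area_is_gap_times_leaf_width():
    f = BeamField(
        field_id="w", gantry=0.0, collimator=0.0, couch=0.0,
        x1=5.0, x2=5.0, y1=5.0, y2=5.0, ssd=100.0, mu=1.0,
    )
    mlc = default_mlc_model()
    a = np.zeros(60)
    b = np.zeros(60)
    b[29] = 1.0  # pair 30, a central 0.5 cm pair
    cp = MLCControlPoint(index=1, mu_fraction=1.0, bank_a=a, bank_b=b)
    ap = aperture_at(f, cp, mlc)
    ylo, yhi = mlc.pair_bounds(30)
    assert ap.open_area() == pytest.approx(1.0 * (yhi - ylo))


@given(
    gaps=st.lists(
        st.tuples(st.floats(-2.5, 2.5), st.floats(0.0, 2.5)),
        min_size=60, max_size=60,
    ),
    pair=st.integers(1, 60),
    retract=st.floats(0.1, 3.0),
)
def test_retracting_a_leaf_never_shrinks_the_aperture(gaps, pair, retract):
    f = _demo_field()
    mlc = default_mlc_model()
    a = np.array([min(lo, lo + w) for lo, w in gaps])
    b = np.array([lo + w for lo, w in gaps])
    cp = MLCControlPoint(index=1, mu_fraction=1.0, bank_a=a, bank_b=b)
    before = aperture_at(f, cp, mlc).open_area()
    a2 = a.copy()
    a2[pair - 1] -= retract  # retract one bank-A leaf
    cp2 = MLCControlPoint(index=1, mu_fraction=1.0, bank_a=a2, bank_b=b)
    after = aperture_at(f, cp2, mlc).open_area()
    assert after >= before - 1e-12


def test_angle_out_of_range_rejected():
    with pytest.raises(ValueError, match="gantry"):
        BeamField(
            field_id="bad", gantry=360.0, collimator=0.0, couch=0.0,
            x1=1.0, x2=1.0, y1=1.0, y2=1.0, ssd=100.0, mu=1.0,
        )
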