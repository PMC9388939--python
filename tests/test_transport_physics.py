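"""Physics validation of the transport engine against closed forms:
exponential slab attenuation, Klein-Nishina moments, the inverse-square
law, energy conservation and variance-reduction unbiasedness."""

import numpy as np
import pytest
from scipy import integrate

from oofdose.materials import get_material
from oofdose.phantom import OrganSpec, build_phantom
from oofdose.plan import BeamField, MLCControlPoint, aperture_at
from oofdose.transport import (
    CollimationModel,
    SourceModel,
    TransportConfig,
    _ELECTRON_REST_MEV,
    get_lattice,
    run_histories,
    sample_compton,
    sample_source_photon,
    transport_photon,
)

SEED = 424242


def water_slab_phantom(thickness=10.0):
    body = OrganSpec("slab", "box", (10.0, 10.0, thickness / 2), (0, 0, 0), "water", is_target=True)
    return build_phantom([], body, (40, 40, int(thickness * 2)), (0.5, 0.5, 0.5), (-10, -10, -thickness / 2))


def pencil_beam(n, energy=1.0, z_start=20.0, weight=1.0):
    pos = np.zeros((n, 3))
    pos[:, 2] = z_start
    d = np.tile([0.0, 0.0, -1.0], (n, 1))
    return pos, d, np.full(n, energy), np.full(n, weight)


# -- attenuation -----------------------------------------------------------

def test_slab_transmission_matches_exponential_attenuation():
    """In absorption-only mode the transmitted weight through a water
    slab equals e^(-mu t) within 3 sigma binomial error."""
    ph = water_slab_phantom(10.0)
    n = 100_000
    cfg = TransportConfig(mode="absorb", n_histories=n, seed=SEED)
    rng = np.random.default_rng(SEED)
    _, diag = transport_photon(ph, pencil_beam(n), cfg, rng)
    p = diag["escaped"] / diag["initial"]
    mu = get_material("water").mu(1.0) * get_material("water").density
    expected = np.exp(-mu * 10.0)
    sigma = np.sqrt(expected * (1 - expected) / n)
    assert abs(p - expected) < 3 * sigma


def test_energy_ledger_balances():
    """Deposited plus escaping energy equals the emitted energy, in
    both full and absorption-only modes."""
    ph = water_slab_phantom(10.0)
    for mode in ("absorb", "full"):
        cfg = TransportConfig(mode=mode, n_histories=20_000, seed=SEED)
        rng = np.random.default_rng(SEED + 1)
        _, diag = transport_photon(ph, pencil_beam(20_000, energy=3.0), cfg, rng)
        assert diag["deposited"] + diag["escaped"] == pytest.approx(diag["initial"], rel=1e-12)


def test_vacuum_phantom_deposits_nothing():
    body = OrganSpec("void", "box", (10.0, 10.0, 5.0), (0, 0, 0), "vacuum", is_target=True)
    ph = build_phantom([], body, (20, 20, 10), (1.0, 1.0, 1.0), (-10, -10, -5))
    cfg = TransportConfig(n_histories=1000, seed=SEED)
    rng = np.random.default_rng(SEED)
    tally, diag = transport_photon(ph, pencil_beam(1000), cfg, rng)
    assert tally.sum() == 0.0
    assert diag["escaped"] == pytest.approx(diag["initial"])


def test_sub_cutoff_photons_deposit_locally():
    ph = water_slab_phantom(10.0)
    cfg = TransportConfig(photon_cutoff=0.05, n_histories=100, seed=SEED)
    rng = np.random.default_rng(SEED)
    _, diag = transport_photon(ph, pencil_beam(100, energy=0.02), cfg, rng)
    assert diag["deposited"] == pytest.approx(diag["initial"])
    assert diag["escaped"] == 0.0


def test_non_finite_photon_state_raises():
    ph = water_slab_phantom(10.0)
    pos, d, e, w = pencil_beam(10)
    w[3] = np.nan
    cfg = TransportConfig(n_histories=10, seed=SEED)
    with pytest.raises(ValueError, match="non-finite"):
        transport_photon(ph, (pos, d, e, w), cfg, np.random.default_rng(SEED))


# -- Compton sampling ------------------------------------------------------

def _kn_pdf_weight(eps, alpha):
    # dsigma/deps up to a constant: eps + 1/eps - sin^2(theta(eps))
    cost = 1.0 - (1.0 / eps - 1.0) / alpha
    return eps + 1.0 / eps - (1.0 - cost**2)


def test_compton_energies_respect_the_edge():
    rng = np.random.default_rng(SEED)
    e = 1.0
    e_out, theta, phi = sample_compton(np.full(20_000, e), rng)
    eps_min = 1.0 / (1.0 + 2.0 * e / _ELECTRON_REST_MEV)
    assert np.all(e_out >= e * eps_min - 1e-12)
    assert np.all(e_out <= e + 1e-12)
    assert np.all((theta >= 0) & (theta <= np.pi))


def test_compton_mean_energy_matches_quadrature():
    """Sampled mean scattered-energy fraction at 1 MeV agrees with
    numerical quadrature of the Klein-Nishina spectrum within 3 sigma."""
    e = 1.0
    alpha = e / _ELECTRON_REST_MEV
    eps_min = 1.0 / (1.0 + 2.0 * alpha)
    norm, _ = integrate.quad(_kn_pdf_weight, eps_min, 1.0, args=(alpha,))
    first, _ = integrate.quad(lambda x: x * _kn_pdf_weight(x, alpha), eps_min, 1.0, args=())
    expected = first / norm
    rng = np.random.default_rng(SEED)
    n = 1_000_000
    e_out, _, _ = sample_compton(np.full(n, e), rng)
    eps = e_out / e
    se = eps.std(ddof=1) / np.sqrt(n)
    assert abs(eps.mean() - expected) < 3 * se


def test_compton_thomson_limit():
    """As E -> 0 the mean energy loss fraction vanishes."""
    rng = np.random.default_rng(SEED)
    e_out, _, _ = sample_compton(np.full(50_000, 1e-3), rng)
    assert 1.0 - (e_out / 1e-3).mean() < 0.01


# -- source sampling -------------------------------------------------------

def _open_field(x=5.0, y=5.0):
    return BeamField(
        field_id="ref", gantry=0.0, collimator=0.0, couch=0.0,
        x1=x, x2=x, y1=y, y2=y, ssd=100.0, mu=1.0,
    )


def test_closed_aperture_without_transmission_gives_zero_weight():
    f = _open_field()
    closed = MLCControlPoint(
        index=1, mu_fraction=1.0, bank_a=np.zeros(60), bank_b=np.zeros(60)
    )
    col = CollimationModel(
        aperture=aperture_at(f, closed),
        mlc_transmission=0.0, jaw_transmission=0.0, head_leakage_fraction=0.0,
    )
    rng = np.random.default_rng(SEED)
    _, _, _, w = sample_source_photon(SourceModel(spectrum=2.0), col, rng, 5000)
    assert np.all(w == 0.0)


def test_monoenergetic_source():
    col = CollimationModel(aperture=aperture_at(_open_field(), None))
    rng = np.random.default_rng(SEED)
    _, _, e, _ = sample_source_photon(SourceModel(spectrum=2.0), col, rng, 1000)
    assert np.all(e == 2.0)


def test_open_fraction_matches_aperture_area_ratio():
    """The full-weight fraction of sampled photons matches the open
    aperture's share of the sampling box within 3 sigma."""
    f = _open_field(5.0, 5.0)
    ap = aperture_at(f, None)
    col = CollimationModel(
        aperture=ap, mlc_transmission=0.0, jaw_transmission=0.0,
        head_leakage_fraction=0.0, sampling_margin_cm=1.0,
    )
    rng = np.random.default_rng(SEED)
    n = 100_000
    _, _, _, w = sample_source_photon(SourceModel(spectrum=2.0), col, rng, n)
    p_open = (w > 0).mean()
    expected = ap.open_area() / (12.0 * 12.0)
    sigma = np.sqrt(expected * (1 - expected) / n)
    assert abs(p_open - expected) < 3 * sigma


# -- inverse square --------------------------------------------------------

def test_inverse_square_law_in_air():
    """Kerma in small air detectors at d and 2d from an isotropic point
    source falls off as 1/r^2 within 3 sigma."""
    body = OrganSpec("airbox", "box", (17.5, 17.5, 17.5), (0, 0, 0), "air", is_target=True)
    near = OrganSpec("near", "ellipsoid", (1.5, 1.5, 1.5), (0.0, 0.0, -7.5), "air")
    far = OrganSpec("far", "ellipsoid", (1.5, 1.5, 1.5), (0.0, 0.0, -15.0), "air")
    ph = build_phantom([near, far], body, (70, 70, 70), (0.5, 0.5, 0.5), (-17.5, -17.5, -17.5))
    lat = get_lattice(ph)
    rng = np.random.default_rng(SEED)
    n_batches, n = 20, 30_000
    cfg = TransportConfig(n_histories=n, seed=SEED)
    ratios_num, ratios_den = np.empty(n_batches), np.empty(n_batches)
    for b in range(n_batches):
        cost = rng.uniform(-1, 1, n)
        sint = np.sqrt(1 - cost**2)
        phi = rng.uniform(0, 2 * np.pi, n)
        d = np.column_stack([sint * np.cos(phi), sint * np.sin(phi), cost])
        pos = np.zeros((n, 3))
        tally, _ = run_histories(lat, pos, d, np.full(n, 1.0), np.ones(n), cfg, rng)
        ratios_num[b] = tally[ph.label_of("near")]
        ratios_den[b] = tally[ph.label_of("far")]
    num, den = ratios_num.mean(), ratios_den.mean()
    ratio = num / den
    rel_se = np.sqrt(
        (ratios_num.std(ddof=1) / np.sqrt(n_batches) / num) ** 2
        + (ratios_den.std(ddof=1) / np.sqrt(n_batches) / den) ** 2
    )
    assert ratio == pytest.approx(4.0, rel=3 * rel_se + 0.03)


# -- variance reduction ----------------------------------------------------

def test_roulette_and_splitting_leave_tallies_unbiased():
    """A low-weight beam through a water slab tallies the same deep
    dose with and without Russian roulette + splitting, within 3 sigma."""
    ph = water_slab_phantom(10.0)
    deep = OrganSpec("deep", "box", (10.0, 10.0, 1.0), (0.0, 0.0, -3.5), "water")
    body = OrganSpec("slab", "box", (10.0, 10.0, 5.0), (0, 0, 0), "water", is_target=True)
    ph = build_phantom([deep], body, (40, 40, 20), (0.5, 0.5, 0.5), (-10, -10, -5))
    lat = get_lattice(ph)
    lab = ph.label_of("deep")

    def run(cfg, seed):
        rng = np.random.default_rng(seed)
        n_b, n = 20, 10_000
        vals = np.empty(n_b)
        for b in range(n_b):
            tally, _ = run_histories(
                lat, *pencil_beam(n, energy=2.0, weight=0.02), cfg, rng
            )
            vals[b] = tally[lab]
        return vals.mean(), vals.std(ddof=1) / np.sqrt(n_b)

    plain = TransportConfig(n_histories=1, seed=SEED, rr_weight_threshold=0.0)
    vr = TransportConfig(
        n_histories=1, seed=SEED,
        rr_weight_threshold=0.05, rr_survival=0.3,
        split_weight_threshold=0.08, split_factor=2,
    )
    m_plain, se_plain = run(plain, SEED)
    m_vr, se_vr = run(vr, SEED + 1)
    assert abs(m_plain - m_vr) < 3 * np.hypot(se_plain, se_vr)
    assert m_vr > 0
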