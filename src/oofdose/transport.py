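"""Simplified Monte Carlo photon transport with per-organ kerma tallies.

The engine emulates the out-of-field dose calculation chain of a
6 MV linac treatment at desk scale:

* a parametric point-ish source 100 cm from the isocenter fires
  photons at the isocenter plane, importance-sampled over the jaw
  bounding box (plus margin); photons aimed at jaw- or MLC-blocked
  regions carry the corresponding transmission factor as statistical
  weight, and a configurable fraction of histories is emitted as
  isotropic head leakage instead;
* voxel transport uses Woodcock delta-tracking against an
  energy-dependent majorant cross-section, with Compton scattering
  (Klein-Nishina), photoelectric absorption and pair production
  (above 1.022 MeV, two back-to-back 511 keV annihilation photons);
* organ doses are scored with a track-length kerma estimator
  (fluence x E x muen/rho accumulated at every delta-tracking
  collision), i.e. charged particles are assumed to deposit their
  energy locally - the same electronic-equilibrium assumption the TLD
  reduction chain makes.  Electrons are never transported.
* Russian roulette (below a weight threshold) and splitting (above
  one) are available as an unbiased variance-reduction pair, and
  tallies are batched (20 batches by default) for a 1-sigma relative
  standard error per organ.

Absolute doses are obtained by normalizing the per-particle tallies
with a conversion factor (CF) calibrated under reference conditions:
10 x 10 cm field, MLC retracted, SSD 100 cm on a water phantom, with a
configurable reference dose per monitor unit at 10 cm depth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .materials import Material
from .phantom import VoxelPhantom, build_phantom, OrganSpec
from .plan import Aperture, BeamField, MLCModel, SimJob, TreatmentPlan, aperture_at, default_mlc_model, make_job_list

__all__ = [
    "SourceModel",
    "CollimationModel",
    "TransportConfig",
    "TallyResult",
    "CalibrationResult",
    "DoseReport",
    "default_6mv_spectrum",
    "sample_source_photon",
    "sample_compton",
    "transport_photon",
    "run_beam",
    "run_histories",
    "calibrate_cf",
    "simulate_plan",
    "field_transform",
]

_ELECTRON_REST_MEV = 0.510998
_PAIR_THRESHOLD_MEV = 2.0 * _ELECTRON_REST_MEV
_RE_CM = 2.8179403e-13  # classical electron radius
_N_AVOGADRO = 6.02214076e23


# ---------------------------------------------------------------------------
# Models / configuration

def default_6mv_spectrum(n_bins: int = 48) -> np.ndarray:
    """Parametric 6 MV bremsstrahlung-like spectrum, (N, 2) of
    (energy MeV, probability).  Gamma-shaped fluence peaking near
    0.9 MeV with mean ~1.7 MeV, truncated to [0.1, 6.0] MeV."""
    edges = np.linspace(0.1, 6.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = centers * np.exp(-centers / 0.9) * np.diff(edges)
    return np.column_stack([centers, w / w.sum()])


@dataclass(frozen=True)
class SourceModel:
    """Photon source 100 cm from the isocenter on the beam axis."""

    sad: float = 100.0  # source-axis distance, cm
    focal_spot_fwhm_mm: float = 1.2
    spectrum: float | np.ndarray = field(default_factory=default_6mv_spectrum)

    def __post_init__(self) -> None:
        spec = self.spectrum
        if np.ndim(spec) == 0:
            if not (0.01 < float(spec) <= 7.0):
                raise ValueError("monoenergetic source energy outside (0.01, 7.0] MeV")
        else:
            spec = np.asarray(spec, dtype=float)
            if np.any(spec[:, 0] <= 0.01) or np.any(spec[:, 0] > 7.0):
                raise ValueError("spectrum energies outside (0.01, 7.0] MeV")
            if abs(spec[:, 1].sum() - 1.0) > 1e-9:
                raise ValueError("spectrum probabilities must sum to 1")
            object.__setattr__(self, "spectrum", spec)

    def sample_energy(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if np.ndim(self.spectrum) == 0:
            return np.full(n, float(self.spectrum))
        spec = self.spectrum
        idx = rng.choice(len(spec), size=n, p=spec[:, 1])
        return spec[idx, 0]


@dataclass(frozen=True)
class CollimationModel:
    """Parametric surrogate for the treatment head: an aperture at the
    isocenter plane plus bulk transmission/leakage fractions."""

    aperture: Aperture | None = None
    mlc_transmission: float = 0.017
    jaw_transmission: float = 0.002
    head_leakage_fraction: float = 0.001
    sampling_margin_cm: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mlc_transmission", "jaw_transmission", "head_leakage_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.mlc_transmission < self.jaw_transmission:
            import warnings

            warnings.warn("MLC transmission below jaw transmission is unusual", stacklevel=2)


@dataclass(frozen=True)
class TransportConfig:
    photon_cutoff: float = 0.01  # MeV; photons below deposit locally
    n_histories: int = 100_000
    rr_weight_threshold: float = 1e-4
    rr_survival: float = 0.4
    split_factor: int = 2
    split_weight_threshold: float = math.inf  # splitting off by default
    batches: int = 20
    seed: int = 0
    mode: str = "full"  # "full" | "absorb" (absorption-only test mode)
    max_steps: int = 50_000
    # Optional lower bound on the delta-tracking majorant (cm^-1).
    # Forcing extra virtual collisions densifies the track-length
    # kerma scoring in thin regions at proportional CPU cost; it does
    # not bias the transport (any majorant >= mu is valid).
    majorant_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.photon_cutoff < 0.01:
            raise ValueError("photon cutoff below the 0.01 MeV table floor")
        if self.batches < 10:
            raise ValueError("need >= 10 batches for the batch error estimate")
        if not (0.0 < self.rr_survival <= 1.0):
            raise ValueError("rr_survival must be in (0, 1]")
        if self.split_factor < 1:
            raise ValueError("split_factor must be >= 1")
        if self.mode not in ("full", "absorb"):
            raise ValueError(f"unknown transport mode {self.mode!r}")


@dataclass
class TallyResult:
    """Per-organ dose per source particle with batch statistics."""

    organs: list[str]
    dose_per_particle: dict[str, float]  # MeV/g per source particle
    rel_se: dict[str, float]  # 1-sigma relative standard error
    histories: int
    batches: int
    diagnostics: dict = field(default_factory=dict)

    def dose(self, organ: str) -> float:
        return self.dose_per_particle[organ]

    def se_flags(self) -> dict[str, bool]:
        """True where the batch SE is undefined (fewer than 2 nonzero
        batch means) - flagged, never silently zero."""
        return {o: not np.isfinite(self.rel_se[o]) for o in self.organs}


@dataclass(frozen=True)
class CalibrationResult:
    cf: float  # mGy per (MeV/g per particle) per MU
    reference: str = "10x10 cm, MLC retracted, SSD 100 cm, water, 10 cm depth"

    def __post_init__(self) -> None:
        if not (self.cf > 0):
            raise ValueError("conversion factor must be positive")


@dataclass
class DoseReport:
    """Absolute per-organ dose (mGy) for a full prescribed course."""

    technique: str
    plan_id: str
    organ_dose_mgy: dict[str, float]
    organ_unc_mgy: dict[str, float]
    n_fractions: int
    histories: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "organ": list(self.organ_dose_mgy),
                "dose_mgy": list(self.organ_dose_mgy.values()),
                "uncertainty_mgy": [self.organ_unc_mgy[o] for o in self.organ_dose_mgy],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "technique": self.technique,
                "plan_id": self.plan_id,
                "n_fractions": self.n_fractions,
                "histories": self.histories,
                "organ_dose_mgy": self.organ_dose_mgy,
                "organ_unc_mgy": self.organ_unc_mgy,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DoseReport":
        d = json.loads(text)
        return cls(
            technique=d["technique"],
            plan_id=d["plan_id"],
            organ_dose_mgy=d["organ_dose_mgy"],
            organ_unc_mgy=d["organ_unc_mgy"],
            n_fractions=d["n_fractions"],
            histories=d.get("histories", 0),
        )


# ---------------------------------------------------------------------------
# Cross-section lattice

def _sigma_kn_total(energy: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross-section per electron, cm^2."""
    a = np.asarray(energy, dtype=float) / _ELECTRON_REST_MEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * _RE_CM**2 * (t1 + t2 - t3)


class TransportLattice:
    """Precomputed per-material linear-coefficient lookup tables on a
    dense log-energy grid, plus the flattened voxel arrays."""

    def __init__(self, phantom: VoxelPhantom, n_energy: int = 256):
        self.phantom = phantom
        self.dims = np.asarray(phantom.dims)
        self.origin = phantom.origin
        self.voxel_size = phantom.voxel_size
        self.mat_flat = phantom.material_index.ravel()
        self.org_flat = phantom.organ_label.ravel()
        self.n_labels = int(self.org_flat.max()) + 1
        self.label_names = dict(phantom.label_names)

        e = np.geomspace(0.01, 7.0, n_energy)
        self.ln_e0 = np.log(e[0])
        self.dln = np.log(e[1] / e[0])
        self.n_energy = n_energy
        mats = phantom.materials
        self.mu_lin = np.empty((len(mats), n_energy))
        self.muen_lin = np.empty((len(mats), n_energy))
        self.compton_lin = np.empty((len(mats), n_energy))
        for i, m in enumerate(mats):
            self.mu_lin[i] = m.mu(e) * m.density
            self.muen_lin[i] = m.muen(e) * m.density
            e_dens = m.density * m.z_over_a * _N_AVOGADRO  # electrons / cm^3
            self.compton_lin[i] = np.minimum(e_dens * _sigma_kn_total(e), self.mu_lin[i])
        self.majorant = self.mu_lin.max(axis=0)
        self.vacuum_like = bool(np.all(self.majorant < 1e-12))

        dens = np.array([m.density for m in mats])
        vox_mass = dens[self.mat_flat] * phantom.voxel_volume
        self.organ_mass = np.bincount(self.org_flat, weights=vox_mass, minlength=self.n_labels)

    def e_index(self, energy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = (np.log(energy) - self.ln_e0) / self.dln
        t = np.clip(t, 0.0, self.n_energy - 1.000001)
        i = t.astype(np.int64)
        return i, t - i

    def lookup(self, table: np.ndarray, mat: np.ndarray, i: np.ndarray, f: np.ndarray) -> np.ndarray:
        return table[mat, i] * (1.0 - f) + table[mat, i + 1] * f

    def majorant_at(self, i: np.ndarray, f: np.ndarray) -> np.ndarray:
        return self.majorant[i] * (1.0 - f) + self.majorant[i + 1] * f


def get_lattice(phantom: VoxelPhantom) -> TransportLattice:
    lat = getattr(phantom, "_transport_lattice", None)
    if lat is None:
        lat = TransportLattice(phantom)
        phantom._transport_lattice = lat
    return lat


# ---------------------------------------------------------------------------
# Sampling

def sample_compton(energy, rng: np.random.Generator):
    """Sample Klein-Nishina Compton scattering.

    Returns (scattered energy MeV, polar angle rad, azimuth rad) with
    the same shape as ``energy``.  Uses Kahn's composition-rejection
    method, valid at all energies.
    """
    e = np.atleast_1d(np.asarray(energy, dtype=float))
    scalar = np.ndim(energy) == 0
    a = e / _ELECTRON_REST_MEV
    x = np.empty_like(e)  # x = E / E'
    todo = np.ones(e.shape, dtype=bool)
    while todo.any():
        n = int(todo.sum())
        at = a[todo]
        r1, r2, r3 = rng.random(n), rng.random(n), rng.random(n)
        branch1 = r1 <= (1 + 2 * at) / (9 + 2 * at)
        xt = np.where(branch1, 1 + 2 * at * r2, (1 + 2 * at) / (1 + 2 * at * r2))
        cost = 1 - (xt - 1) / at
        acc1 = r3 <= 4 * (1 / xt - 1 / xt**2)
        acc2 = r3 <= 0.5 * (cost**2 + 1 / xt)
        accept = np.where(branch1, acc1, acc2)
        idx = np.nonzero(todo)[0][accept]
        x[idx] = xt[accept]
        todo[idx] = False
    eps = 1.0 / x
    cost = np.clip(1 - (x - 1) / a, -1.0, 1.0)
    theta = np.arccos(cost)
    phi = rng.uniform(0.0, 2 * np.pi, size=e.shape)
    e_out = e * eps
    if scalar:
        return float(e_out[0]), float(theta[0]), float(phi[0])
    return e_out, theta, phi


def _rotate(direction: np.ndarray, cost: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors by polar angle (cos theta) about themselves
    with azimuth phi."""
    d = direction
    sint = np.sqrt(np.maximum(0.0, 1.0 - cost**2))
    # Build an orthonormal frame avoiding degeneracy at |dz| ~ 1.
    helper = np.zeros_like(d)
    use_z = np.abs(d[:, 2]) < 0.99
    helper[use_z, 2] = 1.0
    helper[~use_z, 0] = 1.0
    e1 = np.cross(helper, d)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    out = (
        cost[:, None] * d
        + sint[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _isotropic(rng: np.random.Generator, n: int, hemisphere_down: bool = False) -> np.ndarray:
    cost = rng.uniform(-1.0, 1.0, n)
    if hemisphere_down:
        cost = -np.abs(cost)
    sint = np.sqrt(1.0 - cost**2)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    return np.column_stack([sint * np.cos(phi), sint * np.sin(phi), cost])


def sample_source_photon(
    source: SourceModel,
    collimation: CollimationModel,
    rng: np.random.Generator,
    n: int = 1,
):
    """Sample source photons in the *beam* frame.

    Beam frame: source near (0, 0, sad), beam axis -z toward the
    isocenter plane z = 0.  Primary photons aim at points uniformly
    covering the jaw bounding box plus margin; those aimed at blocked
    regions carry the jaw/MLC transmission as weight.  With
    probability ``head_leakage_fraction`` a photon is emitted
    isotropically (downward hemisphere) from the source instead.

    Returns (position (n,3), direction (n,3), energy (n,), weight (n,)).
    """
    ap = collimation.aperture
    sigma_cm = source.focal_spot_fwhm_mm / 10.0 / 2.35482
    spot = np.zeros((n, 3))
    spot[:, 0] = rng.normal(0.0, sigma_cm, n)
    spot[:, 1] = rng.normal(0.0, sigma_cm, n)
    spot[:, 2] = source.sad
    energy = source.sample_energy(rng, n)

    leak = rng.random(n) < collimation.head_leakage_fraction
    weight = np.ones(n)
    direction = np.empty((n, 3))

    if ap is None:
        # Uncollimated: everything is leakage-style isotropic emission.
        direction = _isotropic(rng, n, hemisphere_down=True)
        return spot, direction, energy, weight

    xlo, xhi, ylo, yhi = ap.bounding_box(collimation.sampling_margin_cm)
    # Photons are importance-sampled over the jaw bounding box, so a
    # history's base weight carries the sampled fluence area relative
    # to the 10 x 10 cm reference: tallies are then per unit primary
    # fluence and comparable across field sizes (and to the CF
    # reference geometry).
    base = (xhi - xlo) * (yhi - ylo) / 100.0
    tx = rng.uniform(xlo, xhi, n)
    ty = rng.uniform(ylo, yhi, n)
    code = ap.classify(tx, ty)
    weight = base * np.where(
        code == 0, 1.0, np.where(code == 1, collimation.mlc_transmission, collimation.jaw_transmission)
    )
    target = np.column_stack([tx, ty, np.zeros(n)])
    d = target - spot
    direction = d / np.linalg.norm(d, axis=1, keepdims=True)

    n_leak = int(leak.sum())
    if n_leak:
        # Leakage replaces the primary history at the base (unblocked)
        # weight, emitted isotropically into the lower hemisphere.
        direction[leak] = _isotropic(rng, n_leak, hemisphere_down=True)
        weight[leak] = base
    return spot, direction, energy, weight


# ---------------------------------------------------------------------------
# Core transport

def _advance_to_box(pos, direction, lo, hi):
    """Move photons outside the grid AABB to their entry point (plus a
    small epsilon); returns (pos, hit) where ``hit`` is False for rays
    that miss the box entirely."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / direction
        t1 = (lo - pos) * inv
        t2 = (hi - pos) * inv
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    hit = (tmax > np.maximum(tmin, 0.0)) | np.all((pos > lo) & (pos < hi), axis=1)
    t_entry = np.clip(tmin, 0.0, None)
    moved = pos + direction * (t_entry[:, None] + 1e-9)
    inside_already = np.all((pos > lo) & (pos < hi), axis=1)
    out = np.where(inside_already[:, None], pos, moved)
    return out, hit


def run_histories(
    lattice: TransportLattice,
    pos: np.ndarray,
    direction: np.ndarray,
    energy: np.ndarray,
    weight: np.ndarray,
    config: TransportConfig,
    rng: np.random.Generator,
):
    """Transport a bank of photons to extinction.

    Returns ``(organ_energy, diagnostics)`` where ``organ_energy[l]``
    is the track-length-estimated energy (MeV, statistical-weighted)
    released in organ label ``l`` and diagnostics carries the analog
    energy ledger (initial / deposited / escaped, all in weighted MeV).
    """
    pos = np.array(pos, dtype=float)
    direction = np.array(direction, dtype=float)
    energy = np.array(energy, dtype=float)
    weight = np.array(weight, dtype=float)
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(weight))):
        raise ValueError("non-finite photon position or weight entering transport")

    organ_e = np.zeros(lattice.n_labels)
    initial = float((weight * energy).sum())
    deposited = 0.0
    escaped = 0.0

    # Drop zero-weight or sub-cutoff photons outright.
    alive = (weight > 0) & (energy >= config.photon_cutoff)
    deposited += float((weight[~alive] * energy[~alive]).sum())
    pos, direction, energy, weight = pos[alive], direction[alive], energy[alive], weight[alive]

    if lattice.vacuum_like:
        # No interaction anywhere: everything escapes.
        return organ_e, {"initial": initial, "deposited": deposited,
                         "escaped": initial - deposited, "steps": 0}

    # Photons emitted away from the grid fly in vacuum until they reach
    # the grid bounding box; rays that miss it escape outright.
    lo = lattice.origin
    hi = lattice.origin + lattice.dims * lattice.voxel_size
    pos, hit = _advance_to_box(pos, direction, lo, hi)
    escaped += float((weight[~hit] * energy[~hit]).sum())
    pos, direction, energy, weight = pos[hit], direction[hit], energy[hit], weight[hit]

    inv_vox = 1.0 / lattice.voxel_size
    dims = lattice.dims
    steps = 0
    while pos.shape[0]:
        steps += 1
        if steps > config.max_steps:
            raise RuntimeError("transport exceeded the step guard (simulation bug trap)")
        n = pos.shape[0]
        ei, ef = lattice.e_index(energy)
        smaj = lattice.majorant_at(ei, ef)
        if config.majorant_floor > 0.0:
            smaj = np.maximum(smaj, config.majorant_floor)
        flight = -np.log(rng.random(n)) / smaj
        pos = pos + direction * flight[:, None]

        ijk = np.floor((pos - lattice.origin) * inv_vox).astype(np.int64)
        inside = np.all((ijk >= 0) & (ijk < dims), axis=1)
        if not inside.all():
            escaped += float((weight[~inside] * energy[~inside]).sum())
            pos, direction, energy, weight = pos[inside], direction[inside], energy[inside], weight[inside]
            ijk, smaj, ei, ef = ijk[inside], smaj[inside], ei[inside], ef[inside]
            n = pos.shape[0]
            if n == 0:
                break
        flat = (ijk[:, 0] * dims[1] + ijk[:, 1]) * dims[2] + ijk[:, 2]
        mat = lattice.mat_flat[flat]
        org = lattice.org_flat[flat]

        mu = lattice.lookup(lattice.mu_lin, mat, ei, ef)
        muen = lattice.lookup(lattice.muen_lin, mat, ei, ef)
        # Track-length kerma estimator at every delta-tracking collision:
        # expected track length per collision is 1/Sigma_maj, so the
        # energy released per collision is w * E * muen_lin / Sigma_maj.
        np.add.at(organ_e, org, weight * energy * muen / smaj)

        real = rng.random(n) * smaj < mu
        if real.any():
            if config.mode == "absorb":
                deposited += float((weight[real] * energy[real]).sum())
                keep = ~real
                pos, direction, energy, weight = pos[keep], direction[keep], energy[keep], weight[keep]
            else:
                r_idx = np.nonzero(real)[0]
                mu_r = mu[r_idx]
                comp = lattice.lookup(lattice.compton_lin, mat[r_idx], ei[r_idx], ef[r_idx])
                is_c = rng.random(len(r_idx)) < comp / mu_r
                # Compton scatter
                c_idx = r_idx[is_c]
                if c_idx.size:
                    e_new, theta, phi = sample_compton(energy[c_idx], rng)
                    deposited += float((weight[c_idx] * (energy[c_idx] - e_new)).sum())
                    energy[c_idx] = e_new
                    direction[c_idx] = _rotate(direction[c_idx], np.cos(theta), phi)
                # Photoelectric / pair for the remainder
                o_idx = r_idx[~is_c]
                pairs = o_idx[energy[o_idx] > _PAIR_THRESHOLD_MEV]
                pe = o_idx[energy[o_idx] <= _PAIR_THRESHOLD_MEV]
                deposited += float((weight[pe] * energy[pe]).sum())
                new_pos = new_dir = new_e = new_w = None
                if pairs.size:
                    deposited += float((weight[pairs] * (energy[pairs] - _PAIR_THRESHOLD_MEV)).sum())
                    ann_dir = _isotropic(rng, len(pairs))
                    # Parent becomes one annihilation photon; the
                    # back-to-back partner is appended to the bank.
                    energy[pairs] = _ELECTRON_REST_MEV
                    direction[pairs] = ann_dir
                    new_pos = pos[pairs].copy()
                    new_dir = -ann_dir
                    new_e = np.full(len(pairs), _ELECTRON_REST_MEV)
                    new_w = weight[pairs].copy()
                keep = np.ones(n, dtype=bool)
                keep[pe] = False
                pos, direction, energy, weight = pos[keep], direction[keep], energy[keep], weight[keep]
                if new_pos is not None:
                    pos = np.concatenate([pos, new_pos])
                    direction = np.concatenate([direction, new_dir])
                    energy = np.concatenate([energy, new_e])
                    weight = np.concatenate([weight, new_w])

        # Energy cutoff: residual local deposit.
        low = energy < config.photon_cutoff
        if low.any():
            deposited += float((weight[low] * energy[low]).sum())
            keep = ~low
            pos, direction, energy, weight = pos[keep], direction[keep], energy[keep], weight[keep]

        # Russian roulette.
        if pos.shape[0]:
            rr = weight < config.rr_weight_threshold
            if rr.any():
                survive = rng.random(pos.shape[0]) < config.rr_survival
                kill = rr & ~survive
                weight = np.where(rr & survive, weight / config.rr_survival, weight)
                if kill.any():
                    keep = ~kill
                    pos, direction, energy, weight = pos[keep], direction[keep], energy[keep], weight[keep]

        # Splitting.
        if pos.shape[0] and np.isfinite(config.split_weight_threshold) and config.split_factor > 1:
            heavy = weight > config.split_weight_threshold
            if heavy.any():
                k = config.split_factor
                weight[heavy] /= k
                rep_pos = np.repeat(pos[heavy], k - 1, axis=0)
                rep_dir = np.repeat(direction[heavy], k - 1, axis=0)
                rep_e = np.repeat(energy[heavy], k - 1)
                rep_w = np.repeat(weight[heavy], k - 1)
                pos = np.concatenate([pos, rep_pos])
                direction = np.concatenate([direction, rep_dir])
                energy = np.concatenate([energy, rep_e])
                weight = np.concatenate([weight, rep_w])

        if not np.all(np.isfinite(weight)) or not np.all(np.isfinite(pos)):
            raise ValueError("non-finite photon weight or position (simulation bug trap)")

    return organ_e, {
        "initial": initial,
        "deposited": deposited,
        "escaped": escaped,
        "steps": steps,
    }


def transport_photon(phantom, photons, config: TransportConfig, rng, tally=None):
    """Transport a photon bank through a phantom, accumulating an
    organ-energy tally.

    ``photons`` is a (pos, direction, energy, weight) tuple of arrays
    in patient coordinates.  Returns ``(tally, diagnostics)`` with
    ``tally`` a (n_labels,) array of weighted MeV per organ label,
    added to the passed-in tally when one is given.
    """
    lattice = get_lattice(phantom)
    pos, direction, energy, weight = photons
    organ_e, diag = run_histories(lattice, pos, direction, energy, weight, config, rng)
    if tally is not None:
        organ_e = organ_e + tally
    return organ_e, diag


# ---------------------------------------------------------------------------
# Field geometry

def _rot_z(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


# Base beam frame: beam axis z maps to patient +y (gantry 0 = beam from
# anterior, supine patient), beam x to patient x.
_BASE = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])


def field_transform(beam_field: BeamField) -> np.ndarray:
    """3x3 matrix mapping beam-frame vectors to patient coordinates.

    Gantry rotates the beam about the patient's superior-inferior axis
    (z), collimator about the beam axis, couch about the vertical
    (anterior) axis.
    """
    return _rot_y(-beam_field.couch) @ _rot_z(-beam_field.gantry) @ _BASE @ _rot_z(beam_field.collimator)


def run_beam(
    phantom: VoxelPhantom,
    beam_field: BeamField,
    aperture: Aperture | None,
    source: SourceModel,
    collimation: CollimationModel,
    config: TransportConfig,
) -> TallyResult:
    """Simulate one static field (or leaf snapshot) and tally per-organ
    dose per source particle with batch-based standard errors."""
    lattice = get_lattice(phantom)
    if aperture is None:
        aperture = aperture_at(beam_field, None)
    collim = replace(collimation, aperture=aperture)
    M = field_transform(beam_field)

    n_batch = max(1, config.n_histories // config.batches)
    rng = np.random.default_rng(config.seed)
    batch_dose = np.zeros((config.batches, lattice.n_labels))
    diag_total = {"initial": 0.0, "deposited": 0.0, "escaped": 0.0}
    for b in range(config.batches):
        pos_b, dir_b, e_b, w_b = sample_source_photon(source, collim, rng, n_batch)
        pos_p = pos_b @ M.T
        dir_p = dir_b @ M.T
        organ_e, diag = run_histories(lattice, pos_p, dir_p, e_b, w_b, config, rng)
        with np.errstate(divide="ignore", invalid="ignore"):
            batch_dose[b] = np.where(lattice.organ_mass > 0, organ_e / lattice.organ_mass, 0.0) / n_batch
        for k in diag_total:
            diag_total[k] += diag[k]

    mean = batch_dose.mean(axis=0)
    se = batch_dose.std(axis=0, ddof=1) / math.sqrt(config.batches)
    organs = [lattice.label_names.get(l, f"label{l}") for l in range(lattice.n_labels)]
    dose = {}
    rel = {}
    for l, name in enumerate(organs):
        if l not in lattice.label_names:
            continue
        dose[name] = float(mean[l])
        nonzero = int((batch_dose[:, l] > 0).sum())
        if nonzero >= 2 and mean[l] > 0:
            rel[name] = float(se[l] / mean[l])
        else:
            rel[name] = float("nan")  # flagged: SE undefined
    return TallyResult(
        organs=list(dose),
        dose_per_particle=dose,
        rel_se=rel,
        histories=n_batch * config.batches,
        batches=config.batches,
        diagnostics=diag_total,
    )


# ---------------------------------------------------------------------------
# Calibration and plan simulation

def _reference_water_phantom() -> VoxelPhantom:
    """Water phantom for CF calibration: surface at the isocenter plane
    (SSD 100 cm for a 100 cm SAD source), scoring the central in-field
    region (8 x 8 x 1 cm, well inside the 10 x 10 cm field) at 10 cm
    depth on the beam axis."""
    dims = (60, 60, 50)
    voxel = (0.5, 0.5, 0.5)
    origin = (-15.0, -15.0, -25.0)  # tank surface exactly at z = 0
    body = OrganSpec("water_tank", "box", (15.0, 15.0, 12.5), (0.0, 0.0, -12.5), "water")
    ref = OrganSpec(
        "reference_region", "box", (4.0, 4.0, 0.5), (0.0, 0.0, -10.0), "water", is_target=True
    )
    return build_phantom([ref], body, dims, voxel, origin)


def calibrate_cf(
    source: SourceModel,
    collimation: CollimationModel,
    config: TransportConfig,
    calibration_dose_mgy_per_mu: float = 10.0,
) -> CalibrationResult:
    """Determine the conversion factor mapping per-particle tallies to
    absolute dose.

    Reference conditions: 10 x 10 cm field with the MLC retracted,
    SSD 100 cm on a water phantom; the scoring point on the central
    axis at 10 cm depth is assigned ``calibration_dose_mgy_per_mu``
    (default 10 mGy/MU)."""
    ref_field = BeamField(
        field_id="reference", gantry=0.0, collimator=0.0, couch=0.0,
        x1=5.0, x2=5.0, y1=5.0, y2=5.0, ssd=100.0, mu=1.0,
    )
    # Beam enters from anterior (gantry 0); the reference phantom is
    # built with its surface at the isocenter plane along the beam
    # axis, so rotate the phantom frame: build in beam coordinates.
    phantom = _reference_water_phantom()
    lattice = get_lattice(phantom)
    aperture = aperture_at(ref_field, None)
    collim = replace(collimation, aperture=aperture, head_leakage_fraction=0.0)
    # Densify the track-length scoring in the 1 cm-thick reference
    # region unless the caller chose a floor already.
    run_cfg = config if config.majorant_floor > 0 else replace(config, majorant_floor=0.25)
    rng = np.random.default_rng(config.seed)
    n = config.n_histories
    pos, direction, energy, weight = sample_source_photon(source, collim, rng, n)
    organ_e, _ = run_histories(lattice, pos, direction, energy, weight, run_cfg, rng)
    lab = phantom.label_of("reference_region")
    tally = organ_e[lab] / lattice.organ_mass[lab] / n  # MeV/g per particle
    if tally <= 0:
        raise ValueError("zero reference tally; cannot calibrate")
    return CalibrationResult(cf=calibration_dose_mgy_per_mu / tally)


def simulate_plan(
    phantom: VoxelPhantom,
    plan: TreatmentPlan,
    source: SourceModel,
    config: TransportConfig,
    collimation: CollimationModel | None = None,
    cf: CalibrationResult | None = None,
    step: int = 5,
    mlc_model: MLCModel | None = None,
    min_histories_per_job: int = 2000,
) -> DoseReport:
    """Simulate a full plan and report absolute organ doses in mGy for
    the prescribed course.

    ``config.n_histories`` is the total budget, divided evenly over
    the job list (one job per static field; one per subsampled control
    point for dynamic fields).  Organ dose is the MU- and CF-weighted
    sum of per-job tallies times the number of fractions."""
    plan.validate()
    jobs = make_job_list(plan, step=step)
    if cf is None:
        cal_cfg = replace(config, n_histories=max(100_000, config.n_histories // 10))
        cf = calibrate_cf(source, collimation or CollimationModel(), cal_cfg)
    collimation = collimation or CollimationModel()
    n_job = max(min_histories_per_job, config.n_histories // max(1, len(jobs)))
    mlc_model = mlc_model or default_mlc_model()

    seeds = np.random.SeedSequence(config.seed).spawn(len(jobs))
    dose: dict[str, float] = {}
    var: dict[str, float] = {}
    total_hist = 0
    for job, seq in zip(jobs, seeds):
        apt = aperture_at(job.field, job.control_point, mlc_model)
        job_cfg = replace(config, n_histories=n_job, seed=int(seq.generate_state(1)[0] % (2**31)))
        tally = run_beam(phantom, job.field, apt, source, collimation, job_cfg)
        total_hist += tally.histories
        scale = cf.cf * job.mu * plan.n_fractions
        for organ, d in tally.dose_per_particle.items():
            dose[organ] = dose.get(organ, 0.0) + d * scale
            r = tally.rel_se[organ]
            if np.isfinite(r):
                var[organ] = var.get(organ, 0.0) + (d * r * scale) ** 2
    unc = {o: math.sqrt(var.get(o, 0.0)) for o in dose}
    return DoseReport(
        technique=plan.technique,
        plan_id=plan.plan_id,
        organ_dose_mgy=dose,
        organ_unc_mgy=unc,
        n_fractions=plan.n_fractions,
        histories=total_hist,
    )
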