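"""Synthetic input generators with the statistical structure the analyses assume.

Every generator is a pure function of its spec (seed included), so each
downstream stage — membrane geometry, solvation, conformational
classification, WHAM, NEB, residue electrostatics — can be validated
against planted ground truth without the original simulations.

Generated here:

* bilayer trajectories: phosphate planes with Gaussian z-spread plus
  per-residue centre-of-geometry markers at planted depths;
* active-site ensembles: mixtures of single-water / assisting-water /
  non-productive microstates built by explicit geometric placement so the
  drawn catalytic distances are realised exactly;
* biased collective-variable samples from known 1-D free-energy surfaces
  (Metropolis Monte Carlo under a harmonic umbrella restraint);
* analytic test surfaces (1-D double well, 2-D Gaussian sums) with exact
  gradients, for path optimisation;
* point-charge fixtures for the residue-deletion electrostatics scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import T_DEFAULT, rt
from .io_formats import (
    AtomRecord,
    TimeSeries,
    Trajectory,
    UmbrellaMetadata,
    ValidationError,
)

log = logging.getLogger("rpk.synthetic")

WATER_OH = 0.9572  # internal O-H bond length, Å


class ConstructionError(ValueError):
    """A drawn distance set admits no 3-D realization."""


# ---------------------------------------------------------------------------
# analytic surfaces
# ---------------------------------------------------------------------------

@dataclass
class DoubleWell1D:
    """C¹ double well with exactly planted barrier and reaction free energy.

    The reactant minimum sits at −well_separation/2 with F = 0, the product
    at +well_separation/2 with F = delta_g, and the transition state between
    them with F = barrier; the branches are half-cosines whose lengths are
    chosen so their curvatures match at the top (the profile is C² there,
    C¹ at the well/wall junctions), making the three feature values exact
    by construction. Harmonic walls confine the coordinate outside the
    minima. For delta_g = 0 the barrier top is the midpoint.
    """

    barrier: float = 17.0          # kcal/mol above the reactant minimum
    well_separation: float = 3.0   # Å between the two minima
    delta_g: float = 0.0           # kcal/mol, product minus reactant
    wall_k: float = 50.0           # kcal/mol/Å² confinement outside the wells

    ndim = 1

    def __post_init__(self):
        if self.barrier <= max(0.0, self.delta_g):
            raise ValidationError("barrier must exceed both well energies")
        if self.well_separation <= 0:
            raise ValidationError("well_separation must be > 0")

    @property
    def x_reactant(self):
        return -self.well_separation / 2.0

    @property
    def x_product(self):
        return self.well_separation / 2.0

    @property
    def x_ts(self):
        # curvature matching: B/L1² = (B − ΔG)/L2² with L1 + L2 = separation
        ratio = math.sqrt((self.barrier - self.delta_g) / self.barrier)
        return self.x_reactant + self.well_separation / (1.0 + ratio)

    def energy(self, x):
        scalar = np.isscalar(x) or np.ndim(x) == 0
        x = np.atleast_1d(np.asarray(x, dtype=float))
        xr, xp, xt = self.x_reactant, self.x_product, self.x_ts
        B, dG = self.barrier, self.delta_g
        L1, L2 = xt - xr, xp - xt
        e = np.empty_like(x)
        left = x < xr
        right = x > xp
        up = (~left) & (x <= xt)
        down = (~right) & (x > xt)
        e[left] = 0.5 * self.wall_k * (x[left] - xr) ** 2
        e[right] = dG + 0.5 * self.wall_k * (x[right] - xp) ** 2
        e[up] = 0.5 * B * (1.0 - np.cos(np.pi * (x[up] - xr) / L1))
        e[down] = dG + 0.5 * (B - dG) * (1.0 + np.cos(np.pi * (x[down] - xt) / L2))
        return float(e[0]) if scalar else e

    def gradient(self, x):
        scalar = np.isscalar(x) or np.ndim(x) == 0
        x = np.atleast_1d(np.asarray(x, dtype=float))
        xr, xp, xt = self.x_reactant, self.x_product, self.x_ts
        B, dG = self.barrier, self.delta_g
        L1, L2 = xt - xr, xp - xt
        g = np.empty_like(x)
        left = x < xr
        right = x > xp
        up = (~left) & (x <= xt)
        down = (~right) & (x > xt)
        g[left] = self.wall_k * (x[left] - xr)
        g[right] = self.wall_k * (x[right] - xp)
        g[up] = 0.5 * B * np.pi / L1 * np.sin(np.pi * (x[up] - xr) / L1)
        g[down] = -0.5 * (B - dG) * np.pi / L2 * np.sin(np.pi * (x[down] - xt) / L2)
        return float(g[0]) if scalar else g

    def energy_scalar(self, x: float) -> float:
        """Scalar fast path for tight Monte Carlo loops."""
        xr, xp, xt = self.x_reactant, self.x_product, self.x_ts
        B, dG = self.barrier, self.delta_g
        if x < xr:
            return 0.5 * self.wall_k * (x - xr) ** 2
        if x > xp:
            return dG + 0.5 * self.wall_k * (x - xp) ** 2
        if x <= xt:
            return 0.5 * B * (1.0 - math.cos(math.pi * (x - xr) / (xt - xr)))
        return dG + 0.5 * (B - dG) * (1.0 + math.cos(math.pi * (x - xt) / (xp - xt)))


@dataclass
class GaussianSum2D:
    """Sum of isotropic 2-D Gaussians; negative amplitudes are wells."""

    amplitudes: np.ndarray
    centers: np.ndarray     # (K, 2)
    widths: np.ndarray      # (K,)

    ndim = 2

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if np.any(self.widths <= 0):
            raise ValidationError("Gaussian widths must be positive")

    def _terms(self, p):
        d = p[None, :] - self.centers            # (K, 2)
        r2 = np.sum(d * d, axis=1)
        return d, self.amplitudes * np.exp(-r2 / (2.0 * self.widths ** 2))

    def energy(self, p):
        _, t = self._terms(np.asarray(p, dtype=float))
        return float(np.sum(t))

    def gradient(self, p):
        # ∇ A exp(−r²/2w²) = −(A exp(..)/w²)(p − c)
        d, t = self._terms(np.asarray(p, dtype=float))
        return np.sum(-t[:, None] * d / self.widths[:, None] ** 2, axis=0)


def default_2d_surface() -> GaussianSum2D:
    """Standard test surface: two wells joined through one saddle, with a
    shallow shaping well that bends the minimum-energy path off the straight
    line. Stationary points are meant to be located numerically (dense grid
    + gradient root polishing), never assumed."""
    return GaussianSum2D(
        amplitudes=[-5.0, -6.0, -1.5, 2.5],
        centers=[[-1.0, 0.0], [1.1, 0.1], [0.0, -1.1], [0.05, 0.4]],
        widths=[0.6, 0.6, 0.8, 0.7],
    )


def eval_surface(surface, point):
    """(energy, gradient) of an analytic surface at a point."""
    p = np.atleast_1d(np.asarray(point, dtype=float))
    if surface.ndim == 1:
        return surface.energy(float(p[0])), np.atleast_1d(surface.gradient(float(p[0])))
    return surface.energy(p), np.asarray(surface.gradient(p), dtype=float)


# ---------------------------------------------------------------------------
# membrane fixture
# ---------------------------------------------------------------------------

@dataclass
class MembraneFixtureSpec:
    """Bilayer + protein-marker fixture.

    ``residue_depths`` maps residue_id → (depth_mean, depth_sd) in Å, where
    depth is measured downward from the upper-leaflet phosphate plane
    (positive = buried below the plane).
    """

    n_frames: int = 100
    n_lipids_per_leaflet: int = 80
    plane_z: float = 20.0
    plane_sigma: float = 1.5
    residue_depths: dict = field(default_factory=dict)
    residue_names: dict = field(default_factory=dict)
    box: tuple = (93.21, 88.40, 103.30)
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.plane_sigma < 0:
            raise ValidationError("plane_sigma must be >= 0")


def gen_membrane_trajectory(spec: MembraneFixtureSpec) -> Trajectory:
    """Phosphate planes at z ≈ ±plane_z with Gaussian spread, plus one
    centre-of-geometry marker atom per protein residue at the planted depth."""
    rng = np.random.default_rng(spec.seed)
    nL, nF = spec.n_lipids_per_leaflet, spec.n_frames
    box = np.asarray(spec.box, dtype=float)
    res_ids = sorted(spec.residue_depths)

    atoms = []
    for i in range(nL):
        atoms.append(AtomRecord("P", "P", "POP", 1000 + i, "U"))
    for i in range(nL):
        atoms.append(AtomRecord("P", "P", "POP", 2000 + i, "L"))
    for rid in res_ids:
        atoms.append(AtomRecord("CG", "C", spec.residue_names.get(rid, "GLY"),
                                rid, "A"))

    n_atoms = 2 * nL + len(res_ids)
    coords = np.empty((nF, n_atoms, 3))
    half = box / 2.0
    # lipid xy positions uniform in the box, z Gaussian about the leaflet plane
    coords[:, : 2 * nL, 0] = rng.uniform(-half[0], half[0], size=(nF, 2 * nL))
    coords[:, : 2 * nL, 1] = rng.uniform(-half[1], half[1], size=(nF, 2 * nL))
    coords[:, :nL, 2] = spec.plane_z + rng.normal(0.0, spec.plane_sigma, (nF, nL)) \
        if spec.plane_sigma > 0 else spec.plane_z
    coords[:, nL: 2 * nL, 2] = -spec.plane_z + (
        rng.normal(0.0, spec.plane_sigma, (nF, nL)) if spec.plane_sigma > 0 else 0.0)
    for j, rid in enumerate(res_ids):
        mean, sd = spec.residue_depths[rid]
        col = 2 * nL + j
        coords[:, col, 0] = rng.uniform(-half[0] / 2, half[0] / 2, nF)
        coords[:, col, 1] = rng.uniform(-half[1] / 2, half[1] / 2, nF)
        z = spec.plane_z - mean
        coords[:, col, 2] = z + (rng.normal(0.0, sd, nF) if sd > 0 else 0.0)

    traj = Trajectory(atoms, coords, box)
    traj.add_selection("upper_leaflet_P", np.arange(nL))
    traj.add_selection("lower_leaflet_P", np.arange(nL, 2 * nL))
    traj.add_selection("residue_cog_markers", np.arange(2 * nL, n_atoms))
    return traj


# ---------------------------------------------------------------------------
# active-site fixture
# ---------------------------------------------------------------------------

STATE_SINGLE = "single_water"
STATE_ASSIST = "assisting_water"
STATE_NONPROD = "nonproductive"
STATES = (STATE_SINGLE, STATE_ASSIST, STATE_NONPROD)

#: catalytic distance keys: His-Nδ→water-H, substrate-C→water-O, the
#: water O–H (internal bond, or the W1–W2 bridge in the assisting state),
#: His-Nδ→substrate-C, Ca²⁺→carbonyl-O, Ca²⁺→nucleophile-water-O.
DISTANCE_KEYS = ("nd_h", "c_o", "o_h", "nd_c", "ca_opopc", "ca_ow")

DEFAULT_STATE_DISTANCES = {
    STATE_SINGLE: {
        "nd_h": (1.8, 0.15), "c_o": (3.0, 0.25), "o_h": (WATER_OH, 0.0),
        "nd_c": (4.3, 0.2), "ca_opopc": (2.3, 0.1), "ca_ow": (3.6, 1.5),
    },
    STATE_ASSIST: {
        "nd_h": (1.9, 0.15), "c_o": (3.5, 0.15), "o_h": (1.9, 0.15),
        "nd_c": (4.3, 0.2), "ca_opopc": (2.3, 0.1), "ca_ow": (4.8, 0.2),
    },
    STATE_NONPROD: {
        "nd_h": (4.5, 0.4), "c_o": (5.5, 0.4), "o_h": (WATER_OH, 0.0),
        "nd_c": (4.3, 0.2), "ca_opopc": (2.3, 0.1), "ca_ow": (4.5, 0.8),
    },
}


@dataclass
class ActiveSiteFixtureSpec:
    n_frames: int = 1000
    state_probabilities: tuple = (0.75, 0.04, 0.21)
    state_distances: dict = field(
        default_factory=lambda: {s: dict(d) for s, d in
                                 DEFAULT_STATE_DISTANCES.items()})
    n_bulk_waters: int = 20
    box: tuple = (60.0, 60.0, 60.0)
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.state_probabilities, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or np.any(p > 1):
            raise ValidationError("state_probabilities must be three values in [0,1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("state_probabilities must sum to 1")
        for s, d in self.state_distances.items():
            for k, (_, sd) in d.items():
                if sd < 0:
                    raise ValidationError(f"sd for {s}/{k} must be >= 0")


@dataclass
class ActiveSiteEnsemble:
    """Generated ensemble plus its ground truth (planted labels and draws)."""

    trajectory: Trajectory
    labels: np.ndarray           # per-frame state string
    atom_map: dict               # names → index / index arrays for `conformations`
    drawn: dict                  # key → per-frame drawn target distance


def _draw_trunc_normal(rng, mean, sd, lo=0.05, size=None):
    """Normal(mean, sd) truncated below at `lo` (distances must be positive)."""
    if sd == 0:
        return np.full(size, float(mean)) if size else float(mean)
    from scipy.stats import truncnorm
    a = (lo - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                         size=size, random_state=rng)


def _trilaterate_xy(d_ab, r_a, r_b, label):
    """Place P in the xy-plane with |P - A| = r_a, |P - B| = r_b where
    A = origin and B = (d_ab, 0, 0). Returns the y > 0 solution."""
    x = (d_ab ** 2 + r_a ** 2 - r_b ** 2) / (2.0 * d_ab)
    y2 = r_a ** 2 - x ** 2
    if y2 < -1e-9:
        raise ConstructionError(
            f"infeasible distance triple {label}: "
            f"d(A,B)={d_ab:.3f}, r_A={r_a:.3f}, r_B={r_b:.3f}")
    return np.array([x, np.sqrt(max(y2, 0.0)), 0.0])


def _unit(v):
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ConstructionError("degenerate direction in geometric placement")
    return v / n


def _build_site(state, draws):
    """Place the ten active-site atoms in a local frame so every drawn
    target distance is realised exactly. Returns (10, 3) coordinates in
    order: Nδ, C, O_carbonyl, Ca, O_W1, H_W1a, H_W1b, O_W2, H_W2a, H_W2b."""
    a, b, oh, d_nc, c1, c2 = (draws[k] for k in DISTANCE_KEYS)
    nd = np.zeros(3)
    c = np.array([d_nc, 0.0, 0.0])

    if state in (STATE_SINGLE, STATE_NONPROD):
        # one catalytic water: H on the Nδ→O axis at the drawn d(Nδ–H),
        # O at d(Nδ–H)+d(O–H) so both distances are exact.
        r_no = a + oh
        o_w1 = _trilaterate_xy(d_nc, r_no, b,
                               "(d(Nd-H)+d(O-H), d(C-O), d(Nd-C))")
        h_w1a = o_w1 * (a / r_no)
        h_w1b = o_w1 + WATER_OH * _unit(o_w1)
        ca = o_w1 + np.array([0.0, 0.0, c2])
        o_pop = ca + c1 * _unit(c - ca)
        # spectator water parked far outside the candidate shell
        o_w2 = np.array([14.0, 10.0, 6.0])
        h_w2a = o_w2 + np.array([WATER_OH, 0.0, 0.0])
        h_w2b = o_w2 + np.array([0.0, WATER_OH, 0.0])
    elif state == STATE_ASSIST:
        # W1 = nucleophile near the carbonyl C, W2 = relay donor H-bonded to
        # Nδ, bridged to O_W1 at the drawn d(O_W1–H_W2).
        br = oh
        d_no1 = float(np.clip(3.0, abs(a - br) + 0.05, a + br - 0.05))
        o_w1 = _trilaterate_xy(d_nc, d_no1, b, "(d(Nd-O_W1), d(C-O), d(Nd-C))")
        h_w1a = o_w1 + WATER_OH * _unit(o_w1 - nd)
        h_w1b = o_w1 + WATER_OH * _unit(o_w1 - c)
        # bridge H: trilaterate between Nδ (drawn d(Nδ–H)) and O_W1 (bridge)
        u = _unit(o_w1)
        x_loc = (d_no1 ** 2 + a ** 2 - br ** 2) / (2.0 * d_no1)
        p2 = a ** 2 - x_loc ** 2
        if p2 < -1e-9:
            raise ConstructionError(
                f"infeasible distance triple (d(Nd-H), d(O_W1-H), d(Nd-O_W1)): "
                f"{a:.3f}, {br:.3f}, {d_no1:.3f}")
        perp = _unit(np.cross(np.array([0.0, 0.0, 1.0]), u))
        cand1 = x_loc * u + np.sqrt(max(p2, 0.0)) * perp
        cand2 = x_loc * u - np.sqrt(max(p2, 0.0)) * perp
        h_w2a = cand1 if np.linalg.norm(cand1 - c) >= np.linalg.norm(cand2 - c) \
            else cand2
        o_w2 = h_w2a + WATER_OH * _unit(h_w2a - c)
        h_w2b = o_w2 + WATER_OH * _unit(o_w2 - nd)
        ca = o_w1 + np.array([0.0, 0.0, c2])
        o_pop = ca + c1 * _unit(c - ca)
    else:  # pragma: no cover
        raise ValidationError(f"unknown state {state!r}")
    return np.stack([nd, c, o_pop, ca, o_w1, h_w1a, h_w1b, o_w2, h_w2a, h_w2b])


def gen_active_site_trajectory(spec: ActiveSiteFixtureSpec) -> ActiveSiteEnsemble:
    """Mixture ensemble of catalytic microstates with exactly realised
    distances, a uniformly random rigid rotation per frame, and bulk waters
    kept ≥ 6 Å from both His-Nδ and the substrate carbon so they can never
    masquerade as catalytic candidates."""
    rng = np.random.default_rng(spec.seed)
    nF = spec.n_frames
    states = rng.choice(3, size=nF, p=np.asarray(spec.state_probabilities))
    labels = np.array([STATES[s] for s in states])

    draws = {}
    for k in DISTANCE_KEYS:
        vals = np.empty(nF)
        for si, s in enumerate(STATES):
            m = states == si
            if m.any():
                mean, sd = spec.state_distances[s][k]
                vals[m] = _draw_trunc_normal(rng, mean, sd, size=int(m.sum()))
        draws[k] = vals

    nb = spec.n_bulk_waters
    n_atoms = 10 + 3 * nb
    coords = np.empty((nF, n_atoms, 3))
    box = np.asarray(spec.box, dtype=float)

    state_sds = {s: {k: spec.state_distances[s][k][1] for k in DISTANCE_KEYS}
                 for s in STATES}
    for f in range(nF):
        # rare extreme tails can violate a triangle inequality; such frames
        # are redrawn (the feasible region covers all but ~1e-5 of the mass,
        # so the planted distance laws are unaffected). A distance set that
        # is deterministically infeasible still raises.
        attempts = 0
        while True:
            try:
                site = _build_site(labels[f],
                                   {k: draws[k][f] for k in DISTANCE_KEYS})
                break
            except ConstructionError:
                sds = state_sds[labels[f]]
                if all(v == 0 for v in sds.values()) or attempts >= 100:
                    raise
                attempts += 1
                retry_rng = np.random.default_rng(
                    np.random.SeedSequence([spec.seed, 7_000_000 + f,
                                            attempts]))
                for k in DISTANCE_KEYS:
                    mean, sd = spec.state_distances[labels[f]][k]
                    draws[k][f] = _draw_trunc_normal(retry_rng, mean, sd)
        nd_pos, c_pos = site[0], site[1]
        # bulk waters: uniform, excluded from 6 Å spheres around Nδ and C
        bulk = np.empty((nb, 3))
        placed = 0
        while placed < nb:
            cand = rng.uniform(-box / 2 * 0.8, box / 2 * 0.8, size=(2 * nb, 3))
            ok = (np.linalg.norm(cand - nd_pos, axis=1) >= 6.0) & \
                 (np.linalg.norm(cand - c_pos, axis=1) >= 6.0)
            take = cand[ok][: nb - placed]
            bulk[placed: placed + len(take)] = take
            placed += len(take)
        bulk_atoms = np.empty((3 * nb, 3))
        bulk_atoms[0::3] = bulk
        dirs = rng.normal(size=(nb, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        bulk_atoms[1::3] = bulk + WATER_OH * dirs
        dirs2 = rng.normal(size=(nb, 3))
        dirs2 /= np.linalg.norm(dirs2, axis=1, keepdims=True)
        bulk_atoms[2::3] = bulk + WATER_OH * dirs2
        frame = np.vstack([site, bulk_atoms])
        rot = Rotation.random(random_state=rng)
        coords[f] = rot.apply(frame)

    atoms = [
        AtomRecord("ND1", "N", "HIS", 47),
        AtomRecord("C21", "C", "POP", 200),
        AtomRecord("O22", "O", "POP", 200),
        AtomRecord("CA", "Ca", "CAL", 300),
        AtomRecord("OW", "O", "WAT", 400),
        AtomRecord("HW1", "H", "WAT", 400),
        AtomRecord("HW2", "H", "WAT", 400),
        AtomRecord("OW", "O", "WAT", 401),
        AtomRecord("HW1", "H", "WAT", 401),
        AtomRecord("HW2", "H", "WAT", 401),
    ]
    for w in range(nb):
        rid = 402 + w
        atoms.append(AtomRecord("OW", "O", "WAT", rid))
        atoms.append(AtomRecord("HW1", "H", "WAT", rid))
        atoms.append(AtomRecord("HW2", "H", "WAT", rid))

    traj = Trajectory(atoms, coords, box)
    water_o = np.array([4, 7] + [10 + 3 * w for w in range(nb)])
    water_h = np.array([[5, 6], [8, 9]] + [[11 + 3 * w, 12 + 3 * w]
                                           for w in range(nb)])
    atom_map = {
        "his_nd": 0, "sub_c": 1, "carbonyl_o": 2, "calcium": 3,
        "water_o": water_o, "water_h": water_h,
    }
    traj.add_selection("catalytic_Ca", [3])
    traj.add_selection("water_O", water_o)
    return ActiveSiteEnsemble(traj, labels, atom_map, draws)


# ---------------------------------------------------------------------------
# biased sampling on analytic surfaces
# ---------------------------------------------------------------------------

def sample_biased_windows(surface, metadata: UmbrellaMetadata, n_steps: int,
                          step_size: float = 0.05,
                          temperature_K: float = T_DEFAULT,
                          seed: int = 0,
                          discard_fraction: float = 0.2,
                          extraction_stride: int = 10,
                          dt_ps: float = 0.005):
    """Metropolis Monte Carlo on F(ξ) + ½k(ξ−ξ₀)² for every window in the
    metadata; returns one CV TimeSeries per window with the leading
    `discard_fraction` (equilibration) removed.

    Only the stationary distribution matters downstream, so MC proposals
    (Gaussian, width `step_size`) stand in for dynamics. Mirroring the MD
    convention of extracting the collective variable at a coarser period
    than the integration step, only every `extraction_stride`-th MC state
    is recorded; `n_steps` counts recorded samples, spaced `dt_ps` apart.
    """
    if step_size <= 0:
        raise ValidationError("step_size must be > 0")
    if not 0 <= discard_fraction < 1:
        raise ValidationError("discard_fraction must be in [0, 1)")
    if temperature_K <= 0:
        raise ValidationError("temperature must be > 0")
    if extraction_stride < 1:
        raise ValidationError("extraction_stride must be >= 1")
    kT = rt(temperature_K)
    e_fn = getattr(surface, "energy_scalar", surface.energy)
    out = []
    for wi, (path, center, k) in enumerate(metadata.entries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, wi]))
        x = float(center)
        u = e_fn(x) + 0.5 * k * (x - center) ** 2
        total = n_steps * extraction_stride
        xs = np.empty(n_steps)
        accepted = 0
        steps = rng.normal(0.0, step_size, total)
        unif = rng.random(total)
        log_unif = np.log(unif)
        for i in range(total):
            xn = x + steps[i]
            un = e_fn(xn) + 0.5 * k * (xn - center) ** 2
            if un <= u or log_unif[i] < -(un - u) / kT:
                x, u = xn, un
                accepted += 1
            if (i + 1) % extraction_stride == 0:
                xs[(i + 1) // extraction_stride - 1] = x
        n_discard = int(discard_fraction * n_steps)
        kept = xs[n_discard:]
        times = (np.arange(n_discard, n_steps) + 1) * dt_ps
        log.info("window %d (center %.3f): acceptance %.2f", wi, center,
                 accepted / total)
        out.append(TimeSeries(str(path), times, kept))
    return out


# ---------------------------------------------------------------------------
# charge fixtures
# ---------------------------------------------------------------------------

@dataclass
class ChargeFixtureSpec:
    n_mm_residues: int = 12
    n_qm_charges: int = 4
    qm_extent: float = 3.0       # Å, QM charge cloud radius
    mm_shell: tuple = (6.0, 18.0)  # Å, radial band for MM residues
    ts_shift: float = 0.8        # Å, displacement of QM charges in the TS
    seed: int = 0


def gen_charge_states(spec: ChargeFixtureSpec):
    """Reproducible point-charge sets for the residue-deletion scan:
    a small QM cluster whose geometry (and thus field) differs between the
    reactant and transition states, surrounded by MM residue charge groups.
    Returns (qm_R, qm_TS, mm_groups) with qm_* = (charges, positions)."""
    from .residue_energetics import ChargeGroup, classify_residue

    rng = np.random.default_rng(spec.seed)
    nq = spec.n_qm_charges
    q_qm = rng.uniform(-0.8, 0.8, nq)
    q_qm[-1] -= q_qm.sum()  # neutral QM region overall
    pos_r = rng.uniform(-spec.qm_extent, spec.qm_extent, (nq, 3))
    shift = rng.normal(0.0, spec.ts_shift, (nq, 3))
    pos_ts = pos_r + shift

    names = ["ASP", "GLU", "LYS", "ARG", "SER", "THR", "ALA", "LEU", "PHE",
             "GLY", "ASN", "HIS"]
    groups = []
    lo, hi = spec.mm_shell
    for i in range(spec.n_mm_residues):
        r = rng.uniform(lo, hi)
        d = rng.normal(size=3)
        center = r * d / np.linalg.norm(d)
        n_c = rng.integers(1, 4)
        qs = rng.uniform(-0.6, 0.6, n_c)
        ps = center + rng.normal(0.0, 0.5, (n_c, 3))
        name = names[i % len(names)]
        groups.append(ChargeGroup(f"{name}_{i + 1}", list(zip(qs, ps)),
                                  classify_residue(name)))
    # positions must not coincide with QM charges
    for g in groups:
        for _, p in g.charges:
            for ps in (pos_r, pos_ts):
                if np.min(np.linalg.norm(ps - p, axis=1)) < 0.1:
                    raise ValidationError(
                        f"MM charge of {g.label} coincides with a QM charge")
    return (q_qm, pos_r), (q_qm, pos_ts), groups
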