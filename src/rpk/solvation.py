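"""Radial distribution functions, shell occupancies, coordination numbers,
and Shrake–Rupley solvent-accessible surface area.

g(r) is normalised against the mean number density of the population in the
simulation box (per frame, then pooled); the cumulative water count n(r) is
counted directly rather than integrated, so the quadrature identity
n(r) = ρ ∫ g 4πs² ds is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import (
    SelectionError,
    Trajectory,
    ValidationError,
    mi_distance,
)

#: Bondi van der Waals radii, Å (element-keyed, overridable per call).
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "Ca": 2.31, "Na": 2.27, "Mg": 1.73,
    "K": 2.75, "Zn": 1.39, "Fe": 2.00, "X": 1.70,
}


@dataclass
class RdfResult:
    bin_centers: np.ndarray
    g_of_r: np.ndarray
    cumulative_n: np.ndarray
    reference_density: float
    bin_width: float
    smoothed_g: np.ndarray | None = None


@dataclass
class SasaResult:
    areas: np.ndarray         # Ų, one per target atom
    probe_radius: float
    n_sphere_points: int


def _reference_positions(traj, reference):
    """Reference point per frame: an atom index, or a pair (i, j) whose
    midpoint is recomputed every frame."""
    if np.isscalar(reference):
        return traj.coords[:, int(reference), :]
    ref = np.asarray(reference, dtype=int)
    if ref.size == 1:
        return traj.coords[:, ref[0], :]
    if ref.size != 2:
        raise ValidationError("reference must be one atom or a pair of atoms")
    return 0.5 * (traj.coords[:, ref[0], :] + traj.coords[:, ref[1], :])


def _population_distances(traj, population_selection, reference):
    idx = traj.selection(population_selection) \
        if isinstance(population_selection, str) \
        else np.asarray(population_selection, dtype=int)
    if idx.size == 0:
        raise SelectionError("population selection is empty")
    ref = _reference_positions(traj, reference)          # (F, 3)
    return mi_distance(traj.coords[:, idx, :], ref[:, None, :], traj.box), idx


def rdf(traj: Trajectory, population_selection, reference,
        r_max: float = 10.0, bin_width: float = 0.1,
        smooth_sigma_bins: float | None = None) -> RdfResult:
    """g(r) of the population around a per-frame reference point.

    `reference` is an atom index or an (i, j) pair (midpoint). Requires
    r_max ≤ half the smallest box edge so minimum-image shells are complete.
    """
    if r_max > traj.box.min() / 2:
        raise ValidationError(
            f"r_max {r_max} exceeds half the smallest box edge "
            f"({traj.box.min() / 2:.2f})")
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    dists, idx = _population_distances(traj, population_selection, reference)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts, _ = np.histogram(dists.ravel(), bins=edges)
    mean_counts = counts / traj.n_frames

    volume = float(np.prod(traj.box))
    rho = idx.size / volume
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = mean_counts / (rho * shell_vol)
    cum = np.cumsum(mean_counts)
    smoothed = None
    if smooth_sigma_bins is not None:
        smoothed = ndimage.gaussian_filter1d(g, smooth_sigma_bins, mode="nearest")
    return RdfResult(centers, g, cum, rho, bin_width, smoothed)


def shell_statistics(source, r_lo: float, r_hi: float,
                     population_selection=None, reference=None) -> float:
    """Mean per-frame count of population atoms with r ∈ [r_lo, r_hi).

    Accepts either a Trajectory (exact counting; needs population and
    reference) or an RdfResult (quadrature of ρ g(r) 4πr² over the shell).
    """
    if not 0 <= r_lo < r_hi:
        raise ValidationError("need 0 <= r_lo < r_hi")
    if isinstance(source, RdfResult):
        r = source.bin_centers
        mask = (r >= r_lo) & (r < r_hi)
        integrand = source.reference_density * source.g_of_r[mask] \
            * 4.0 * np.pi * r[mask] ** 2
        return float(np.sum(integrand) * source.bin_width)
    dists, _ = _population_distances(source, population_selection, reference)
    in_shell = (dists >= r_lo) & (dists < r_hi)
    return float(in_shell.sum(axis=1).mean())


def coordination_number(traj: Trajectory, center_selection, ligand_selection,
                        r_cut: float) -> float:
    """Mean per-frame count of ligand atoms within r_cut of the center
    (averaged over centers if several are selected)."""
    if r_cut <= 0:
        raise ValidationError("r_cut must be > 0")
    cen = traj.selection(center_selection) if isinstance(center_selection, str) \
        else np.atleast_1d(np.asarray(center_selection, dtype=int))
    if cen.size == 0:
        raise SelectionError("center selection is empty")
    lig = traj.selection(ligand_selection) if isinstance(ligand_selection, str) \
        else np.asarray(ligand_selection, dtype=int)
    counts = np.empty((traj.n_frames, cen.size))
    for k, ci in enumerate(cen):
        d = mi_distance(traj.coords[:, lig, :], traj.coords[:, ci, None, :],
                        traj.box)
        counts[:, k] = (d < r_cut).sum(axis=1)
    return float(counts.mean())


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def sasa(frame, target_atoms, all_atoms=None, probe: float = 1.4,
         n_points: int = 960, radii: dict | None = None) -> SasaResult:
    """Shrake–Rupley accessible area of the target atoms within one frame.

    Each target's expanded sphere (r_vdw + probe) is sampled with `n_points`
    golden-spiral test points; a point buried inside any neighbour's
    expanded sphere is inaccessible. Radii come from the Bondi table keyed
    by element (override via `radii`).
    """
    table = dict(BONDI_RADII)
    if radii:
        table.update(radii)
    atoms, coords = frame.atoms, frame.coords
    all_idx = np.arange(len(atoms)) if all_atoms is None \
        else np.asarray(all_atoms, dtype=int)
    tgt = np.atleast_1d(np.asarray(target_atoms, dtype=int))

    def radius_of(i):
        el = atoms[i].element
        if el not in table:
            raise LookupError(f"no van der Waals radius for element {el!r}")
        return table[el]

    unit = _sphere_points(n_points)
    areas = np.empty(tgt.size)
    exp_r = np.array([radius_of(i) + probe for i in all_idx])
    for k, ti in enumerate(tgt):
        r_t = radius_of(ti) + probe
        pts = coords[ti] + r_t * unit
        neighbours = all_idx[all_idx != ti]
        nb_r = exp_r[all_idx != ti]
        accessible = np.ones(n_points, dtype=bool)
        for nb, rr in zip(neighbours, nb_r):
            d2 = np.sum((pts - coords[nb]) ** 2, axis=1)
            accessible &= d2 > rr * rr
        areas[k] = 4.0 * np.pi * r_t ** 2 * accessible.mean()
    return SasaResult(areas, probe, n_points)
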