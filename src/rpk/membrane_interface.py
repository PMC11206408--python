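"""Protein–bilayer geometry: penetration depth, buried-residue hotspots,
in-plane density maps and residue–substrate minimum-distance profiles.

The penetration depth Δz of a residue is the difference between the mean z
coordinate of the upper-leaflet phosphate atoms (the reference plane) and
the z of the residue's centre of geometry; Δz > 0 means the residue sits
below the phosphate plane (buried toward the membrane interior). A residue
whose deepest excursion passes the pooled x̄ − σ band of the phosphate z
distribution (equivalently max Δz > σ_z) is flagged buried, and runs of
flagged residues contiguous in sequence numbering form hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import SelectionError, Trajectory, ValidationError, minimum_image


@dataclass
class DepthProfile:
    """Per-residue depth statistics plus the phosphate-plane reference."""

    residues: pd.DataFrame        # index residue_id; mean_dz, min_dz, max_dz
    plane_mean_z: np.ndarray      # per frame
    plane_sigma_z: np.ndarray     # per frame
    pooled_mean_z: float
    pooled_sigma_z: float
    sign_convention: str = "dz>0 means buried below the upper-leaflet P plane"


@dataclass
class Hotspot:
    residue_ids: list
    peak_depth: float


@dataclass
class DensityMap2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray | None = None
    smooth_sigma: float | None = None

    @property
    def total(self):
        return float(self.counts.sum())


def assign_leaflets(traj: Trajectory, p_name: str = "P"):
    """Static leaflet split of phosphate atoms: atoms whose time-averaged z
    lies above the bilayer midplane (mean phosphate z over all frames) form
    the upper leaflet. No flip-flop is assumed at these timescales."""
    p_idx = traj.select(atom_name=p_name)
    if p_idx.size == 0:
        raise SelectionError(f"no atoms named {p_name!r}")
    z_mean = traj.coords[:, p_idx, 2].mean(axis=0)
    mid = z_mean.mean()
    upper = p_idx[z_mean > mid]
    lower = p_idx[z_mean <= mid]
    traj.add_selection("upper_leaflet_P", upper)
    traj.add_selection("lower_leaflet_P", lower)
    return upper, lower


def reference_plane(traj: Trajectory, selection: str = "upper_leaflet_P"):
    """Per-frame mean and population standard deviation of the selected
    phosphate z coordinates."""
    idx = traj.selection(selection)
    if idx.size == 0:
        raise SelectionError(f"selection {selection!r} is empty")
    z = traj.coords[:, idx, 2]
    return z.mean(axis=1), z.std(axis=1)


def penetration_depth(traj: Trajectory, residues=None,
                      selection: str = "upper_leaflet_P") -> DepthProfile:
    """Depth profile Δz(residue, frame) aggregated to mean/min/max per residue.

    The centre of geometry is unweighted. Pooled plane statistics are taken
    over all selected phosphate atoms in all frames.
    """
    idx = traj.selection(selection)
    if idx.size == 0:
        raise SelectionError(f"selection {selection!r} is empty")
    z_p = traj.coords[:, idx, 2]
    mean_z, sigma_z = z_p.mean(axis=1), z_p.std(axis=1)
    pooled_mean, pooled_sigma = float(z_p.mean()), float(z_p.std())

    if residues is None:
        # default: every residue that is not part of a phosphate leaflet
        lipid = set(idx.tolist())
        for other in ("upper_leaflet_P", "lower_leaflet_P"):
            if other in traj.selections:
                lipid |= set(traj.selections[other].tolist())
        residues = [rid for rid in traj.residue_ids()
                    if not set(traj.select(residue_id=rid).tolist()) <= lipid]
    rows = {}
    for rid in residues:
        aidx = traj.residue_indices(rid)
        cog_z = traj.coords[:, aidx, 2].mean(axis=1)
        dz = mean_z - cog_z
        rows[rid] = (dz.mean(), dz.min(), dz.max())
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["mean_dz", "min_dz", "max_dz"])
    df.index.name = "residue_id"
    return DepthProfile(df, mean_z, sigma_z, pooled_mean, pooled_sigma)


def find_buried_hotspots(profile: DepthProfile) -> list:
    """Residues whose deepest excursion passes the pooled x̄ − σ phosphate
    band (max Δz > pooled σ_z), merged into sequence-contiguous hotspots."""
    flagged = profile.residues.index[
        profile.residues["max_dz"] > profile.pooled_sigma_z]
    hotspots = []
    run = []
    for rid in sorted(flagged):
        if run and rid != run[-1] + 1:
            hotspots.append(run)
            run = []
        run.append(rid)
    if run:
        hotspots.append(run)
    return [Hotspot(r, float(profile.residues.loc[r, "max_dz"].max()))
            for r in hotspots]


def density_map(traj: Trajectory, selection, bin_width: float = 1.0,
                smooth_sigma: float | None = None) -> DensityMap2D:
    """xy histogram of the selected atoms over all frames, optionally
    smoothed with an isotropic Gaussian of width `smooth_sigma` (Å). The
    smoothing kernel wraps periodically, conserving total counts."""
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    idx = traj.selection(selection) if isinstance(selection, str) \
        else np.asarray(selection, dtype=int)
    xy = traj.coords[:, idx, :2].reshape(-1, 2)

    def _edges(vals):
        lo = np.floor(vals.min() / bin_width) * bin_width
        n = max(1, int(np.ceil((vals.max() - lo) / bin_width + 1e-9)))
        return lo + bin_width * np.arange(n + 1)

    counts, x_edges, y_edges = np.histogram2d(xy[:, 0], xy[:, 1],
                                              bins=[_edges(xy[:, 0]),
                                                    _edges(xy[:, 1])])
    smoothed = None
    if smooth_sigma is not None:
        smoothed = ndimage.gaussian_filter(counts, sigma=smooth_sigma / bin_width,
                                           mode="wrap")
    return DensityMap2D(x_edges, y_edges, counts, smoothed, smooth_sigma)


def residue_min_distance(traj: Trajectory, residues, target_selection,
                         shell_cutoff: float = 5.0) -> pd.DataFrame:
    """Per-residue mean (over frames) of the minimum atom-pair distance to
    the target selection, minimum-image convention; `in_shell` is strict
    (mean < cutoff)."""
    tgt = traj.selection(target_selection) if isinstance(target_selection, str) \
        else np.asarray(target_selection, dtype=int)
    if tgt.size == 0:
        raise SelectionError("target selection is empty")
    box = traj.box
    rows = {}
    for rid in residues:
        aidx = traj.residue_indices(rid)
        # (F, n_res, n_tgt, 3) displacement block, minimum image per axis
        d = traj.coords[:, aidx, None, :] - traj.coords[:, None, tgt, :]
        d = minimum_image(d, box)
        dist = np.sqrt(np.sum(d * d, axis=-1))
        per_frame_min = dist.min(axis=(1, 2))
        m = float(per_frame_min.mean())
        rows[rid] = (m, m < shell_cutoff)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["mean_min_distance", "in_shell"])
    df.index.name = "residue_id"
    return df
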