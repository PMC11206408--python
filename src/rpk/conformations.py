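"""Classification of active-site microstates.

A frame is *single-water* when one water simultaneously donates a hydrogen
bond to His-Nδ (d(Nδ–H) < 2.5 Å) and positions its oxygen for nucleophilic
attack on the substrate carbonyl carbon (d(C–O) < 4.0 Å). When no single
water does both, a two-water relay — nucleophile W1 near the carbon plus a
donor W2 hydrogen-bonded to His and bridged to W1 (d(O_W1–H_W2) < 2.5 Å) —
marks the frame *assisting-water*; otherwise it is *non-productive*. All
inequalities are strict; ties fall toward non-productive.

Hydrogen ambiguity is resolved by minimising over each water's two
hydrogens. Candidate waters are restricted to oxygens within 8 Å of the
substrate carbon (performance guard).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import SelectionError, Trajectory, ValidationError, mi_distance

LABEL_SINGLE = "single_water"
LABEL_ASSIST = "assisting_water"
LABEL_NONPROD = "nonproductive"

CANDIDATE_CUTOFF = 8.0  # Å, water O to substrate C


@dataclass
class ClassificationCriteria:
    """Geometric thresholds (Å), strict '<' comparisons throughout."""

    d_his_h_max: float = 2.5
    d_c_o_max: float = 4.0
    d_bridge_max: float = 2.5

    def __post_init__(self):
        if min(self.d_his_h_max, self.d_c_o_max, self.d_bridge_max) <= 0:
            raise ValidationError("all criteria thresholds must be > 0")


@dataclass
class ConformationRecord:
    """Per-frame catalytic geometry.

    Scalar fields summarise the optimal candidate assignment; the per-water
    arrays (`cand_*`) keep everything the classifier needs to re-evaluate
    the criteria exhaustively.
    """

    frame: int
    d_nd_h: float          # min over candidate waters/hydrogens
    d_c_o: float           # nucleophile water O to substrate C
    d_o_h_bridge: float    # best relay bridge O_W1–H_W2 (inf if < 2 waters)
    d_nd_c: float
    d_ca_opopc: float
    d_ca_ow: float         # Ca to the nucleophile water O
    cand_nd_h: np.ndarray = field(repr=False, default=None)
    cand_c_o: np.ndarray = field(repr=False, default=None)
    cand_oo_h: np.ndarray = field(repr=False, default=None)  # (W1, W2) bridge matrix
    label: str | None = None


def catalytic_distances(traj: Trajectory, atom_map: dict) -> list:
    """Per-frame catalytic distances with the optimal water assignment.

    `atom_map` must resolve: his_nd, sub_c, carbonyl_o, calcium (ints),
    water_o (n_w,), water_h (n_w, 2). Distances are minimum-image.
    """
    for key in ("his_nd", "sub_c", "carbonyl_o", "calcium",
                "water_o", "water_h"):
        if key not in atom_map:
            raise SelectionError(f"atom_map missing {key!r}")
    box = traj.box
    nd = traj.coords[:, atom_map["his_nd"], :]
    c = traj.coords[:, atom_map["sub_c"], :]
    o_pop = traj.coords[:, atom_map["carbonyl_o"], :]
    ca = traj.coords[:, atom_map["calcium"], :]
    w_o = traj.coords[:, np.asarray(atom_map["water_o"], dtype=int), :]
    w_h = traj.coords[:, np.asarray(atom_map["water_h"], dtype=int), :]

    d_nd_c = mi_distance(nd, c, box)
    d_ca_opop = mi_distance(ca, o_pop, box)
    d_co_all = mi_distance(w_o, c[:, None, :], box)              # (F, W)
    d_ndh_all = mi_distance(w_h, nd[:, None, None, :], box).min(axis=2)
    d_ca_o_all = mi_distance(w_o, ca[:, None, :], box)

    records = []
    for f in range(traj.n_frames):
        cand = np.where(d_co_all[f] < CANDIDATE_CUTOFF)[0]
        if cand.size == 0:
            records.append(ConformationRecord(
                f, np.inf, np.inf, np.inf, float(d_nd_c[f]),
                float(d_ca_opop[f]), np.inf,
                np.empty(0), np.empty(0), np.empty((0, 0))))
            continue
        c_o = d_co_all[f, cand]
        nd_h = d_ndh_all[f, cand]
        # bridge matrix: O of W1 (rows) to nearest H of W2 (cols)
        o_pos = w_o[f, cand]                                    # (k, 3)
        h_pos = w_h[f, cand]                                    # (k, 2, 3)
        oo_h = mi_distance(o_pos[:, None, None, :], h_pos[None, :, :, :],
                           box).min(axis=2)                     # (k, k)
        np.fill_diagonal(oo_h, np.inf)

        nuc = int(np.argmin(c_o))        # nucleophile = water closest to C
        bridge = float(oo_h[nuc].min()) if cand.size > 1 else np.inf
        records.append(ConformationRecord(
            f, float(nd_h.min()), float(c_o[nuc]), bridge,
            float(d_nd_c[f]), float(d_ca_opop[f]),
            float(d_ca_o_all[f, cand[nuc]]),
            nd_h, c_o, oo_h))
    return records


def classify(records, criteria: ClassificationCriteria | None = None):
    """Label records and return (records, summary DataFrame of fractions).

    Precedence: a lone water meeting both the His H-bond and attack
    criteria forces single-water; the relay is only examined otherwise.
    """
    crit = criteria or ClassificationCriteria()
    for rec in records:
        nd_h, c_o, oo_h = rec.cand_nd_h, rec.cand_c_o, rec.cand_oo_h
        if nd_h.size and np.any((nd_h < crit.d_his_h_max) &
                                (c_o < crit.d_c_o_max)):
            rec.label = LABEL_SINGLE
            continue
        assisted = False
        if nd_h.size > 1:
            w1 = c_o < crit.d_c_o_max
            w2 = nd_h < crit.d_his_h_max
            if np.any(w1[:, None] & w2[None, :] & (oo_h < crit.d_bridge_max)):
                assisted = True
        rec.label = LABEL_ASSIST if assisted else LABEL_NONPROD
    labels = pd.Series([r.label for r in records])
    frac = labels.value_counts(normalize=True)
    summary = pd.DataFrame({
        "fraction": [frac.get(k, 0.0) for k in
                     (LABEL_SINGLE, LABEL_ASSIST, LABEL_NONPROD)],
        "count": [int((labels == k).sum()) for k in
                  (LABEL_SINGLE, LABEL_ASSIST, LABEL_NONPROD)],
    }, index=[LABEL_SINGLE, LABEL_ASSIST, LABEL_NONPROD])
    return records, summary


def hbond_occupancy(records, cutoff: float = 2.5) -> float:
    """Fraction of frames whose closest water hydrogen is within `cutoff`
    of His-Nδ (the short-H-bond occupancy of the catalytic histidine)."""
    if not records:
        raise ValidationError("no records")
    hits = sum(1 for r in records if r.d_nd_h < cutoff)
    return hits / len(records)


@dataclass
class ClusterResult:
    assignments: np.ndarray      # cluster id per record, -1 = noise
    fractions: dict              # cluster id → fraction of all records
    centroids: dict              # cluster id → (x, y) centroid
    threshold: float
    n_clusters: int


def cluster_microstates(records, fields=("d_nd_c", "d_ca_opopc"),
                        kde_sigma: float = 1.0,
                        density_quantile: float = 0.5,
                        grid_bin: float = 0.05) -> ClusterResult:
    """Density-based clustering in a 2-distance plane.

    A Gaussian kernel-density estimate (width `kde_sigma`, Å) is evaluated
    on a grid; cells whose density exceeds the `density_quantile` of all
    grid-cell densities form 8-connected components, and each record joins
    the component containing its cell (else noise).
    """
    if len(records) < 50:
        raise ValidationError("need at least 50 records to cluster")
    x = np.array([getattr(r, fields[0]) for r in records])
    y = np.array([getattr(r, fields[1]) for r in records])
    tol_x = 1e-12 * max(1.0, abs(float(x.mean())))
    tol_y = 1e-12 * max(1.0, abs(float(y.mean())))
    if x.std() <= tol_x and y.std() <= tol_y:
        raise ValidationError("degenerate data: zero variance in both fields")

    pad = 3.0 * kde_sigma
    gx = np.arange(x.min() - pad, x.max() + pad + grid_bin, grid_bin)
    gy = np.arange(y.min() - pad, y.max() + pad + grid_bin, grid_bin)
    hist, _, _ = np.histogram2d(x, y, bins=[gx, gy])
    dens = ndimage.gaussian_filter(hist, sigma=kde_sigma / grid_bin,
                                   mode="constant")

    ix = np.clip(np.searchsorted(gx, x, side="right") - 1, 0, len(gx) - 2)
    iy = np.clip(np.searchsorted(gy, y, side="right") - 1, 0, len(gy) - 2)
    thr = float(np.quantile(dens, density_quantile))

    mask = dens > thr
    structure = np.ones((3, 3), dtype=int)          # 8-neighbourhood
    labels_grid, n_comp = ndimage.label(mask, structure=structure)
    assign = labels_grid[ix, iy] - 1                # -1 = below threshold

    fractions, centroids = {}, {}
    for cid in range(n_comp):
        sel = assign == cid
        if not sel.any():
            continue
        fractions[cid] = float(sel.mean())
        centroids[cid] = (float(x[sel].mean()), float(y[sel].mean()))
    return ClusterResult(assign, fractions, centroids, thr, len(fractions))


def state_distance_summary(records) -> pd.DataFrame:
    """Mean and standard deviation of every catalytic distance per label."""
    rows = []
    for r in records:
        if r.label is None:
            raise ValidationError("records must be classified first")
        rows.append((r.label, r.d_nd_h, r.d_c_o, r.d_o_h_bridge,
                     r.d_nd_c, r.d_ca_opopc, r.d_ca_ow))
    df = pd.DataFrame(rows, columns=["label", "d_nd_h", "d_c_o",
                                     "d_o_h_bridge", "d_nd_c",
                                     "d_ca_opopc", "d_ca_ow"])
    df = df.replace(np.inf, np.nan)

    def _sd(v):  # population convention: a lone record has spread 0
        return float(np.std(v.dropna())) if v.notna().any() else np.nan

    return df.groupby("label").agg(["mean", _sd]).rename(
        columns={"_sd": "sd"}, level=1)
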