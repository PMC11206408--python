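"""Per-residue electrostatic contributions to the activation barrier.

Each MM residue's point charges interact with the QM-region charge
distribution of the reactant (R) and transition state (TS); the residue's
barrier contribution is the interaction-energy difference

    ΔΔE_a(residue) = E_int(residue, TS) − E_int(residue, R),

equivalently the barrier change when the residue's charges are deleted,
with the sign convention that negative values stabilise the TS (the
residue lowers the barrier). Electrostatics are bare Coulomb sums in
vacuum (ε = 1, no cutoff) over point charges in elementary-charge units
and Å, giving kcal mol⁻¹ through the 332.0637 conversion constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import COULOMB_K
from .io_formats import ValidationError

#: four-way residue classification used for display grouping
RESIDUE_CLASSES = {
    "ASP": "negative", "GLU": "negative",
    "LYS": "positive", "ARG": "positive", "HIS": "positive",
    "SER": "polar", "THR": "polar", "ASN": "polar", "GLN": "polar",
    "TYR": "polar", "CYS": "polar", "TRP": "polar",
    "ALA": "apolar", "VAL": "apolar", "LEU": "apolar", "ILE": "apolar",
    "MET": "apolar", "PHE": "apolar", "PRO": "apolar", "GLY": "apolar",
}


def classify_residue(name: str) -> str:
    return RESIDUE_CLASSES.get(name.upper()[:3], "apolar")


@dataclass
class ChargeGroup:
    """One residue's point charges: list of (q in e, position in Å)."""

    label: str
    charges: list
    classification: str = "apolar"

    def q_array(self):
        return np.array([q for q, _ in self.charges], dtype=float)

    def pos_array(self):
        return np.array([p for _, p in self.charges], dtype=float).reshape(-1, 3)

    def scaled(self, factor: float) -> "ChargeGroup":
        return ChargeGroup(self.label,
                           [(q * factor, p) for q, p in self.charges],
                           self.classification)


@dataclass
class StateChargeSystem:
    """QM charges for both states plus the MM residue groups per state.

    Group geometries may differ between R and TS; labels must match.
    """

    qm_r: tuple                 # (charges (n,), positions (n, 3))
    qm_ts: tuple
    mm_groups_r: list = field(default_factory=list)
    mm_groups_ts: list | None = None   # defaults to the R geometries

    def __post_init__(self):
        if self.mm_groups_ts is None:
            self.mm_groups_ts = self.mm_groups_r
        labels_r = {g.label for g in self.mm_groups_r}
        labels_ts = {g.label for g in self.mm_groups_ts}
        if labels_r != labels_ts:
            missing = labels_r ^ labels_ts
            raise ValidationError(
                f"groups present in one state only: {sorted(missing)}")


@dataclass
class ResidueBarrierContribution:
    label: str
    dde_a: float                # kcal mol⁻¹, negative = TS-stabilising
    classification: str
    axis_coordinate: float | None = None


def coulomb_interaction(group: ChargeGroup, qm_charges) -> float:
    """Bare Coulomb energy between a residue group and a QM charge set,
    E = 332.0637 Σᵢⱼ qᵢqⱼ/rᵢⱼ (kcal mol⁻¹). Pairs closer than 0.1 Å are a
    singularity error."""
    q_mm, p_mm = group.q_array(), group.pos_array()
    q_qm, p_qm = qm_charges
    q_qm = np.asarray(q_qm, dtype=float)
    p_qm = np.asarray(p_qm, dtype=float).reshape(-1, 3)
    if q_mm.size == 0 or q_qm.size == 0:
        return 0.0
    r = cdist(p_mm, p_qm)
    if np.any(r < 0.1):
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise ValidationError(
            f"near-singular pair: {group.label} charge {i} within "
            f"{r[i, j]:.3f} Å of QM charge {j}")
    return float(COULOMB_K * np.sum(np.outer(q_mm, q_qm) / r))


def residue_deletion_scan(system: StateChargeSystem) -> list:
    """ΔΔE_a for every MM residue group (each state uses its own
    geometry). Pairwise additivity makes the group total exactly the
    total-interaction difference between the states."""
    ts_by_label = {g.label: g for g in system.mm_groups_ts}
    out = []
    for g_r in system.mm_groups_r:
        g_ts = ts_by_label[g_r.label]
        e_r = coulomb_interaction(g_r, system.qm_r)
        e_ts = coulomb_interaction(g_ts, system.qm_ts)
        out.append(ResidueBarrierContribution(
            g_r.label, e_ts - e_r, g_r.classification))
    return out


def axis_projection(group: ChargeGroup, acceptor_reference,
                    donor_reference) -> float:
    """Geometric display axis: d(cog → proton-accepting base reference) −
    d(cog → proton-donating acid reference). The sign places the residue on
    one side of the plane dividing the protein between the two reaction
    centres."""
    cog = group.pos_array().mean(axis=0)
    acc = np.asarray(acceptor_reference, dtype=float)
    don = np.asarray(donor_reference, dtype=float)
    return float(np.linalg.norm(cog - acc) - np.linalg.norm(cog - don))


def scan_to_frame(contributions) -> pd.DataFrame:
    df = pd.DataFrame(
        [(c.label, c.dde_a, c.classification, c.axis_coordinate)
         for c in contributions],
        columns=["label", "dde_a_kcal", "classification", "axis_coordinate"])
    return df.set_index("label")


# ---------------------------------------------------------------------------
# plain-text charge tables: label q x y z, '#' comments
# ---------------------------------------------------------------------------

def read_charge_table(path):
    """QM-region table → (charges, positions)."""
    qs, ps = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 5:
                raise ValidationError(f"{path}:{lineno}: expected 'label q x y z'")
            qs.append(float(parts[1]))
            ps.append([float(parts[2]), float(parts[3]), float(parts[4])])
    return np.asarray(qs), np.asarray(ps).reshape(-1, 3)


def read_group_table(path):
    """MM residue table → list of ChargeGroup (rows grouped by label)."""
    groups: dict[str, list] = {}
    order = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 5:
                raise ValidationError(f"{path}:{lineno}: expected 'label q x y z'")
            label = parts[0]
            if label not in groups:
                groups[label] = []
                order.append(label)
            groups[label].append((float(parts[1]),
                                  np.array([float(parts[2]), float(parts[3]),
                                            float(parts[4])])))
    return [ChargeGroup(lbl, groups[lbl],
                        classify_residue(lbl.split("_")[0]))
            for lbl in order]
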