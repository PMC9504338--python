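"""Ligand-receptor interaction fingerprints.

Geometric detection, per frame, of hydrogen bonds, weak hydrogen bonds and
hydrophobic contacts between a ligand selection and a receptor selection,
followed by persistence filtering (a contact must hold in at least a
fraction of frames to be counted).

Default criteria (configurable, always echoed in reports): strong hydrogen
bond at donor-acceptor distance <= 3.5 Å with donor-H-acceptor angle >=
120 deg; weak hydrogen bond in the 3.5-4.0 Å distance bin (or angle
90-120 deg within 3.5 Å); hydrophobic contact between apolar carbons
within 4.5 Å; persistence >= 0.5.  When the topology carries no hydrogens
the angle term is dropped and detection falls back to donor-acceptor
distance only (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .traj_io import AtomSelection, Trajectory

log = logging.getLogger(__name__)

_POLAR_ELEMENTS = {"N", "O"}
_COVALENT_H_MAX = 1.25    # Å, H considered bonded to a donor below this
_POLAR_BOND_MAX = 1.75    # Å, carbon-heteroatom bond distance for polarity typing


@dataclass
class InteractionCriteria:
    hbond_distance_max: float = 3.5          # Å donor-acceptor
    hbond_angle_min: float = 120.0           # deg donor-H-acceptor
    weak_hbond_distance_range: tuple[float, float] = (3.5, 4.0)
    weak_hbond_angle_range: tuple[float, float] = (90.0, 120.0)
    hydrophobic_distance_max: float = 4.5    # Å carbon-carbon
    persistence_min: float = 0.5             # fraction of frames

    def __post_init__(self):
        if min(self.hbond_distance_max, self.hydrophobic_distance_max) <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not 0 < self.hbond_angle_min <= 180:
            raise ValueError("hbond_angle_min must be in (0, 180]")
        lo, hi = self.weak_hbond_distance_range
        if lo < self.hbond_distance_max - 1e-9:
            raise ValueError("weak H-bond distance range must start at or above the strong cutoff")
        if hi <= lo:
            raise ValueError("weak H-bond distance range must be increasing")
        if not 0 <= self.persistence_min <= 1:
            raise ValueError("persistence_min must be in [0, 1]")


@dataclass
class Contact:
    atom_i: int          # ligand atom index (0-based)
    atom_j: int          # receptor atom index
    residue_j: int       # 1-based receptor residue
    occupancy: float


@dataclass
class InteractionFingerprint:
    hbonds: list[Contact]
    weak_hbonds: list[Contact]
    hydrophobic_contacts: list[Contact]
    criteria: InteractionCriteria
    per_residue: dict[int, dict[str, int]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {"hbonds": len(self.hbonds), "weak_hbonds": len(self.weak_hbonds),
                "hydrophobic": len(self.hydrophobic_contacts)}


def _polar_atoms(traj: Trajectory, selection: AtomSelection):
    """Polar heavy atoms (N, O) and, for donors, their covalent hydrogens.

    Bonding is inferred from first-frame geometry, which is adequate for
    the rigid covalent scaffold the detection needs.
    """
    top = traj.topology
    xyz0 = traj.coordinates[0]
    sel = selection.indices
    heavies = [a for a in sel if top.elements[a].upper() in _POLAR_ELEMENTS]
    hydrogens = [a for a in sel if top.elements[a].upper() == "H"]
    attached: dict[int, list[int]] = {a: [] for a in heavies}
    if hydrogens and heavies:
        D = cdist(xyz0[heavies], xyz0[hydrogens])
        for hi, h in enumerate(hydrogens):
            k = int(np.argmin(D[:, hi]))
            if D[k, hi] <= _COVALENT_H_MAX:
                attached[heavies[k]].append(h)
    return heavies, attached


def _apolar_carbons(traj: Trajectory, selection: AtomSelection) -> list[int]:
    """Carbons with no covalently bonded N/O (first-frame geometry)."""
    top = traj.topology
    xyz0 = traj.coordinates[0]
    sel = selection.indices
    carbons = [a for a in sel if top.elements[a].upper() == "C"]
    polars = [a for a in sel if top.elements[a].upper() in _POLAR_ELEMENTS]
    if not carbons:
        return []
    if not polars:
        return carbons
    D = cdist(xyz0[carbons], xyz0[polars])
    return [c for ci, c in enumerate(carbons) if D[ci].min() > _POLAR_BOND_MAX]


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = (u @ v) / max(np.linalg.norm(u) * np.linalg.norm(v), 1e-300)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(traj: Trajectory, ligand: AtomSelection, receptor: AtomSelection,
                  criteria: InteractionCriteria | None = None
                  ) -> tuple[list[Contact], list[Contact]]:
    """Strong and weak hydrogen bonds between ligand and receptor.

    Both donor directions are evaluated.  Classification per frame: strong
    when distance <= hbond_distance_max and (with hydrogens) the
    donor-H-acceptor angle >= hbond_angle_min; weak when the distance falls
    in ``weak_hbond_distance_range``, or the angle in
    ``weak_hbond_angle_range`` at strong-bin distance.  Occupancy is the
    per-pair fraction of frames; pairs below ``persistence_min`` are dropped.
    """
    crit = criteria or InteractionCriteria()
    lig_heavies, lig_h = _polar_atoms(traj, ligand)
    rec_heavies, rec_h = _polar_atoms(traj, receptor)
    if not lig_heavies or not rec_heavies:
        log.warning("no polar atoms in ligand or receptor selection; no hydrogen bonds")
        return [], []
    has_h = any(lig_h.values()) or any(rec_h.values())
    if not has_h:
        log.info("topology carries no hydrogens: hydrogen bonds use donor-acceptor "
                 "distance only")
    F = traj.n_frames
    strong = np.zeros((len(lig_heavies), len(rec_heavies)))
    weak = np.zeros_like(strong)
    lo, hi = crit.weak_hbond_distance_range
    alo, ahi = crit.weak_hbond_angle_range
    for f in range(F):
        xyz = traj.coordinates[f]
        D = cdist(xyz[lig_heavies], xyz[rec_heavies])
        for i, a_lig in enumerate(lig_heavies):
            for j, a_rec in enumerate(rec_heavies):
                d = D[i, j]
                if d > hi:
                    continue
                hydrogens = lig_h.get(a_lig, []) + rec_h.get(a_rec, [])
                if has_h and hydrogens:
                    # donor-H-acceptor angle; symmetric in the heavy endpoints,
                    # so one expression covers both donor directions
                    best = max(_angle_deg(xyz[a_lig], xyz[h], xyz[a_rec])
                               for h in hydrogens)
                    if d <= crit.hbond_distance_max and best >= crit.hbond_angle_min:
                        strong[i, j] += 1
                    elif (lo <= d <= hi and best >= crit.hbond_angle_min) or \
                         (d <= crit.hbond_distance_max and alo < best < ahi):
                        weak[i, j] += 1
                else:
                    if d <= crit.hbond_distance_max:
                        strong[i, j] += 1
                    elif lo <= d <= hi:
                        weak[i, j] += 1
    out_strong, out_weak = [], []
    resids = traj.topology.resids
    for i, a_lig in enumerate(lig_heavies):
        for j, a_rec in enumerate(rec_heavies):
            occ_s, occ_w = strong[i, j] / F, weak[i, j] / F
            if occ_s >= crit.persistence_min:
                out_strong.append(Contact(a_lig, a_rec, int(resids[a_rec]), occ_s))
            elif occ_w >= crit.persistence_min:
                out_weak.append(Contact(a_lig, a_rec, int(resids[a_rec]), occ_w))
    return out_strong, out_weak


def detect_hydrophobic(traj: Trajectory, ligand: AtomSelection,
                       receptor: AtomSelection,
                       criteria: InteractionCriteria | None = None) -> list[Contact]:
    """Apolar carbon-carbon contacts within the hydrophobic cutoff,
    persistence-filtered; the reported count is the list length."""
    crit = criteria or InteractionCriteria()
    lig_c = _apolar_carbons(traj, ligand)
    rec_c = _apolar_carbons(traj, receptor)
    if not lig_c or not rec_c:
        log.warning("no apolar carbons in ligand or receptor selection")
        return []
    F = traj.n_frames
    hits = np.zeros((len(lig_c), len(rec_c)))
    for f in range(F):
        D = cdist(traj.coordinates[f, lig_c, :], traj.coordinates[f, rec_c, :])
        hits += D <= crit.hydrophobic_distance_max
    occ = hits / F
    resids = traj.topology.resids
    out = []
    for i, a_lig in enumerate(lig_c):
        for j, a_rec in enumerate(rec_c):
            if occ[i, j] >= crit.persistence_min:
                out.append(Contact(a_lig, a_rec, int(resids[a_rec]), float(occ[i, j])))
    return out


def fingerprint_summary(traj: Trajectory, ligand: AtomSelection,
                        receptor: AtomSelection,
                        criteria: InteractionCriteria | None = None
                        ) -> InteractionFingerprint:
    """Combined fingerprint with totals and per-residue aggregation."""
    if len(ligand) == 0 or len(receptor) == 0:
        raise ValueError("ligand and receptor selections must be nonempty")
    crit = criteria or InteractionCriteria()
    strong, weak = detect_hbonds(traj, ligand, receptor, crit)
    hydrophobic = detect_hydrophobic(traj, ligand, receptor, crit)
    per_residue: dict[int, dict[str, int]] = {}
    for kind, contacts in (("hbonds", strong), ("weak_hbonds", weak),
                           ("hydrophobic", hydrophobic)):
        for c in contacts:
            row = per_residue.setdefault(c.residue_j,
                                         {"hbonds": 0, "weak_hbonds": 0, "hydrophobic": 0})
            row[kind] += 1
    return InteractionFingerprint(hbonds=strong, weak_hbonds=weak,
                                  hydrophobic_contacts=hydrophobic,
                                  criteria=crit, per_residue=per_residue)
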