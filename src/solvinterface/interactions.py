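"""Interfacial interaction detection.

Three detector families over a partitioned antibody-antigen complex:

* Atomistic contact pairs (ACPs): cross-interface heavy-atom pairs closer
  than vdW(x) + vdW(y) + 0.5 Å, classified by precedence into aromatic
  (aACP), non-aromatic carbon-carbon (naCC), carbon-polar, donor-donor /
  acceptor-acceptor and other-polar contacts.
* Direct hydrogen bonds (DHBs): D-A ≤ 3.5 Å with D-H-A ≥ 150° for donors
  with fixed hydrogens; for the torsionally flexible sidechain donors the
  angle cutoff is replaced by a hydrogen-between constraint evaluated by a
  36°-step torsion scan at ideal bond geometry.
* Water-mediated hydrogen bonds (WMHBs): a rigid water model rotated
  through a 10 x 10 x 5 Euler grid (36° steps, third angle halved for the
  C2 symmetry of water) must hydrogen-bond to both sides of the interface
  in at least one common orientation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from solvinterface.structio import (
    DONOR_GEOMETRY,
    N_H_LENGTH,
    O_H_LENGTH,
    THREE_TO_ONE,
    AtomRecord,
    CdrAnnotation,
    StructureModel,
)

__all__ = [
    "HBCriteria",
    "ContactPair",
    "DirectHBond",
    "OrientationGrid",
    "WaterBridge",
    "InterfaceSummary",
    "find_acps",
    "classify_acps",
    "find_dhbs",
    "water_orientations",
    "find_wmhbs",
    "summarize_interface",
    "ACP_CLASSES",
    "INTERACTION_CLASSES",
]

ACP_CLASSES = ("aACP", "naCC", "carbon-polar", "donor-donor",
               "acceptor-acceptor", "other-polar")
#: The four interaction classes tracked per CDR position.
INTERACTION_CLASSES = ("aACP", "naCC", "DHB", "WMHB")

CONTACT_BUFFER = 0.5


@dataclass(frozen=True)
class HBCriteria:
    """Geometric hydrogen-bond criteria.

    ``d_max``/``angle_min`` are the rigid-donor cutoffs; flexible donors
    replace the angle cutoff by requiring some scanned hydrogen with
    D-H-A ≥ ``flexible_angle_min`` and H···A ≤ ``flexible_ha_max``.
    """

    d_max: float = 3.5
    angle_min: float = 150.0
    flexible_angle_min: float = 120.0
    flexible_ha_max: float = 2.8
    torsion_step: float = 36.0

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.angle_min <= 180:
            raise ValueError("angle_min must be in (0, 180]")


DEFAULT_CRITERIA = HBCriteria()


@dataclass
class ContactPair:
    ab_atom: AtomRecord
    ag_atom: AtomRecord
    distance: float
    acp_class: str | None = None


@dataclass
class DirectHBond:
    donor: AtomRecord
    acceptor: AtomRecord
    distance: float
    hydrogen: tuple | None = None   # (name, position) for rigid donors
    angle: float | None = None      # absent for flexible-donor acceptances
    flexible: bool = False


@dataclass
class OrientationGrid:
    """Rigid-water rotation grid (ZYZ Euler angles)."""

    step: float
    counts: tuple
    rotations: np.ndarray      # (N, 3, 3) proper rotation matrices
    template_h: np.ndarray     # (2, 3) hydrogen offsets from the oxygen

    def __len__(self):
        return len(self.rotations)


@dataclass
class WaterBridge:
    water_index: int
    ab_atom: AtomRecord
    ab_role: str  # role of the protein atom: "donor" or "acceptor"
    ag_atom: AtomRecord
    ag_role: str
    orientations: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry helpers


def _angle_deg(p_left, apex, p_right) -> float:
    u = p_left - apex
    v = p_right - apex
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


def _orthonormal_frame(axis):
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(axis, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return axis, u, v


def scanned_hydrogens(donor: AtomRecord, by_name: dict,
                      criteria: HBCriteria = DEFAULT_CRITERIA):
    """Candidate hydrogen positions for a flexible donor's torsion scan.

    The hydrogen is placed at ideal bond length on a cone around the
    antecedent-donor axis (tetrahedral or trigonal X-D-H angle), sampled
    every ``criteria.torsion_step`` degrees.  Returns an (n, 3) array, or
    None when the antecedent heavy atom is missing.
    """
    geom = DONOR_GEOMETRY.get((donor.res_name, donor.name))
    if geom is None:
        return None
    parent_name, _, hyb = geom
    parent = by_name.get(parent_name)
    if parent is None:
        return None
    bond_angle = 109.5 if hyb == "sp3" else 120.0
    length = O_H_LENGTH if donor.element == "O" else N_H_LENGTH
    axis, u, v = _orthonormal_frame(donor.pos - parent.pos)
    theta = math.radians(180.0 - bond_angle)
    phis = np.radians(np.arange(0.0, 360.0, criteria.torsion_step))
    dirs = (math.cos(theta) * axis[None, :]
            + math.sin(theta) * (np.cos(phis)[:, None] * u[None, :]
                                 + np.sin(phis)[:, None] * v[None, :]))
    return donor.pos + length * dirs


def _flexible_ok(donor, by_name, acceptor_pos, criteria):
    hs = scanned_hydrogens(donor, by_name, criteria)
    if hs is None:
        return False
    for h in hs:
        if np.linalg.norm(h - acceptor_pos) <= criteria.flexible_ha_max and \
                _angle_deg(donor.pos, h, acceptor_pos) >= criteria.flexible_angle_min:
            return True
    return False


def _rigid_best(donor, acceptor_pos, criteria):
    """Best (angle, hydrogen) meeting the rigid criterion, else None."""
    best = None
    for name, hpos in donor.hydrogens:
        ang = _angle_deg(donor.pos, hpos, acceptor_pos)
        if ang >= criteria.angle_min and (best is None or ang > best[0]):
            best = (ang, (name, hpos))
    return best


def _residue_atom_maps(model: StructureModel):
    out = {}
    for key, _, atoms in model.residues():
        out[key] = {a.name: a for a in atoms}
    return out


# ---------------------------------------------------------------------------
# ACPs


def find_acps(model: StructureModel, table=None) -> list:
    """All cross-partition heavy-atom pairs within vdW sum + 0.5 Å."""
    if not model.annotated:
        raise ValueError("model must be annotated before contact detection")
    model.require_partition()
    ab = [a for a in model.side_atoms("antibody") if a.element != "H"]
    ag = [a for a in model.side_atoms("antigen") if a.element != "H"]
    if not ab or not ag:
        return []
    ab_pos = np.array([a.pos for a in ab])
    ag_pos = np.array([a.pos for a in ag])
    ab_r = np.array([a.vdw_radius for a in ab])
    ag_r = np.array([a.vdw_radius for a in ag])
    cutoff = ab_r.max() + ag_r.max() + CONTACT_BUFFER
    pairs = cKDTree(ab_pos).query_ball_tree(cKDTree(ag_pos), cutoff)
    out = []
    for i, neigh in enumerate(pairs):
        for j in sorted(neigh):
            d = float(np.linalg.norm(ab_pos[i] - ag_pos[j]))
            if d < ab_r[i] + ag_r[j] + CONTACT_BUFFER:
                out.append(ContactPair(ab[i], ag[j], d))
    return out


def classify_acps(pairs, include_his: bool = False):
    """Assign one contact class per pair by precedence.

    Precedence: antibody-side aromatic-ring carbon (Phe/Trp/Tyr; His only
    with ``include_his``) → aACP; both carbons → naCC; carbon against N/O →
    carbon-polar; donor-donor / acceptor-acceptor by flags; other-polar.
    Returns (tagged pairs, per-class counts).
    """
    counts = {c: 0 for c in ACP_CLASSES}
    for p in pairs:
        ab, ag = p.ab_atom, p.ag_atom
        aromatic_ab = (ab.is_carbon and ab.is_aromatic_ring_atom
                       and (include_his or ab.res_name != "HIS"))
        if aromatic_ab:
            cls = "aACP"
        elif ab.is_carbon and ag.is_carbon:
            cls = "naCC"
        elif (ab.is_carbon and ag.element in ("N", "O")) or \
                (ag.is_carbon and ab.element in ("N", "O")):
            cls = "carbon-polar"
        elif ab.is_hb_donor_heavy and ag.is_hb_donor_heavy:
            cls = "donor-donor"
        elif ab.is_hb_acceptor and ag.is_hb_acceptor:
            cls = "acceptor-acceptor"
        else:
            cls = "other-polar"
        p.acp_class = cls
        counts[cls] += 1
    return pairs, counts


# ---------------------------------------------------------------------------
# DHBs


def find_dhbs(model: StructureModel, criteria: HBCriteria = DEFAULT_CRITERIA) -> list:
    """Cross-partition direct hydrogen bonds (both directions).

    Rigid donors need an attached hydrogen with D-H-A ≥ the angle cutoff;
    flexible donors pass through the torsion-scan hydrogen-between test.
    Donors lacking both hydrogens and a scan geometry are skipped with a
    warning.
    """
    model.require_partition()
    res_maps = _residue_atom_maps(model)
    ab = [a for a in model.side_atoms("antibody") if a.element != "H"]
    ag = [a for a in model.side_atoms("antigen") if a.element != "H"]
    out = []
    for donors, acceptors in ((ab, ag), (ag, ab)):
        donors = [a for a in donors if a.is_hb_donor_heavy]
        acceptors = [a for a in acceptors if a.is_hb_acceptor]
        if not donors or not acceptors:
            continue
        d_pos = np.array([a.pos for a in donors])
        a_pos = np.array([a.pos for a in acceptors])
        neigh = cKDTree(d_pos).query_ball_tree(cKDTree(a_pos), criteria.d_max)
        for i, js in enumerate(neigh):
            donor = donors[i]
            for j in sorted(js):
                acc = acceptors[j]
                dist = float(np.linalg.norm(donor.pos - acc.pos))
                if dist > criteria.d_max:
                    continue
                if donor.is_rotatable_donor:
                    if _flexible_ok(donor, res_maps[donor.residue_key],
                                    acc.pos, criteria):
                        out.append(DirectHBond(donor, acc, dist, flexible=True))
                else:
                    if not donor.hydrogens:
                        warnings.warn(
                            f"rigid donor {donor!r} has no hydrogens; skipped"
                        )
                        break
                    best = _rigid_best(donor, acc.pos, criteria)
                    if best is not None:
                        out.append(DirectHBond(donor, acc, dist,
                                               hydrogen=best[1], angle=best[0]))
    return out


# ---------------------------------------------------------------------------
# Water orientation grid and WMHBs

WATER_OH = 0.9572
WATER_HOH = 104.52


def water_orientations(step: float = 36.0) -> OrientationGrid:
    """Rigid-water rotation grid: ZYZ Euler angles sampled every ``step``°.

    The first two angles cover 360°, the third 180° (water's C2 symmetry
    maps the remaining half onto it), so step 36° gives 10 x 10 x 5 = 500
    orientations.
    """
    if step <= 0 or 360.0 % step or 180.0 % step:
        raise ValueError("orientation step must divide 360 (and 180)")
    n_full = int(round(360.0 / step))
    n_half = int(round(180.0 / step))
    angles = [
        (a, b, g)
        for a in np.arange(n_full) * step
        for b in np.arange(n_full) * step
        for g in np.arange(n_half) * step
    ]
    rots = Rotation.from_euler("ZYZ", angles, degrees=True).as_matrix()
    half = math.radians(WATER_HOH / 2.0)
    template = np.array([
        [WATER_OH * math.sin(half), 0.0, WATER_OH * math.cos(half)],
        [-WATER_OH * math.sin(half), 0.0, WATER_OH * math.cos(half)],
    ])
    return OrientationGrid(step=step, counts=(n_full, n_full, n_half),
                           rotations=rots, template_h=template)


def find_wmhbs(model: StructureModel, waters, criteria: HBCriteria = DEFAULT_CRITERIA,
               grid: OrientationGrid | None = None) -> list:
    """Water bridges between the two sides of the interface.

    For every supplied water the rigid water template is rotated through
    the orientation grid about its oxygen.  The water donates to a protein
    acceptor when O-A ≤ d_max and O-H-A ≥ the angle cutoff for an oriented
    hydrogen; it accepts from a protein donor through the rigid/flexible
    direct-bond test with the water oxygen as acceptor (orientation-free).
    A bridge requires one antibody-side and one antigen-side partner
    satisfied simultaneously in at least one common orientation.
    """
    if grid is None:
        grid = water_orientations(criteria.torsion_step)
    model.require_partition()
    positions = waters.positions if hasattr(waters, "positions") else waters
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if len(positions) == 0:
        return []
    res_maps = _residue_atom_maps(model)
    heavy = [a for a in model.atoms if a.element != "H"]
    polar = [a for a in heavy if a.is_hb_donor_heavy or a.is_hb_acceptor]
    if not polar:
        return []
    p_pos = np.array([a.pos for a in polar])
    tree = cKDTree(p_pos)
    # (N, 2, 3) oriented hydrogen offsets
    h_off = np.einsum("nij,kj->nki", grid.rotations, grid.template_h)
    n_orient = len(grid.rotations)

    bridges = []
    for widx, w in enumerate(positions):
        partners = []  # (atom, protein_role, orientation mask or None)
        for j in tree.query_ball_point(w, criteria.d_max):
            atom = polar[j]
            if model.side_of(atom.chain_id) is None:
                continue
            dist = np.linalg.norm(atom.pos - w)
            if dist > criteria.d_max:
                continue
            if atom.is_hb_donor_heavy:
                ok = (_flexible_ok(atom, res_maps[atom.residue_key], w, criteria)
                      if atom.is_rotatable_donor
                      else _rigid_best(atom, w, criteria) is not None)
                if ok:
                    partners.append((atom, "donor", None))
            if atom.is_hb_acceptor:
                h = w + h_off  # (N, 2, 3) absolute hydrogen positions
                wo = w - h
                ao = atom.pos - h
                cosang = np.einsum("nki,nki->nk", wo, ao) / (
                    np.linalg.norm(wo, axis=-1) * np.linalg.norm(ao, axis=-1)
                )
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                mask = (ang >= criteria.angle_min).any(axis=1)
                if mask.any():
                    partners.append((atom, "acceptor", mask))
        seen = set()
        for a_atom, a_role, a_mask in partners:
            if model.side_of(a_atom.chain_id) != "antibody":
                continue
            for b_atom, b_role, b_mask in partners:
                if model.side_of(b_atom.chain_id) != "antigen":
                    continue
                key = (a_atom.key, b_atom.key)
                if key in seen:
                    continue
                if a_mask is None and b_mask is None:
                    common = np.arange(n_orient)
                else:
                    m = np.ones(n_orient, dtype=bool)
                    if a_mask is not None:
                        m &= a_mask
                    if b_mask is not None:
                        m &= b_mask
                    common = np.flatnonzero(m)
                if len(common):
                    seen.add(key)
                    bridges.append(WaterBridge(widx, a_atom, a_role,
                                               b_atom, b_role, list(common)))
    return bridges


# ---------------------------------------------------------------------------
# Interface summary


@dataclass
class InterfaceSummary:
    """Per-CDR-position interaction record for one complex."""

    complex_id: str
    positions: dict          # IMGT label -> {"aa": letter, "classes": set}
    class_totals: dict       # class -> #positions showing it
    pair_counts: dict        # class -> raw detection counts (incl. all ACP classes)
    epitope: list            # antigen residue keys in >=1 ACP
    n_cdr_positions: int


def summarize_interface(model: StructureModel, cdrs: CdrAnnotation,
                        acps, dhbs, wmhbs, complex_id: str = "") -> InterfaceSummary:
    """Fold detections into a per-IMGT-position record.

    A position shows a class when any detection of that class involves an
    antibody atom of the residue mapped to the position.  Class totals are
    de-duplicated by (position, class); raw detection counts are kept
    separately.  The epitope is the set of antigen residues in at least one
    contact pair of any class.
    """
    if len(cdrs) == 0 or not cdrs.cdr_labels:
        raise ValueError("refusing to summarize with an empty CDR annotation")
    res_names = {key: name for key, name, _ in model.residues()}
    label_of = {cdrs.positions[lab]: lab for lab in cdrs.cdr_labels}
    positions = {}
    for lab in cdrs.cdr_labels:
        key = cdrs.positions[lab]
        positions[lab] = {
            "aa": THREE_TO_ONE.get(res_names.get(key, ""), "X"),
            "classes": set(),
        }

    def mark(atom, cls):
        lab = label_of.get(atom.residue_key)
        if lab is not None:
            positions[lab]["classes"].add(cls)

    pair_counts = {c: 0 for c in ACP_CLASSES}
    pair_counts["DHB"] = len(dhbs)
    pair_counts["WMHB"] = len(wmhbs)
    epitope = []
    for p in acps:
        if p.acp_class is None:
            raise ValueError("ACPs must be classified before summarizing")
        pair_counts[p.acp_class] += 1
        if p.acp_class in ("aACP", "naCC"):
            mark(p.ab_atom, p.acp_class)
        if p.ag_atom.residue_key not in epitope:
            epitope.append(p.ag_atom.residue_key)
    for b in dhbs:
        ab = b.donor if model.side_of(b.donor.chain_id) == "antibody" else b.acceptor
        mark(ab, "DHB")
    for b in wmhbs:
        mark(b.ab_atom, "WMHB")

    class_totals = {
        c: sum(1 for rec in positions.values() if c in rec["classes"])
        for c in INTERACTION_CLASSES
    }
    return InterfaceSummary(
        complex_id=complex_id,
        positions=positions,
        class_totals=class_totals,
        pair_counts=pair_counts,
        epitope=sorted(epitope),
        n_cdr_positions=len(positions),
    )
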