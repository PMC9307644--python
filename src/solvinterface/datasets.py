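"""Structure-set curation and null-model decoy generation.

Implements the sequential selection filters used to build a non-redundant
antibody-protein complex set (antigen length, CDR completeness and
lengths, conformational epitope, 95% heavy-chain identity clustering) and
a seeded rigid-body decoy sampler that docks the native paratope onto
non-native epitope surface, scoring poses by cross-interface contact count
— a geometric null model for interface statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from solvinterface.interactions import find_acps
from solvinterface.structio import StructureModel, annotate_atoms

__all__ = [
    "ComplexCriteria",
    "EpitopeSegmentation",
    "DecoyPose",
    "filter_complexes",
    "epitope_segments",
    "generate_decoys",
    "sequence_identity",
]


@dataclass(frozen=True)
class ComplexCriteria:
    """Sequential acceptance criteria for antibody-protein complexes."""

    cdr_lengths: tuple = ((("H1", 13), ("H2", 10), ("L1", 11), ("L2", 8), ("L3", 9)))
    min_antigen_length: int = 35
    require_conformational: bool = True
    identity_cutoff: float = 0.95
    gap_tolerance: int = 2

    def __post_init__(self):
        if not 0 < self.identity_cutoff <= 1:
            raise ValueError("identity cutoff must be in (0, 1]")


@dataclass
class EpitopeSegmentation:
    """Epitope residues split into maximal contiguous runs."""

    residues: list                 # sorted (chain, resnum, icode) keys
    segments: list                 # list of lists of keys
    gap_tolerance: int

    @property
    def conformational(self) -> bool:
        return len(self.segments) >= 2


@dataclass
class DecoyPose:
    """A rigid antibody placement accepted by the decoy sampler."""

    rotation: np.ndarray       # (3, 3)
    translation: np.ndarray    # (3,)
    clash_count: int
    paratope_centering: float  # Å, transformed-paratope vs contact centroid
    native_overlap: int        # shared residues with the native epitope
    score: int                 # cross-partition ACP count
    epitope: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Epitope segmentation


def epitope_segments(summary, gap_tolerance: int = 2) -> EpitopeSegmentation:
    """Split the epitope residue list into discontinuous peptide segments.

    Residues are sorted by (chain, number); a new segment starts when the
    chain changes or the residue-number gap to the previous epitope residue
    exceeds ``gap_tolerance``.  An epitope of two or more segments is
    conformational.
    """
    residues = sorted(getattr(summary, "epitope", summary))
    segments = []
    for key in residues:
        if segments:
            prev = segments[-1][-1]
            if key[0] == prev[0] and key[1] - prev[1] <= gap_tolerance:
                segments[-1].append(key)
                continue
        segments.append([key])
    return EpitopeSegmentation(residues, segments, gap_tolerance)


# ---------------------------------------------------------------------------
# Identity clustering (CD-Hit stand-in)


def sequence_identity(a: str, b: str) -> float:
    """Global ungapped identity: best sliding-offset matches over the
    longer length."""
    if not a or not b:
        return 0.0
    best = 0
    for offset in range(-(len(b) - 1), len(a)):
        matches = sum(
            1
            for i in range(max(0, offset), min(len(a), offset + len(b)))
            if a[i] == b[i - offset]
        )
        best = max(best, matches)
    return best / max(len(a), len(b))


def _heavy_chain_sequence(model: StructureModel) -> str:
    for chain, role in model.chain_roles.items():
        if role == "antibody-heavy":
            return model.chain_sequence(chain)
    return ""


def _antigen_length(model: StructureModel) -> int:
    return sum(
        1 for key, _, _ in model.residues()
        if model.side_of(key[0]) == "antigen"
    )


# ---------------------------------------------------------------------------
# Filtering


def filter_complexes(records, criteria: ComplexCriteria = ComplexCriteria()):
    """Apply the sequential selection filters to (model, cdrs) records.

    Order per record: antigen length; CDR completeness; CDR lengths;
    conformational epitope (contact-derived segments); then greedy
    heavy-chain identity clustering over the survivors in input order,
    keeping one representative per cluster.  Returns (accepted records,
    per-record verdicts) where each verdict is ``None`` for accepted or a
    short rejection reason.
    """
    reasons = [None] * len(records)
    survivors = []
    required = dict(criteria.cdr_lengths)
    for idx, (model, cdrs) in enumerate(records):
        if _antigen_length(model) < criteria.min_antigen_length:
            reasons[idx] = "antigen-length"
            continue
        missing = [
            lab for lab in cdrs.cdr_labels
            if not model.has_residue(*cdrs.positions[lab])
        ]
        if missing:
            reasons[idx] = "cdr-incomplete"
            continue
        lengths = cdrs.lengths
        if any(lengths.get(name, 0) != want for name, want in required.items()):
            reasons[idx] = "cdr-length"
            continue
        if criteria.require_conformational:
            if not model.annotated:
                annotate_atoms(model)
            acps = find_acps(model)
            epitope = sorted({p.ag_atom.residue_key for p in acps})
            seg = epitope_segments(epitope, criteria.gap_tolerance)
            if not seg.conformational:
                reasons[idx] = "epitope-not-conformational"
                continue
        survivors.append(idx)

    representatives = []  # (idx, heavy sequence)
    for idx in survivors:
        seq = _heavy_chain_sequence(records[idx][0])
        if any(sequence_identity(seq, rep_seq) >= criteria.identity_cutoff
               for _, rep_seq in representatives):
            reasons[idx] = "redundant"
            continue
        representatives.append((idx, seq))
    accepted = [records[idx] for idx, _ in representatives]
    return accepted, reasons


# ---------------------------------------------------------------------------
# Decoy generation


def _rotation_between(a: np.ndarray, b: np.ndarray) -> Rotation:
    """Minimal rotation taking unit vector a onto unit vector b."""
    axis = np.cross(a, b)
    norm = np.linalg.norm(axis)
    angle = np.arctan2(norm, np.dot(a, b))
    if norm < 1e-9:
        if np.dot(a, b) > 0:
            return Rotation.identity()
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        norm = np.linalg.norm(axis)
        angle = np.pi
    return Rotation.from_rotvec(axis / norm * angle)


def _transform_antibody(model: StructureModel, rotation, translation):
    out = model.copy()
    for a in out.atoms:
        if out.side_of(a.chain_id) == "antibody":
            a.pos = rotation @ a.pos + translation
            a.hydrogens = [(n, rotation @ p + translation) for n, p in a.hydrogens]
    return out


def generate_decoys(model: StructureModel, summary, n: int = 10, seed: int = 0,
                    max_attempts: int | None = None, hard_clash: float = 0.7,
                    max_centering: float = 8.0, tilt_max: float = 25.0):
    """Sample clash-free rigid antibody placements on non-native epitope.

    The antibody is rotated so the native paratope faces a randomly chosen
    non-epitope patch of the antigen surface (with a random spin about the
    approach axis and a tilt up to ``tilt_max``°), slid into contact, and
    accepted when (i) no heavy-atom pair is closer than ``hard_clash`` x
    the vdW sum, (ii) the decoy epitope shares no residue with the native
    epitope, and (iii) the transformed native-paratope centroid lies within
    ``max_centering`` Å of the decoy contact centroid.  Survivors are
    scored by cross-partition contact-pair count; the top ``n`` are
    returned as (decoy model, DecoyPose) pairs, deterministically for a
    fixed seed.
    """
    if not model.annotated:
        annotate_atoms(model)
    model.require_partition()
    rng = np.random.default_rng(seed)
    native_acps = find_acps(model)
    native_epitope = {p.ag_atom.residue_key for p in native_acps}
    paratope_res = {p.ab_atom.residue_key for p in native_acps}
    if not paratope_res:
        raise ValueError("native complex has no contacts; paratope undefined")

    ab_atoms = [a for a in model.side_atoms("antibody") if a.element != "H"]
    ag_atoms = [a for a in model.side_atoms("antigen") if a.element != "H"]
    ab_pos = np.array([a.pos for a in ab_atoms])
    ag_pos = np.array([a.pos for a in ag_atoms])
    ab_r = np.array([a.vdw_radius for a in ab_atoms])
    ag_r = np.array([a.vdw_radius for a in ag_atoms])
    ag_tree = cKDTree(ag_pos)
    para_mask = np.array([a.residue_key in paratope_res for a in ab_atoms])
    para_centroid = ab_pos[para_mask].mean(axis=0)
    ab_centroid = ab_pos.mean(axis=0)
    ag_centroid = ag_pos.mean(axis=0)
    contact_cut = ab_r.max() + ag_r.max() + 0.5
    clash_cut = hard_clash * (ab_r.max() + ag_r.max())

    anchors = [i for i, a in enumerate(ag_atoms)
               if a.residue_key not in native_epitope]
    if not anchors:
        raise ValueError("antigen has no non-epitope surface to dock against")

    out_dir = para_centroid - ab_centroid
    if np.linalg.norm(out_dir) < 1e-6:
        out_dir = np.array([0.0, 0.0, 1.0])
    out_dir = out_dir / np.linalg.norm(out_dir)

    if max_attempts is None:
        max_attempts = 60 * n
    candidates = []
    for _ in range(max_attempts):
        anchor = ag_pos[anchors[rng.integers(len(anchors))]]
        v = anchor - ag_centroid
        if np.linalg.norm(v) < 1e-6:
            continue
        v = v / np.linalg.norm(v)
        # align the paratope outward normal onto -v, then spin and tilt
        align = _rotation_between(out_dir, -v)
        spin = Rotation.from_rotvec(v * rng.uniform(0.0, 2.0 * np.pi))
        tilt_axis = np.cross(v, rng.normal(size=3))
        if np.linalg.norm(tilt_axis) < 1e-6:
            continue
        tilt_axis /= np.linalg.norm(tilt_axis)
        tilt = Rotation.from_rotvec(
            tilt_axis * np.radians(rng.uniform(0.0, tilt_max))
        )
        rot = (tilt * spin * align).as_matrix()

        # slide the rotated antibody inward along -v until first hard clash
        rotated = (ab_pos - para_centroid) @ rot.T
        rotated_para = rotated[para_mask].mean(axis=0)
        accepted_t = None
        for gap in np.arange(8.0, -4.0, -0.4):
            t = anchor + v * gap - rotated_para
            pts = rotated + t
            clash = False
            for ai, js in enumerate(ag_tree.query_ball_point(pts, clash_cut)):
                for j in js:
                    d = np.linalg.norm(pts[ai] - ag_pos[j])
                    if d < hard_clash * (ab_r[ai] + ag_r[j]):
                        clash = True
                        break
                if clash:
                    break
            if clash:
                break
            accepted_t = t
        if accepted_t is None:
            continue
        pts = rotated + accepted_t
        # contacts of this pose
        contact_pairs = []
        for ai, js in enumerate(ag_tree.query_ball_point(pts, contact_cut)):
            for j in js:
                d = np.linalg.norm(pts[ai] - ag_pos[j])
                if d < ab_r[ai] + ag_r[j] + 0.5:
                    contact_pairs.append((ai, j))
        if not contact_pairs:
            continue
        decoy_epitope = sorted({ag_atoms[j].residue_key for _, j in contact_pairs})
        if native_epitope.intersection(decoy_epitope):
            continue
        contact_centroid = pts[[ai for ai, _ in contact_pairs]].mean(axis=0)
        new_para = pts[para_mask].mean(axis=0)
        centering = float(np.linalg.norm(new_para - contact_centroid))
        if centering > max_centering:
            continue
        # the pose maps x -> rot @ (x - para_centroid) + t, stored affinely
        candidates.append(DecoyPose(
            rotation=rot,
            translation=accepted_t - rot @ para_centroid,
            clash_count=0,
            paratope_centering=centering,
            native_overlap=0,
            score=len(contact_pairs),
            epitope=decoy_epitope,
        ))
        if len(candidates) >= 4 * n:
            break

    candidates.sort(key=lambda d: -d.score)
    chosen = candidates[:n]
    if len(chosen) < n:
        warnings.warn(
            f"decoy sampler found only {len(chosen)} of {n} requested poses"
        )
    results = []
    for pose in chosen:
        decoy = _transform_antibody(model, pose.rotation, pose.translation)
        results.append((decoy, pose))
    return results
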