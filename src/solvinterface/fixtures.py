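"""Synthetic structures with planted, exactly-known interface features.

The generators build chemically simplified two-chain complexes (glycine /
alanine / phenylalanine fragments on an antibody chain H and an antigen
chain G) decorated so that each requested feature satisfies its detector's
criteria exactly at zero noise:

* direct hydrogen bond: backbone N-H donor aimed at a carbonyl O acceptor,
  D-A 2.9 Å, D-H-A 180°;
* water bridge: a water oxygen with an antibody-side carbonyl O placed
  2.85 Å along the identity-orientation water hydrogen, and an
  antigen-side amide N-H aimed at the oxygen at 2.90 Å — so orientation
  index 0 of the rigid-water grid satisfies both sides;
* aromatic contact: a phenylalanine ring carbon 0.2 Å inside the contact
  threshold of an antigen carbon;
* non-aromatic carbon-carbon contact: two alanine CB atoms likewise.

Features are laid out 10 Å apart so detectors cannot cross-talk, and
residue numbering jumps between features so each feature's antigen
residues fall in separate epitope segments.  Gaussian
coordinate noise of width sigma destroys features progressively; at
sigma = 0 the ground truth is recovered exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from solvinterface.structio import (
    AtomRecord,
    StructureModel,
    annotate_atoms,
    place_polar_hydrogens,
)

__all__ = [
    "ToyComplexSpec",
    "make_toy_complex",
    "make_hydrated_interface",
    "make_benchmark_fixture",
    "sample_nnk_sequences",
]

FEATURE_SPACING = 10.0

#: template water geometry (must match the orientation grid's template)
_WATER_OH = 0.9572
_WATER_HOH = 104.52


@dataclass(frozen=True)
class ToyComplexSpec:
    """Counts of planted features plus geometric noise and seed."""

    n_dhb: int = 0
    n_bridge: int = 0
    n_aromatic: int = 0
    n_nacc: int = 0
    sigma: float = 0.0
    seed: int = 0
    chain_size: int = 60  # residues available per chain

    def __post_init__(self):
        if min(self.n_dhb, self.n_bridge, self.n_aromatic, self.n_nacc) < 0:
            raise ValueError("feature counts must be non-negative")
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")


class _Builder:
    def __init__(self):
        self.atoms = []
        self.res_counters = {"H": 0, "G": 0}
        self.waters = []

    def new_residue(self, chain, res_name):
        self.res_counters[chain] += 1
        return self.res_counters[chain], res_name

    def skip_residues(self, n):
        """Advance numbering on both chains (separates feature epitopes)."""
        for chain in self.res_counters:
            self.res_counters[chain] += n

    def add(self, chain, res_seq, res_name, atom_name, pos, element=None):
        element = element or atom_name.strip("0123456789")[0]
        self.atoms.append(
            AtomRecord(chain, res_seq, "", res_name, atom_name, element,
                       np.asarray(pos, dtype=float))
        )


def _amide_support(builder, chain, n_pos, h_dir):
    """Place CA and a preceding-residue C so the amide H lands on h_dir.

    The hydrogen placement rule puts H on the bisector pointing away from
    CA and the previous C; two supports at ±60° off -h_dir in a plane give
    exactly H = N + h_dir.
    """
    h = np.asarray(h_dir, dtype=float)
    h = h / np.linalg.norm(h)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(h, helper)) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    u = np.cross(h, helper)
    u /= np.linalg.norm(u)
    s, c = math.sin(math.radians(60.0)), math.cos(math.radians(60.0))
    a1 = s * u - c * h
    a2 = -s * u - c * h
    prev_seq, prev_name = builder.new_residue(chain, "GLY")
    builder.add(chain, prev_seq, prev_name, "C", n_pos + 1.33 * a2)
    seq, name = builder.new_residue(chain, "GLY")
    builder.add(chain, seq, name, "N", n_pos)
    builder.add(chain, seq, name, "CA", n_pos + 1.46 * a1)
    return seq, name


def make_toy_complex(spec: ToyComplexSpec):
    """Build a planted two-chain complex and its ground-truth feature list.

    Returns (model, truth).  The model is annotated, protonated and
    partitioned (chain H antibody-heavy, chain G antigen); planted waters
    are in ``model.waters``.  ``truth`` maps feature kind ("dhb", "wmhb",
    "aacp", "nacc") to lists of the participating atom keys, with "wmhb"
    entries as (water index, antibody atom key, antigen atom key).
    """
    n_features = spec.n_dhb + spec.n_bridge + spec.n_aromatic + spec.n_nacc
    residues_needed = 2 * n_features  # upper bound per chain
    if residues_needed > spec.chain_size:
        raise ValueError(
            f"spec plants {n_features} features but chain size "
            f"{spec.chain_size} accommodates at most {spec.chain_size // 2}"
        )
    b = _Builder()
    truth = {"dhb": [], "wmhb": [], "aacp": [], "nacc": []}
    x0 = 0.0

    for _ in range(spec.n_dhb):
        n_pos = np.array([x0, 0.0, 0.0])
        seq, name = _amide_support(b, "H", n_pos, [0.0, 1.0, 0.0])
        g_seq, g_name = b.new_residue("G", "GLY")
        o_pos = n_pos + np.array([0.0, 2.9, 0.0])
        b.add("G", g_seq, g_name, "O", o_pos)
        b.add("G", g_seq, g_name, "C", o_pos + np.array([1.0, 0.72, 0.0]))
        truth["dhb"].append((("H", seq, "", "N"), ("G", g_seq, "", "O")))
        b.skip_residues(8)
        x0 += FEATURE_SPACING

    half = math.radians(_WATER_HOH / 2.0)
    h1_dir = np.array([math.sin(half), 0.0, math.cos(half)])
    for _ in range(spec.n_bridge):
        w = np.array([x0, 1.5, 0.0])
        widx = len(b.waters)
        b.waters.append(w)
        # antibody-side acceptor along the identity-orientation hydrogen
        a_seq, a_name = b.new_residue("H", "GLY")
        o_pos = w + 2.85 * h1_dir
        b.add("H", a_seq, a_name, "O", o_pos)
        b.add("H", a_seq, a_name, "C", o_pos + 1.23 * h1_dir)
        # antigen-side amide donor aimed at the water oxygen
        n_pos = w + np.array([0.0, 0.0, -2.9])
        g_seq, g_name = _amide_support(b, "G", n_pos, [0.0, 0.0, 1.0])
        truth["wmhb"].append(
            (widx, ("H", a_seq, "", "O"), ("G", g_seq, "", "N"))
        )
        b.skip_residues(8)
        x0 += FEATURE_SPACING

    ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    ring_angles = [270.0, 330.0, 30.0, 90.0, 150.0, 210.0]
    for _ in range(spec.n_aromatic):
        center = np.array([x0, 0.0, 0.0])
        seq, name = b.new_residue("H", "PHE")
        for atom, ang in zip(ring_names, ring_angles):
            rad = math.radians(ang)
            b.add("H", seq, name, atom,
                  center + 1.39 * np.array([math.cos(rad), math.sin(rad), 0.0]))
        g_seq, g_name = b.new_residue("G", "ALA")
        cb = center + np.array([0.0, 1.39 + 3.2, 0.0])  # vdW sum − 0.2 off CZ
        b.add("G", g_seq, g_name, "CB", cb)
        b.add("G", g_seq, g_name, "CA", cb + np.array([0.0, 1.52, 0.0]))
        truth["aacp"].append((("H", seq, "", "CZ"), ("G", g_seq, "", "CB")))
        b.skip_residues(8)
        x0 += FEATURE_SPACING

    for _ in range(spec.n_nacc):
        seq, name = b.new_residue("H", "ALA")
        b.add("H", seq, name, "CB", [x0, 0.0, 0.0])
        b.add("H", seq, name, "CA", [x0, -1.52, 0.0])
        g_seq, g_name = b.new_residue("G", "ALA")
        b.add("G", g_seq, g_name, "CB", [x0, 3.2, 0.0])
        b.add("G", g_seq, g_name, "CA", [x0, 4.72, 0.0])
        truth["nacc"].append((("H", seq, "", "CB"), ("G", g_seq, "", "CB")))
        b.skip_residues(8)
        x0 += FEATURE_SPACING

    if spec.sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for a in b.atoms:
            a.pos = a.pos + rng.normal(0.0, spec.sigma, 3)
        b.waters = [w + rng.normal(0.0, spec.sigma, 3) for w in b.waters]

    model = StructureModel(
        b.atoms,
        chain_roles={"H": "antibody-heavy", "G": "antigen"},
        waters=np.array(b.waters).reshape(-1, 3),
    )
    annotate_atoms(model)
    place_polar_hydrogens(model)
    return model, truth


def make_hydrated_interface(nx: int = 5, ny: int = 5, separation: float = 5.8,
                            jitter: float = 0.15, seed: int = 0,
                            spacing: float = 6.0):
    """Two facing walls of carbonyl oxygens with known hydration sites.

    Chain H (antibody) carries an ``nx`` x ``ny`` wall of backbone-like
    oxygen atoms at z = 0 on a ``spacing`` Å lattice; chain G (antigen)
    mirrors it at z = ``separation``.  Reference hydration sites sit 2.8 Å
    (the polar kernel peak distance) above the interior antibody-side
    oxygens, inside the interfacial space of the two walls.  ``jitter``
    adds seeded lateral disorder so different seeds give distinct
    complexes while keeping the site geometry exact.

    Returns (model, reference site array).
    """
    rng = np.random.default_rng(seed)
    b = _Builder()
    sites = []
    for chain, z in (("H", 0.0), ("G", separation)):
        for i in range(nx):
            for j in range(ny):
                seq, name = b.new_residue(chain, "GLY")
                dx, dy = rng.normal(0.0, jitter, 2) if jitter > 0 else (0.0, 0.0)
                pos = np.array([i * spacing + dx, j * spacing + dy, z])
                b.add(chain, seq, name, "O", pos)
                interior = 0 < i < nx - 1 and 0 < j < ny - 1
                if chain == "H" and interior:
                    sites.append(pos + np.array([0.0, 0.0, 2.8]))
    model = StructureModel(
        b.atoms, chain_roles={"H": "antibody-heavy", "G": "antigen"})
    annotate_atoms(model)
    return model, np.array(sites).reshape(-1, 3)


def make_benchmark_fixture(n_matched: int, n_ref_only: int, n_pred_only: int,
                           seed: int = 0):
    """Predicted/reference water sets with exact planted match counts.

    Matched pairs are separated by < 1.4 Å; every other cross-set distance
    exceeds 2.8 Å (sites on a 6 Å lattice), so matching recovers exactly
    (TP, FN, FP) = (n_matched, n_ref_only, n_pred_only).
    """
    from solvinterface.hydration import WaterSet

    if min(n_matched, n_ref_only, n_pred_only) < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    total = n_matched + n_ref_only + n_pred_only
    side = max(1, math.ceil(total ** (1.0 / 3.0)))
    sites = np.array([
        [i, j, k] for i in range(side + 1) for j in range(side + 1)
        for k in range(side + 1)
    ], dtype=float)[:total] * 6.0
    rng.shuffle(sites)
    ref, pred = [], []
    for s in sites[:n_matched]:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        offset = rng.uniform(0.2, 0.5)
        ref.append(s)
        pred.append(s + offset * direction)
    for s in sites[n_matched:n_matched + n_ref_only]:
        ref.append(s)
    for s in sites[n_matched + n_ref_only:]:
        pred.append(s)
    return (
        WaterSet(np.array(pred).reshape(-1, 3), source="predicted", seed=seed),
        WaterSet(np.array(ref).reshape(-1, 3), source="reference", seed=seed),
    )


def sample_nnk_sequences(n: int, length: int, seed: int = 0) -> list:
    """Sequences drawn i.i.d. per position from the NNK background."""
    from solvinterface.profiles import nnk_background, sample_background

    if n <= 0 or length <= 0:
        raise ValueError("n and length must be positive")
    return sample_background(nnk_background(), n, length, seed=seed)
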