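import numpy as np
import pytest

from solvinterface.fixtures import ToyComplexSpec, make_toy_complex


@pytest.fixture
def toy_complex():
    """One of each planted feature at zero noise."""
    return make_toy_complex(
        ToyComplexSpec(n_dhb=2, n_bridge=1, n_aromatic=1, n_nacc=1)
    )


@pytest.fixture
def simple_pdb_text():
    """Two chains, ten residues, three waters; one altloc pair on A/3/CB."""
    lines = []
    serial = 0

    def atom(name, res, chain, seq, x, y, z, altloc=" ", occ=1.0, elem=None):
        nonlocal serial
        serial += 1
        elem = elem or name[0]
        return (
            f"ATOM  {serial:>5d}  {name:<3s}{altloc}{res:<3s} {chain}"
            f"{seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {elem:>2s}"
        )

    for chain, offset in (("A", 0.0), ("B", 20.0)):
        for i in range(1, 6):
            x = offset + 4.0 * i
            lines.append(atom("N", "ALA", chain, i, x, 0.0, 0.0))
            lines.append(atom("CA", "ALA", chain, i, x + 1.2, 1.0, 0.0))
            if chain == "A" and i == 3:
                lines.append(atom("CB", "ALA", chain, i, x + 1.0, 2.4, 0.0,
                                  altloc="A", occ=0.6))
                lines.append(atom("CB", "ALA", chain, i, x + 2.0, 2.4, 0.0,
                                  altloc="B", occ=0.4))
            else:
                lines.append(atom("CB", "ALA", chain, i, x + 1.5, 2.4, 0.0))
    for j, wx in enumerate((50.0, 55.0, 60.0), start=1):
        serial += 1
        lines.append(
            f"HETATM{serial:>5d}  O   HOH W{j:>4d}    "
            f"{wx:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}  0.00           O"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the package's neighbor searches)


def acp_oracle(model, buffer=0.5):
    """O(n^2) cross-partition contact enumeration."""
    ab = [a for a in model.atoms
          if model.side_of(a.chain_id) == "antibody" and a.element != "H"]
    ag = [a for a in model.atoms
          if model.side_of(a.chain_id) == "antigen" and a.element != "H"]
    pairs = set()
    for x in ab:
        for y in ag:
            if np.linalg.norm(x.pos - y.pos) < x.vdw_radius + y.vdw_radius + buffer:
                pairs.add((x.key, y.key))
    return pairs


def _angle(p_left, apex, p_right):
    u, v = p_left - apex, p_right - apex
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(c, -1, 1)))


def dhb_oracle(model, d_max=3.5, angle_min=150.0,
               flex_angle=120.0, flex_ha=2.8, step=36.0):
    """O(n^2) direct hydrogen-bond enumeration with its own torsion scan."""
    from solvinterface.structio import DONOR_GEOMETRY, N_H_LENGTH, O_H_LENGTH

    res_atoms = {}
    for a in model.atoms:
        res_atoms.setdefault(a.residue_key, {})[a.name] = a
    sides = {"antibody": [], "antigen": []}
    for a in model.atoms:
        side = model.side_of(a.chain_id)
        if side and a.element != "H":
            sides[side].append(a)

    def scan_positions(donor):
        geom = DONOR_GEOMETRY.get((donor.res_name, donor.name))
        if geom is None:
            return None
        parent = res_atoms[donor.residue_key].get(geom[0])
        if parent is None:
            return None
        bond_angle = 109.5 if geom[2] == "sp3" else 120.0
        length = O_H_LENGTH if donor.element == "O" else N_H_LENGTH
        axis = donor.pos - parent.pos
        axis = axis / np.linalg.norm(axis)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(axis, helper)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(axis, helper)
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        theta = np.radians(180.0 - bond_angle)
        out = []
        for phi in np.radians(np.arange(0.0, 360.0, step)):
            d = (np.cos(theta) * axis
                 + np.sin(theta) * (np.cos(phi) * u + np.sin(phi) * v))
            out.append(donor.pos + length * d)
        return out

    bonds = set()
    for dside, aside in (("antibody", "antigen"), ("antigen", "antibody")):
        for donor in sides[dside]:
            if not donor.is_hb_donor_heavy:
                continue
            for acc in sides[aside]:
                if not acc.is_hb_acceptor:
                    continue
                if np.linalg.norm(donor.pos - acc.pos) > d_max:
                    continue
                if donor.is_rotatable_donor:
                    hs = scan_positions(donor)
                    if hs and any(
                        np.linalg.norm(h - acc.pos) <= flex_ha
                        and _angle(donor.pos, h, acc.pos) >= flex_angle
                        for h in hs
                    ):
                        bonds.add((donor.key, acc.key))
                else:
                    if any(_angle(donor.pos, h, acc.pos) >= angle_min
                           for _, h in donor.hydrogens):
                        bonds.add((donor.key, acc.key))
    return bonds


def benchmark_oracle(pred, ref, threshold=1.4):
    """All-pairs TP/FN/FP matching."""
    tp = fn = 0
    for r in ref:
        if any(np.linalg.norm(r - p) <= threshold for p in pred):
            tp += 1
        else:
            fn += 1
    fp = sum(
        1 for p in pred
        if not any(np.linalg.norm(r - p) <= threshold for r in ref)
    )
    return tp, fn, fp


def interface_space_oracle(model, origin, spacing, shape, probe=1.9):
    """O(voxels x atoms) double-loop scan of the two-sided layer test."""
    flagged = []
    sides = {
        s: [(a.pos, a.vdw_radius) for a in model.atoms
            if model.side_of(a.chain_id) == s and a.element != "H"]
        for s in ("antibody", "antigen")
    }
    flat = 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                x = origin + np.array([i, j, k]) * spacing
                ok = True
                for atoms in sides.values():
                    gap = min(np.linalg.norm(x - p) - r for p, r in atoms)
                    if not (0.0 < gap <= probe):
                        ok = False
                        break
                if ok:
                    flagged.append(flat)
                flat += 1
    return np.array(flagged, dtype=int)
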