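"""CDR-position statistics over interface summaries.

Aggregates per-complex interaction records into position profiles (what
fraction of complexes shows a given interaction class with a given residue
type at each IMGT position), per-complex class percentages, pairwise
amino-acid contact-preference log-odds, sequence LOGOs against the NNK
degenerate-codon background, and Pearson/Student profile comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "AA_ALPHABET",
    "NnkBackground",
    "LogoMatrix",
    "PreferenceMatrix",
    "CorrelationResult",
    "position_profiles",
    "complex_profiles",
    "nnk_background",
    "sample_background",
    "sequence_logo",
    "contact_preferences",
    "profile_correlation",
    "interaction_pair_types",
    "residue_pair_counts",
    "flatten_profiles",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Profiles


def _position_frame(summaries):
    labels = []
    for s in summaries:
        for lab in s.positions:
            if lab not in labels:
                labels.append(lab)
    return labels


def position_profiles(summaries, interaction_class: str,
                      aa_filter: str | None = None) -> pd.DataFrame:
    """Percentage of complexes showing a class with each residue type.

    Entry (position j, type i) = 100 x (#complexes whose residue at j is
    type i AND shows ``interaction_class`` there) / (#complexes).
    ``aa_filter`` restricts the counted types (e.g. "FWY" for aromatic
    panels).  Rows are IMGT positions, columns the 20 amino-acid types.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("refusing to build profiles from an empty summary list")
    labels = _position_frame(summaries)
    counted = set(aa_filter) if aa_filter else set(AA_ALPHABET)
    mat = pd.DataFrame(0.0, index=labels, columns=list(AA_ALPHABET))
    for s in summaries:
        for lab, rec in s.positions.items():
            aa = rec["aa"]
            if aa in counted and aa in mat.columns and \
                    interaction_class in rec["classes"]:
                mat.at[lab, aa] += 1
    return 100.0 * mat / len(summaries)


def complex_profiles(summaries, interaction_class: str) -> pd.Series:
    """Per complex: percentage of its CDR positions showing the class."""
    out = {}
    for i, s in enumerate(summaries):
        if s.n_cdr_positions == 0:
            raise ValueError("summary with zero CDR positions")
        n = sum(1 for rec in s.positions.values()
                if interaction_class in rec["classes"])
        out[s.complex_id or i] = 100.0 * n / s.n_cdr_positions
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# NNK background and LOGOs


@dataclass(frozen=True)
class NnkBackground:
    """Amino-acid distribution of the 31 sense codons of NNK."""

    probs: pd.Series  # indexed by the 20 one-letter types

    def __getitem__(self, aa):
        return float(self.probs[aa])


def nnk_background() -> NnkBackground:
    """Enumerate NNK (N = A/C/G/T, K = G/T), drop the single stop codon,
    and normalize amino-acid counts over the 31 sense codons."""
    counts = {aa: 0 for aa in AA_ALPHABET}
    n_sense = 0
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "GT":
                aa = str(Seq(b1 + b2 + b3).translate())
                if aa == "*":
                    continue
                counts[aa] += 1
                n_sense += 1
    probs = pd.Series(counts, dtype=float) / n_sense
    return NnkBackground(probs=probs.reindex(list(AA_ALPHABET)))


def sample_background(background: NnkBackground, n: int, length: int,
                      seed: int = 0) -> list:
    """Sequences drawn i.i.d. per position from a background distribution."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(background.probs.index))
    p = background.probs.to_numpy()
    draws = rng.choice(letters, size=(n, length), p=p)
    return ["".join(row) for row in draws]


@dataclass
class LogoMatrix:
    """Observed frequencies and signed LOGO heights per position.

    Heights are per-letter relative-entropy contributions against the
    background: d_ji = q_ji * log2(q_ji / p_i) for q_ji > 0, else 0.
    Negative heights mark letters depleted relative to the background.
    """

    q: pd.DataFrame
    d: pd.DataFrame
    background: pd.Series
    n_sequences: int


def sequence_logo(sequences, background: NnkBackground | None = None) -> LogoMatrix:
    """Column frequencies and LOGO heights for an aligned sequence set."""
    sequences = list(sequences)
    if not sequences:
        raise ValueError("need at least one sequence")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences must have uniform length")
    background = background or nnk_background()
    p = background.probs
    q = pd.DataFrame(0.0, index=range(1, length + 1), columns=list(AA_ALPHABET))
    skipped = 0
    for s in sequences:
        for j, aa in enumerate(s.upper(), start=1):
            if aa in q.columns:
                q.at[j, aa] += 1
            else:
                skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} non-standard letters (X/gap)")
    totals = q.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("a position has no countable letters")
    q = q.div(totals, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = q * np.log2(q.div(p, axis=1))
    d = d.where(q > 0, 0.0)
    return LogoMatrix(q=q, d=d, background=p, n_sequences=len(sequences))


# ---------------------------------------------------------------------------
# Contact preferences


@dataclass
class PreferenceMatrix:
    """Pairwise amino-acid contact-preference log-odds P_n(x, y)."""

    values: pd.DataFrame  # antibody type x (rows) vs antigen type y (cols)
    group: int
    alpha: float


def _as_table(counts) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        return counts.reindex(index=list(AA_ALPHABET),
                              columns=list(AA_ALPHABET), fill_value=0.0)
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (20, 20):
        raise ValueError("count tables must be 20 x 20")
    return pd.DataFrame(arr, index=list(AA_ALPHABET), columns=list(AA_ALPHABET))


def contact_preferences(observed, null, group: int = 1,
                        alpha: float = 1.0) -> PreferenceMatrix:
    """Log-odds of observed vs null contact-pair distributions.

    P_n(x,y) = log2[ ((c_obs+α)/Σ(c_obs+α)) / ((c_null+α)/Σ(c_null+α)) ]
    with a symmetric pseudocount α (default 1) keeping every cell finite.
    Contact group n: 1 carbon-carbon contacts, 2 direct hydrogen bonds,
    3 water-mediated hydrogen bonds.
    """
    if alpha <= 0:
        raise ValueError("pseudocount alpha must be positive")
    obs = _as_table(observed)
    nul = _as_table(null)
    if (obs.to_numpy() < 0).any() or (nul.to_numpy() < 0).any():
        raise ValueError("count tables must be non-negative")
    if obs.to_numpy().sum() == 0:
        raise ValueError("refusing an all-zero observed table")
    po = (obs + alpha) / (obs + alpha).to_numpy().sum()
    pn = (nul + alpha) / (nul + alpha).to_numpy().sum()
    return PreferenceMatrix(values=np.log2(po / pn), group=group, alpha=alpha)


def interaction_pair_types(model, acps=None, dhbs=None, wmhbs=None,
                           group: int = 1) -> list:
    """(antibody type, antigen type) letter pairs feeding a contact group.

    Group 1 uses contact pairs where both atoms are carbons; group 2 the
    residues flanking each direct hydrogen bond; group 3 the residues
    flanking each water bridge.
    """
    from solvinterface.structio import THREE_TO_ONE

    def letter(atom):
        return THREE_TO_ONE.get(atom.res_name, "X")

    pairs = []
    if group == 1:
        for p in acps or []:
            if p.ab_atom.is_carbon and p.ag_atom.is_carbon:
                pairs.append((letter(p.ab_atom), letter(p.ag_atom)))
    elif group == 2:
        for b in dhbs or []:
            ab = b.donor if model.side_of(b.donor.chain_id) == "antibody" else b.acceptor
            ag = b.acceptor if ab is b.donor else b.donor
            pairs.append((letter(ab), letter(ag)))
    elif group == 3:
        for b in wmhbs or []:
            pairs.append((letter(b.ab_atom), letter(b.ag_atom)))
    else:
        raise ValueError("contact group must be 1, 2 or 3")
    return [(x, y) for x, y in pairs if x in AA_ALPHABET and y in AA_ALPHABET]


def residue_pair_counts(letter_pairs) -> pd.DataFrame:
    """20 x 20 count table from (antibody, antigen) letter pairs."""
    table = pd.DataFrame(0.0, index=list(AA_ALPHABET), columns=list(AA_ALPHABET))
    for x, y in letter_pairs:
        table.at[x, y] += 1
    return table


# ---------------------------------------------------------------------------
# Correlation


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    t: float
    df: int
    p_value: float


def flatten_profiles(u: pd.DataFrame, v: pd.DataFrame):
    """Row-major flattening of two aligned profile matrices, dropping
    entries that are zero in both."""
    v = v.reindex(index=u.index, columns=u.columns, fill_value=0.0)
    a = u.to_numpy().ravel()
    b = v.to_numpy().ravel()
    keep = ~((a == 0) & (b == 0))
    return a[keep], b[keep]


def profile_correlation(u, v) -> CorrelationResult:
    """Pearson correlation with the Student's-t two-sided P for r = 0.

    t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.  Degenerate
    (zero-variance) inputs are rejected.
    """
    a = np.asarray(u, dtype=float).ravel()
    b = np.asarray(v, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("arrays must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 paired values")
    da, db = a - a.mean(), b - b.mean()
    va, vb = (da ** 2).sum(), (db ** 2).sum()
    if va == 0 or vb == 0:
        raise ValueError("zero variance in input array")
    r = float((da * db).sum() / math.sqrt(va * vb))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t = math.inf
        p = np.finfo(float).tiny
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(r=r, r_squared=r * r, t=t, df=df,
                             p_value=float(min(1.0, max(p, np.finfo(float).tiny))))
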