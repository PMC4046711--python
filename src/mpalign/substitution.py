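"""Joint symbol-pair occurrence probabilities P(a, b).

The joint table plays two roles: it is the match-state emission distribution
of the pair-HMM and the data term of the message-passing update.  It is
position-independent — P(x_i, y_j) depends only on the symbols, never on i, j.

The default protein table is the published BLOSUM62 target (qij) frequency
table, symmetrized and renormalized to sum to exactly 1.  The default
nucleotide table is a one-parameter match/mismatch scheme with uniform
marginals.  Users may override either with a plain-text table file (see
:func:`read_joint_table` / :func:`write_joint_table`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqtypes import alphabet_for, ambiguity_for

# Published BLOSUM62 target (pair) frequencies, lower triangular, 4 decimal
# places, residue order A R N D C Q E G H I L K M F P S T W Y V.  Entries are
# ordered-pair probabilities P(a,b); each off-diagonal is counted twice in the
# full symmetric table (row sums then equal the standard BLOSUM62 background
# frequencies, e.g. p(A) = 0.074).
_BLOSUM62_QIJ = """\
A 0.0215
R 0.0023 0.0178
N 0.0019 0.0020 0.0141
D 0.0022 0.0016 0.0037 0.0213
C 0.0016 0.0004 0.0004 0.0004 0.0119
Q 0.0019 0.0025 0.0015 0.0016 0.0003 0.0073
E 0.0030 0.0027 0.0022 0.0049 0.0004 0.0035 0.0161
G 0.0058 0.0017 0.0029 0.0025 0.0008 0.0014 0.0019 0.0378
H 0.0011 0.0012 0.0014 0.0010 0.0002 0.0010 0.0014 0.0010 0.0093
I 0.0032 0.0012 0.0010 0.0012 0.0011 0.0009 0.0012 0.0014 0.0006 0.0184
L 0.0044 0.0024 0.0014 0.0015 0.0016 0.0016 0.0020 0.0021 0.0010 0.0114 0.0371
K 0.0033 0.0062 0.0024 0.0024 0.0005 0.0031 0.0041 0.0025 0.0012 0.0016 0.0025 0.0161
M 0.0013 0.0008 0.0005 0.0005 0.0004 0.0007 0.0007 0.0007 0.0004 0.0025 0.0049 0.0009 0.0040
F 0.0016 0.0009 0.0008 0.0008 0.0005 0.0005 0.0009 0.0012 0.0008 0.0030 0.0054 0.0009 0.0012 0.0183
P 0.0022 0.0010 0.0009 0.0012 0.0004 0.0008 0.0014 0.0014 0.0005 0.0010 0.0014 0.0016 0.0004 0.0005 0.0191
S 0.0063 0.0023 0.0031 0.0028 0.0010 0.0019 0.0030 0.0038 0.0011 0.0017 0.0024 0.0031 0.0009 0.0012 0.0017 0.0126
T 0.0037 0.0018 0.0022 0.0019 0.0009 0.0014 0.0020 0.0022 0.0007 0.0027 0.0033 0.0023 0.0010 0.0012 0.0014 0.0047 0.0125
W 0.0004 0.0003 0.0002 0.0002 0.0001 0.0002 0.0003 0.0004 0.0002 0.0004 0.0007 0.0003 0.0002 0.0008 0.0001 0.0003 0.0003 0.0065
Y 0.0013 0.0009 0.0007 0.0006 0.0003 0.0007 0.0009 0.0008 0.0015 0.0014 0.0022 0.0010 0.0006 0.0042 0.0005 0.0010 0.0009 0.0009 0.0102
V 0.0051 0.0016 0.0012 0.0013 0.0014 0.0012 0.0017 0.0018 0.0006 0.0120 0.0095 0.0019 0.0023 0.0026 0.0012 0.0024 0.0036 0.0004 0.0015 0.0196
"""

DEFAULT_NUCLEOTIDE_MISMATCH = 0.2


@dataclass(frozen=True)
class JointSubstitutionModel:
    """Symmetric joint probability table over ordered symbol pairs.

    Attributes
    ----------
    alphabet : str
        Ordered residue symbols; row/column order of ``joint``.
    joint : numpy.ndarray
        ``(K, K)`` matrix with ``joint[a, b] = P(a, b)``; strictly positive,
        symmetric, sums to 1.
    marginal : numpy.ndarray
        ``p(a) = sum_b P(a, b)``.
    alphabet_kind : str
        ``"protein"`` or ``"nucleotide"``; selects the ambiguity-code table.
    """

    alphabet: str
    joint: np.ndarray
    marginal: np.ndarray
    alphabet_kind: str = "protein"

    def __post_init__(self) -> None:
        J = np.asarray(self.joint, dtype=float)
        if J.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("joint table shape does not match alphabet size")
        if not np.all(J > 0):
            raise ValueError("all joint probabilities must be strictly positive")
        if not np.allclose(J, J.T, atol=1e-12):
            raise ValueError("joint table must be symmetric")
        if abs(J.sum() - 1.0) > 1e-9:
            raise ValueError("joint table must sum to 1")
        object.__setattr__(self, "joint", J)
        object.__setattr__(self, "marginal", J.sum(axis=1))

    def index(self, symbol: str) -> int:
        idx = self.alphabet.find(symbol)
        if idx < 0:
            raise KeyError(symbol)
        return idx


def _expand(model: JointSubstitutionModel, symbol: str) -> np.ndarray:
    """Weight vector over the alphabet for a (possibly ambiguous) symbol."""
    sym = symbol.upper()
    try:
        vec = np.zeros(len(model.alphabet))
        vec[model.index(sym)] = 1.0
        return vec
    except KeyError:
        pass
    compat = ambiguity_for(model.alphabet_kind).get(sym)
    if compat is None:
        raise ValueError(
            f"symbol {sym!r} is not in the {model.alphabet_kind} alphabet "
            f"and is not a recognized ambiguity code"
        )
    idx = [model.index(c) for c in compat]
    w = model.marginal[idx]
    vec = np.zeros(len(model.alphabet))
    vec[idx] = w / w.sum()
    return vec


def joint_prob(model: JointSubstitutionModel, a: str, b: str) -> float:
    """P(a, b), case-insensitive and symmetric in its arguments.

    Ambiguity codes are marginalized over their compatible residues,
    weighted by the model marginals.
    """
    wa = _expand(model, a)
    wb = _expand(model, b)
    return float(wa @ model.joint @ wb)


def joint_prob_matrix(model: JointSubstitutionModel, x, y) -> np.ndarray:
    """L x M matrix of P(x_i, y_j) for two sequences (the data term)."""
    wx = np.stack([_expand(model, s) for s in x.residues])
    wy = np.stack([_expand(model, s) for s in y.residues])
    return wx @ model.joint @ wy.T


def build_default_joint_model(alphabet_kind: str) -> JointSubstitutionModel:
    """Default joint model for the given alphabet kind.

    ``protein``: BLOSUM62 target frequencies, symmetrized and renormalized.
    ``nucleotide``: uniform marginals with per-pair mismatch probability
    :data:`DEFAULT_NUCLEOTIDE_MISMATCH` spread over the three mismatches.
    """
    if alphabet_kind == "protein":
        alphabet = alphabet_for("protein")
        K = len(alphabet)
        J = np.zeros((K, K))
        for line in _BLOSUM62_QIJ.strip().splitlines():
            parts = line.split()
            r = alphabet.index(parts[0])
            for c, val in enumerate(parts[1:]):
                J[r, c] = J[c, r] = float(val)
        J /= J.sum()
        return JointSubstitutionModel(alphabet, J, J.sum(axis=1), "protein")
    if alphabet_kind == "nucleotide":
        return build_nucleotide_model(DEFAULT_NUCLEOTIDE_MISMATCH)
    raise ValueError(f"unknown alphabet kind: {alphabet_kind!r}")


def build_nucleotide_model(mismatch: float) -> JointSubstitutionModel:
    """One-parameter nucleotide joint model.

    ``mismatch`` is the total probability that an aligned pair differs;
    marginals are uniform (1/4 each).
    """
    if not 0.0 < mismatch < 1.0:
        raise ValueError("mismatch probability must be in (0, 1)")
    alphabet = alphabet_for("nucleotide")
    J = np.full((4, 4), mismatch / 12.0)
    np.fill_diagonal(J, (1.0 - mismatch) / 4.0)
    return JointSubstitutionModel(alphabet, J, J.sum(axis=1), "nucleotide")


def write_joint_table(model: JointSubstitutionModel, path) -> None:
    """Write a joint table file: alphabet header, then the full matrix with
    17 significant digits (round-trips float64 exactly)."""
    with open(path, "w") as fh:
        fh.write(" ".join(model.alphabet) + "\n")
        for row in model.joint:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_joint_table(path, alphabet_kind: str = "protein") -> JointSubstitutionModel:
    """Read a joint table file: header line of alphabet symbols, then a full
    or lower-triangular whitespace-separated probability matrix."""
    text = Path(path).read_text()
    lines = [ln for ln in io.StringIO(text) if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty joint table file: {path}")
    alphabet = "".join(lines[0].split())
    K = len(alphabet)
    rows = [list(map(float, ln.split())) for ln in lines[1:]]
    if len(rows) != K:
        raise ValueError(f"expected {K} matrix rows, found {len(rows)}")
    J = np.zeros((K, K))
    triangular = any(len(vals) != K for vals in rows) or K == 1
    for r, vals in enumerate(rows):
        expected = r + 1 if triangular else K
        if len(vals) != expected:
            raise ValueError(
                f"row {r + 1}: expected {expected} values "
                f"({'lower-triangular' if triangular else 'full'} matrix), "
                f"found {len(vals)}"
            )
        if triangular:
            J[r, : r + 1] = vals
            J[: r + 1, r] = vals
        else:
            J[r, :] = vals
    return JointSubstitutionModel(alphabet, J, J.sum(axis=1), alphabet_kind)
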