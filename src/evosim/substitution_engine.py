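"""Substitution simulation, independent of indels, and the final merge.

Substitutions are simulated with the probability-matrix approach: the
rate matrix ``Q`` is built from symmetric exchangeabilities ``s_ij`` and
stationary frequencies ``pi`` as ``Q_ij = s_ij * pi_j``, normalized so
the expected number of substitutions per site per unit branch length is
one.  Per-branch transition matrices ``P(t) = exp(Qt)`` are obtained by
spectral decomposition (the reversible symmetrization makes this an
``eigh``), and each site of a child sequence is drawn from the parent
residue's row of ``P``.

Residue content is simulated on the template alignment's columns: a root
sequence of the alignment length ``L`` is drawn from ``pi`` and evolved
down the tree without length changes; the final MSA superimposes these
residues onto the indel template, keeping its gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_assembly import GAP, Alignment

__all__ = [
    "AMINO_ACIDS",
    "NUCLEOTIDES",
    "SubstitutionModel",
    "normalize_rate_matrix",
    "transition_probabilities",
    "draw_root_sequence",
    "evolve_substitutions",
    "superimpose",
    "get_model",
    "jtt_model",
    "jc_model",
    "read_paml_rates",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
NUCLEOTIDES = "ACGT"

# JTT amino-acid replacement model (Jones, Taylor & Thornton 1992):
# symmetric exchangeability counts as the column-major lower triangle of a
# 20x20 matrix in the alphabet order above, plus stationary frequencies.
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101,
    64, 126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15,
    503, 232, 8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59,
    38, 4, 46, 31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209,
    62, 323, 26, 597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26,
    12, 9, 181, 18, 5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201,
    33, 55, 8, 47, 16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21,
    479, 89, 10, 40, 245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24,
    180, 65, 4, 21, 47, 103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17,
    92, 12, 53, 536, 62, 285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112,
    71, 25, 16,
]
_JTT_FREQS = [
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830,
    0.073152, 0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126,
    0.050901, 0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
]


@dataclass
class SubstitutionModel:
    """Normalized reversible substitution model.

    ``Q`` has nonnegative off-diagonals, zero row sums, unit expected
    rate under ``pi`` (``-sum(pi_i * Q_ii) = 1``).
    """

    alphabet: str
    Q: np.ndarray
    pi: np.ndarray
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def size(self) -> int:
        return len(self.alphabet)

    def _decomposition(self) -> tuple:
        if self._eig is None:
            sqrt_pi = np.sqrt(self.pi)
            B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
            w, V = np.linalg.eigh((B + B.T) / 2.0)
            left = V.T * sqrt_pi[None, :]
            right = V / sqrt_pi[:, None]
            self._eig = (w, right, left)
        return self._eig


def normalize_rate_matrix(exchangeabilities: np.ndarray, pi: np.ndarray, alphabet: str) -> SubstitutionModel:
    """Build a unit-rate reversible model from ``s_ij`` and ``pi``.

    ``exchangeabilities`` must be symmetric with nonnegative off-diagonal
    entries (the diagonal is ignored); ``pi`` positive, summing to one.
    """
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if s.shape != (len(alphabet), len(alphabet)):
        raise ValueError("exchangeability matrix does not match the alphabet")
    if not np.allclose(s, s.T):
        raise ValueError("exchangeabilities must be symmetric")
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError("pi must be positive and sum to 1")
    pi = pi / pi.sum()
    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float((pi * np.diag(Q)).sum())
    return SubstitutionModel(alphabet, Q / scale, pi)


def transition_probabilities(model: SubstitutionModel, t: float) -> np.ndarray:
    """``P(t) = exp(Qt)`` via the model's spectral decomposition."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    w, right, left = model._decomposition()
    P = (right * np.exp(w * t)[None, :]) @ left
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def draw_root_sequence(pi: np.ndarray, L: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. residue indices from the stationary distribution."""
    if L < 0:
        raise ValueError("length must be nonnegative")
    cdf = np.cumsum(np.asarray(pi, dtype=float))
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(L), side="right").astype(np.int64)


def evolve_substitutions(
    tree, L: int, model: SubstitutionModel, rng: np.random.Generator
) -> dict:
    """Fixed-length residue simulation down the tree.

    The root is drawn from ``pi``; along each branch every site is drawn
    from the parent residue's row of ``P(branch length)``.  Returns a
    dict mapping node id to an index array of length ``L``.
    """
    seqs = {tree.root.id: draw_root_sequence(model.pi, L, rng)}
    P_cache: dict[float, np.ndarray] = {}
    for parent, child, blen in tree.preorder_branches():
        P = P_cache.get(blen)
        if P is None:
            P = transition_probabilities(model, blen)
            P_cache[blen] = P
        cdf = np.cumsum(P, axis=1)
        cdf[:, -1] = 1.0
        parent_seq = seqs[parent.id]
        u = rng.random(L)
        rows = cdf[parent_seq]
        seqs[child.id] = (rows > u[:, None]).argmax(axis=1).astype(np.int64)
    return seqs


def indices_to_string(indices: np.ndarray, alphabet: str) -> str:
    return "".join(alphabet[i] for i in indices)


def superimpose(template: Alignment, residues: dict, alphabet: str) -> Alignment:
    """Replace template placeholders with simulated residues, keep gaps.

    ``residues`` maps row name to an index array whose length equals the
    template width.
    """
    L = template.width
    rows_out = []
    for name, row in template:
        res = residues[name]
        if len(res) != L:
            raise ValueError(
                f"residue sequence for {name!r} has length {len(res)}, template width is {L}"
            )
        rows_out.append(
            "".join(
                GAP if cell == GAP else alphabet[res[c]]
                for c, cell in enumerate(row)
            )
        )
    return Alignment(list(template.names), rows_out)


def jtt_model() -> SubstitutionModel:
    """The JTT amino-acid replacement model (shipped constants)."""
    s = np.zeros((20, 20))
    it = iter(_JTT_LOWER)
    for j in range(19):
        for i in range(j + 1, 20):
            s[i, j] = s[j, i] = next(it)
    return normalize_rate_matrix(s, np.array(_JTT_FREQS), AMINO_ACIDS)


def jc_model() -> SubstitutionModel:
    """One-parameter nucleotide model: equal rates, uniform frequencies."""
    s = np.ones((4, 4))
    return normalize_rate_matrix(s, np.full(4, 0.25), NUCLEOTIDES)


def read_paml_rates(path) -> SubstitutionModel:
    """Custom amino-acid model from a PAML rate file.

    Layout: 19 lines with the row-wise lower triangle of the symmetric
    exchangeability matrix (line ``i`` has ``i`` entries), followed by 20
    stationary frequencies; whitespace/newlines are free-form.
    """
    with open(path) as fh:
        values = [float(tok) for tok in fh.read().split()]
    if len(values) < 190 + 20:
        raise ValueError("PAML rate file needs 190 exchangeabilities + 20 frequencies")
    s = np.zeros((20, 20))
    it = iter(values[:190])
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = next(it)
    pi = np.array(values[190:210])
    return normalize_rate_matrix(s, pi, AMINO_ACIDS)


def get_model(name: str) -> SubstitutionModel:
    """Model registry: ``jtt``, ``jc`` or ``custom:<paml file>``."""
    if name == "jtt":
        return jtt_model()
    if name == "jc":
        return jc_model()
    if name.startswith("custom:"):
        return read_paml_rates(name.split(":", 1)[1])
    raise ValueError(f"unknown substitution model {name!r}")
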