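"""Codon substitution machinery (GY94-style) shared by the simulator and the
maximum-likelihood branch-model fitter.

The rate of change between sense codons i and j differing at exactly one
nucleotide position is

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

with q_ij = 0 for multi-nucleotide changes and for changes to or from stop
codons.  Q is scaled so that one unit of branch length equals one expected
substitution per codon.  Equilibrium codon frequencies follow the F3x4
convention (position-specific nucleotide frequencies).
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np

NUCS = "TCAG"
_NT_INDEX = {n: i for i, n in enumerate(NUCS)}

_CODON_TABLE = {}
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AMINO[16 * _i + 4 * _j + _k]

STOP_CODONS = tuple(c for c, a in _CODON_TABLE.items() if a == "*")
SENSE_CODONS = tuple(c for c, a in _CODON_TABLE.items() if a != "*")
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61
CODON_AA = np.array([_CODON_TABLE[c] for c in SENSE_CODONS])

GENETIC_CODE = dict(_CODON_TABLE)


def translate(cds: str) -> str:
    """Translate a CDS (standard code); stops emitted as '*'."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    cds = cds.upper().replace("U", "T")
    return "".join(_CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3))


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


@lru_cache(maxsize=1)
def _change_tables():
    """Precompute, for all sense-codon pairs differing at one position:
    (i, j, transition?, nonsynonymous?)."""
    ii, jj, ts, nonsyn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            ii.append(i)
            jj.append(j)
            ts.append(_is_transition(*diffs[0]))
            nonsyn.append(CODON_AA[i] != CODON_AA[j])
    return (
        np.array(ii),
        np.array(jj),
        np.array(ts, dtype=bool),
        np.array(nonsyn, dtype=bool),
    )


def codons_to_indices(cds: str) -> np.ndarray:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    idx = []
    for k in range(0, len(cds), 3):
        codon = cds[k : k + 3]
        if codon not in CODON_INDEX:
            raise ValueError(f"stop or ambiguous codon {codon!r} at nt {k}")
        idx.append(CODON_INDEX[codon])
    return np.array(idx, dtype=np.int64)


def indices_to_cds(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def f3x4(codon_rows: list[str], floor: float = 1e-4) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    A small floor keeps every sense codon reachable (zero frequencies break
    both reversible eigendecomposition and simulation).
    """
    counts = np.full((3, 4), 0.0)
    for row in codon_rows:
        row = row.upper().replace("U", "T")
        for k in range(0, len(row) - len(row) % 3, 3):
            for pos in range(3):
                nt = row[k + pos]
                if nt in _NT_INDEX:
                    counts[pos, _NT_INDEX[nt]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, _NT_INDEX[c[0]]]
            * freqs[1, _NT_INDEX[c[1]]]
            * freqs[2, _NT_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unscaled GY94 rate matrix over the 61 sense codons."""
    ii, jj, ts, nonsyn = _change_tables()
    Q = np.zeros((N_SENSE, N_SENSE))
    rates = pi[jj].copy()
    rates[ts] *= kappa
    rates[nonsyn] *= omega
    Q[ii, jj] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def mean_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    return float(-(pi * np.diag(Q)).sum())


def scaled_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    Q = rate_matrix(kappa, omega, pi)
    return Q / mean_rate(Q, pi)


def nonsyn_rate_fraction(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Fraction of the total substitution rate that is nonsynonymous."""
    ii, jj, ts, nonsyn = _change_tables()
    rates = pi[ii] * pi[jj]
    rates[ts] *= kappa
    flow_n = rates[nonsyn].sum() * omega
    flow_s = rates[~nonsyn].sum()
    return float(flow_n * 1.0 / (flow_n + flow_s))


class CodonPropagator:
    """Eigendecomposition of a reversible scaled Q; cheap P(t) for any t."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        self.pi = pi
        Q = scaled_rate_matrix(kappa, omega, pi)
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        lam, U = np.linalg.eigh((B + B.T) / 2.0)
        self._lam = lam
        self._left = U / sqrt_pi[:, None]   # D^{-1/2} U
        self._right = U.T * sqrt_pi[None, :]  # U^T D^{1/2}
        self.Q = Q

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._lam * t)) @ self._right
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P
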