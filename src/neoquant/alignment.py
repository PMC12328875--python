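"""Local peptide alignment and alignment-derived immunogenicity scores.

Implements affine-gap Smith-Waterman on BLOSUM62 for short peptides, the
TCR-recognition probability obtained by aligning a candidate peptide against
a set of known immunogenic epitopes, and its complement against the self
proteome (the "dissimilarity" score).

The recognition model is a logistic transform of a partition function over
alignment scores:

    Z(p) = sum_e exp(-k * (a - s(p, e)))      R = Z / (1 + Z)

where ``s`` is the Smith-Waterman score of the peptide against epitope ``e``,
``a`` is the score horizon (alignments scoring above ``a`` dominate) and
``k`` sets the sharpness of the transition.  Dissimilarity to self is
``1 - R_self`` with the same functional form evaluated against a peptidome of
wildtype k-mers.
"""

from __future__ import annotations

import functools
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from scipy.special import expit, logsumexp

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: gap of length L costs ``gap_open + L * gap_extend``
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

#: recognition-model constants (score horizon and logistic sharpness)
DEFAULT_A = 26.0
DEFAULT_K = 4.87


try:  # JIT kernel for the batch path; the numpy path is the fallback
    from numba import njit as _njit

    @_njit(cache=False, fastmath=False)
    def _sw_kernel_numba(enc_q, enc_s, sub, gap_open, gap_extend):  # pragma: no cover
        Q, n = enc_q.shape
        N, m = enc_s.shape
        out = np.zeros((Q, N), dtype=np.float32)
        open_cost = gap_open + gap_extend
        H = np.zeros((n + 1, m + 1), dtype=np.float32)
        E = np.zeros((n + 1, m + 1), dtype=np.float32)
        F = np.zeros((n + 1, m + 1), dtype=np.float32)
        for qi in range(Q):
            for si in range(N):
                best = np.float32(0.0)
                for i in range(1, n + 1):
                    a = enc_q[qi, i - 1]
                    for j in range(1, m + 1):
                        e = H[i, j - 1] - open_cost
                        e2 = E[i, j - 1] - gap_extend
                        if e2 > e:
                            e = e2
                        E[i, j] = e
                        f = H[i - 1, j] - open_cost
                        f2 = F[i - 1, j] - gap_extend
                        if f2 > f:
                            f = f2
                        F[i, j] = f
                        h = H[i - 1, j - 1] + sub[a, enc_s[si, j - 1]]
                        if h < 0.0:
                            h = 0.0
                        if e > h:
                            h = e
                        if f > h:
                            h = f
                        H[i, j] = h
                        if h > best:
                            best = h
                out[qi, si] = best
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


@functools.lru_cache(maxsize=1)
def _blosum62() -> Tuple[np.ndarray, Dict[str, int]]:
    """20x20 BLOSUM62 slice over the canonical alphabet, plus residue index."""
    mat = substitution_matrices.load("BLOSUM62")
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    sub = np.zeros((20, 20), dtype=np.float32)
    for a, i in idx.items():
        for b, j in idx.items():
            sub[i, j] = mat[a, b]
    return sub, idx


def encode_peptide(peptide: str) -> np.ndarray:
    """Map a peptide to residue indices, rejecting non-canonical residues."""
    _, idx = _blosum62()
    try:
        return np.array([idx[aa] for aa in peptide], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(
            f"invalid residue {exc.args[0]!r} in peptide {peptide!r}"
        ) from exc


def smith_waterman(
    a: str,
    b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Affine-gap local alignment score of two peptides (floor at 0).

    A gap of length ``L`` costs ``gap_open + L * gap_extend``; substitution
    scores come from BLOSUM62.
    """
    if not a or not b:
        raise ValueError("peptides must be non-empty")
    sub, _ = _blosum62()
    ea, eb = encode_peptide(a), encode_peptide(b)
    n, m = len(ea), len(eb)
    neg = -np.inf
    open_cost = gap_open + gap_extend
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (consuming b)
    F = np.full((n + 1, m + 1), neg)  # gap in b (consuming a)
    best = 0.0
    for i in range(1, n + 1):
        row = sub[ea[i - 1]]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - open_cost, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - open_cost, F[i - 1, j] - gap_extend)
            h = max(0.0, H[i - 1, j - 1] + row[eb[j - 1]], E[i, j], F[i, j])
            H[i, j] = h
            if h > best:
                best = h
    return best


class PeptideSet:
    """A reference peptide collection pre-encoded for repeated alignment.

    Encoding dominates the cost of aligning many queries against the same
    large set (e.g. a self peptidome); build once, score many times.
    """

    def __init__(self, peptides: Sequence[str]) -> None:
        self.peptides = list(peptides)
        self._groups: List[Tuple[np.ndarray, np.ndarray]] = []
        by_len: Dict[int, List[int]] = {}
        for pos, s in enumerate(self.peptides):
            by_len.setdefault(len(s), []).append(pos)
        for m, positions in sorted(by_len.items()):
            enc = np.stack([encode_peptide(self.peptides[p]) for p in positions])
            self._groups.append((np.asarray(positions, dtype=np.intp), enc))

    def __len__(self) -> int:
        return len(self.peptides)

    def scores(
        self,
        query: str,
        gap_open: float = DEFAULT_GAP_OPEN,
        gap_extend: float = DEFAULT_GAP_EXTEND,
    ) -> np.ndarray:
        """Smith-Waterman score of ``query`` against every member."""
        sub, _ = _blosum62()
        eq = encode_peptide(query)
        n = len(eq)
        open_cost = gap_open + gap_extend
        out = np.zeros(len(self.peptides))
        for positions, enc in self._groups:
            m = enc.shape[1]
            N = enc.shape[0]
            H_prev = np.zeros((m + 1, N), dtype=np.float32)
            H_cur = np.zeros((m + 1, N), dtype=np.float32)
            E = np.full((m + 1, N), -np.inf, dtype=np.float32)
            best = np.zeros(N, dtype=np.float32)
            for i in range(1, n + 1):
                scores = sub[eq[i - 1]][enc]  # (N, m)
                E[:] = -np.inf
                F_prev = np.full(N, -np.inf)
                H_cur[0] = 0.0
                for j in range(1, m + 1):
                    E[j] = np.maximum(H_cur[j - 1] - open_cost,
                                      E[j - 1] - gap_extend)
                    F = np.maximum(H_prev[j] - open_cost, F_prev - gap_extend)
                    h = np.maximum(H_prev[j - 1] + scores[:, j - 1], 0.0)
                    h = np.maximum(h, np.maximum(E[j], F))
                    H_cur[j] = h
                    F_prev = F
                    np.maximum(best, h, out=best)
                H_prev, H_cur = H_cur, H_prev
            out[positions] = best
        return out


    def scores_many(
        self,
        queries: Sequence[str],
        gap_open: float = DEFAULT_GAP_OPEN,
        gap_extend: float = DEFAULT_GAP_EXTEND,
        max_cells: int = 400_000,
    ) -> np.ndarray:
        """Score matrix (n_queries x n_members) of pairwise SW scores.

        Queries are grouped by length and processed in chunks sized so the
        DP working set stays below ``max_cells`` cells; identical in value
        to calling :meth:`scores` per query but with far less per-call
        overhead.
        """
        queries = list(queries)
        out = np.zeros((len(queries), len(self.peptides)))
        open_cost = gap_open + gap_extend
        sub, _ = _blosum62()
        by_len: Dict[int, List[int]] = {}
        for qi, q in enumerate(queries):
            by_len.setdefault(len(q), []).append(qi)
        for n, q_positions in sorted(by_len.items()):
            enc_q = np.stack(
                [encode_peptide(queries[qi]) for qi in q_positions]
            )  # (Q, n)
            if _HAVE_NUMBA:
                for s_positions, enc_s in self._groups:
                    best = _sw_kernel_numba(
                        np.ascontiguousarray(enc_q, dtype=np.int64),
                        np.ascontiguousarray(enc_s, dtype=np.int64),
                        sub, np.float32(gap_open), np.float32(gap_extend),
                    )
                    out[np.ix_(np.asarray(q_positions), s_positions)] = best
                continue
            for s_positions, enc_s in self._groups:
                m = enc_s.shape[1]
                N = enc_s.shape[0]
                chunk = max(1, max_cells // max(1, N))
                for c0 in range(0, enc_q.shape[0], chunk):
                    eq = enc_q[c0 : c0 + chunk]  # (q, n)
                    q = eq.shape[0]
                    H_prev = np.zeros((m + 1, q, N), dtype=np.float32)
                    H_cur = np.zeros((m + 1, q, N), dtype=np.float32)
                    E = np.full((m + 1, q, N), -np.inf, dtype=np.float32)
                    best = np.zeros((q, N), dtype=np.float32)
                    for i in range(1, n + 1):
                        scores = sub[eq[:, i - 1]][:, enc_s]  # (q, N, m)
                        E[:] = -np.inf
                        F_prev = np.full((q, N), -np.inf)
                        H_cur[0] = 0.0
                        for j in range(1, m + 1):
                            E[j] = np.maximum(H_cur[j - 1] - open_cost,
                                              E[j - 1] - gap_extend)
                            F = np.maximum(H_prev[j] - open_cost,
                                           F_prev - gap_extend)
                            h = np.maximum(
                                H_prev[j - 1] + scores[:, :, j - 1], 0.0
                            )
                            h = np.maximum(h, np.maximum(E[j], F))
                            H_cur[j] = h
                            F_prev = F
                            np.maximum(best, h, out=best)
                        H_prev, H_cur = H_cur, H_prev
                    rows = np.asarray(q_positions[c0 : c0 + chunk])
                    out[np.ix_(rows, s_positions)] = best
        return out


def recognition_scores_many(
    queries: Sequence[str],
    epitopes: "PeptideSet",
    a: float = DEFAULT_A,
    k: float = DEFAULT_K,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> np.ndarray:
    """Vectorised :func:`recognition_score` for many query peptides."""
    if len(epitopes) == 0:
        return np.zeros(len(queries))
    s = epitopes.scores_many(queries, gap_open, gap_extend)
    log_z = logsumexp(-k * (a - s), axis=1)
    return expit(log_z)


def smith_waterman_many(
    query: str,
    subjects: "Sequence[str] | PeptideSet",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> np.ndarray:
    """Smith-Waterman scores of one query against many subject peptides.

    Subjects are grouped by length and each group is aligned with a DP whose
    cell updates are vectorised across the group; identical in value to
    :func:`smith_waterman` on each pair.  Pass a :class:`PeptideSet` to
    amortise subject encoding across queries.
    """
    if len(subjects) == 0:
        return np.zeros(0)
    if not isinstance(subjects, PeptideSet):
        subjects = PeptideSet(subjects)
    return subjects.scores(query, gap_open, gap_extend)


def recognition_score(
    peptide: str,
    epitopes: Sequence[str],
    a: float = DEFAULT_A,
    k: float = DEFAULT_K,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """TCR-recognition probability of a peptide against an epitope set.

    Returns ``Z / (1 + Z)`` with ``Z = sum_e exp(-k (a - s_e))``; 0.0 for an
    empty epitope set.  Computed in log space so near-identical matches
    (``s >> a``) saturate to 1 without overflow.
    """
    if not np.isfinite(a) or not np.isfinite(k):
        raise ValueError("recognition parameters must be finite")
    if not isinstance(epitopes, PeptideSet):
        epitopes = list(epitopes)
    if len(epitopes) == 0:
        return 0.0
    s = smith_waterman_many(peptide, epitopes, gap_open, gap_extend)
    log_z = logsumexp(-k * (a - s))
    return float(expit(log_z))


# the published threshold for calling a neoantigen "IEDB-like"
iedb_recognition_score = recognition_score


def dissimilarity_score(
    peptide: str,
    self_peptidome: Sequence[str],
    a: float = DEFAULT_A,
    k: float = DEFAULT_K,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """One minus the recognition score against the wildtype self peptidome.

    A peptide present verbatim in self scores ~0; a peptide with no positive
    local alignment to any self k-mer scores ~1.  The self set is mandatory.
    """
    if not isinstance(self_peptidome, PeptideSet):
        self_peptidome = list(self_peptidome)
    if len(self_peptidome) == 0:
        raise ValueError("self peptidome must be non-empty")
    return 1.0 - recognition_score(peptide, self_peptidome, a, k, gap_open, gap_extend)


def build_self_peptidome(
    proteome: Dict[str, str],
    genes: Iterable[str] | None = None,
    lengths: Iterable[int] = range(8, 15),
) -> List[str]:
    """All k-mers of the given genes' wildtype sequences (deduplicated).

    By default restricted to ``genes`` (typically the genes carrying
    variants) to keep the alignment workload proportional to the mutated
    fraction of the proteome.
    """
    lengths = list(lengths)
    names = list(genes) if genes is not None else list(proteome)
    seen = set()
    out: List[str] = []
    for g in names:
        seq = proteome[g]
        for k in lengths:
            for i in range(len(seq) - k + 1):
                pep = seq[i : i + k]
                if pep not in seen:
                    seen.add(pep)
                    out.append(pep)
    return out
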