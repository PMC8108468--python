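"""Independent reference implementations used as oracles by the tests.

Each function here recomputes a quantity by the most transparent route
available (plain dynamic programming, exhaustive scanning, triple loops,
normal equations) without touching the package's own code paths.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

_CODON_TABLE = {}
_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AA_ORDER[16 * _i + 4 * _j + _k]


def gotoh_global_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Affine-gap global alignment score by the three-matrix recurrence.

    A gap of length L costs gap_open + (L - 1) * gap_extend; end gaps
    are penalized.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open,
                X[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def orfs_bruteforce(seq: str, min_aa_len: int):
    """All maximal ATG-to-stop ORFs in six frames.

    Returns a set of (frame, fwd_start, fwd_end, peptide, truncated)
    with 1-based inclusive forward-strand coordinates of the codons.
    """
    out = set()
    n = len(seq)
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        for offset in range(3):
            codons = [
                s[p : p + 3] for p in range(offset, len(s) - 2, 3)
            ]
            aa = "".join(_CODON_TABLE[c] for c in codons)
            seg_start = 0
            segments = []
            for i, ch in enumerate(aa):
                if ch == "*":
                    segments.append((seg_start, i, False))
                    seg_start = i + 1
            if seg_start < len(aa):
                segments.append((seg_start, len(aa), True))
            for a0, a1, truncated in segments:
                seg = aa[a0:a1]
                m = seg.find("M")
                if m < 0 or len(seg) - m < min_aa_len:
                    continue
                peptide = seg[m:]
                cs = offset + 3 * (a0 + m)  # 0-based on scanned strand
                ce = cs + 3 * len(peptide) - 1
                if strand == 1:
                    start, end = cs + 1, ce + 1
                else:
                    start, end = n - ce, n - cs
                out.add((strand * (offset + 1), start, end, peptide, truncated))
    return out


def greedy_cluster_reference(peptides, identity_fn, threshold: float):
    """The greedy longest-first clustering rule, written out naively.

    ``peptides`` is a list of (id, seq); ``identity_fn(a, b)`` returns
    the identity fraction over the shorter sequence.  Returns id ->
    cluster index and the list of representative ids.
    """
    ordered = sorted(peptides, key=lambda p: (-len(p[1]), p[0]))
    reps = []
    assignment = {}
    for pid, pseq in ordered:
        for ci, (rid, rseq) in enumerate(reps):
            if identity_fn(pseq, rseq) > threshold:
                assignment[pid] = ci
                break
        else:
            assignment[pid] = len(reps)
            reps.append((pid, pseq))
    return assignment, [r[0] for r in reps]


def mws_like_tripleloop(rows, groups, bovine_map):
    """Triple-loop substitution caller over an explicit alignment.

    ``rows``: id -> gapped string; ``groups``: id -> group;
    ``bovine_map``: bovine position -> 1-based column.  Returns the set
    of (bovine_pos, residue, frozenset(carriers)).
    """
    baikal = [i for i, g in groups.items() if g == "BAIKAL_LWS"]
    elws = [i for i, g in groups.items() if g == "EUROPEAN_LWS"]
    emws = [i for i, g in groups.items() if g == "EUROPEAN_MWS"]
    events = set()
    for pos, col in bovine_map.items():
        by_res = defaultdict(list)
        for sid in baikal:
            ch = rows[sid][col - 1]
            if ch not in "-X":
                by_res[ch].append(sid)
        for res, carriers in by_res.items():
            in_mws = any(rows[sid][col - 1] == res for sid in emws)
            in_elws = any(rows[sid][col - 1] == res for sid in elws)
            if in_mws and not in_elws:
                events.add((pos, res, frozenset(carriers)))
    return events


def ols_normal_equations(x, y):
    """Slope, intercept, R2, adjusted R2 and slope p-value from first principles."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    sigma2 = ss_res / (n - 2)
    se_slope = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    t = beta[1] / se_slope
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return {
        "intercept": float(beta[0]),
        "slope": float(beta[1]),
        "r2": r2,
        "adj_r2": adj,
        "p_slope": float(p),
    }
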