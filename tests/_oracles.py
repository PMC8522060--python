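"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles, separate from
the package code paths it verifies: a full-matrix Smith-Waterman in plain
Python, a dictionary-lookup codon translator, a Lance-Williams Ward
clustering, and a closed-form 2x2 chi-squared test.
"""

import math

from Bio.Align import substitution_matrices

# ---------------------------------------------------------------------------
# plain-Python affine-gap Smith-Waterman
#
# Conventions (shared with the production aligner, implemented independently):
# a gap of length L costs open + L * extend; traceback starts at the
# highest-scoring cell, first in row-major order on ties; at each step a
# substitution column is preferred over a gap in the subject (consuming a
# query residue) over a gap in the query; within a gap state closing the gap
# is preferred over extending it; '*' pairs score -1000 and never count as
# identities.

_B62 = substitution_matrices.load("BLOSUM62")


def _pair_score(a: str, b: str) -> int:
    if a == "*" or b == "*":
        return -1000
    a = a if a in _B62.alphabet else "X"
    b = b if b in _B62.alphabet else "X"
    return int(_B62[a, b])


def sw_oracle(query: str, subject: str, gap_open: int = 11,
              gap_extend: int = 1) -> dict:
    n, m = len(query), len(subject)
    NEG = float("-inf")
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            H[i][j] = max(0,
                          H[i - 1][j - 1]
                          + _pair_score(query[i - 1], subject[j - 1]),
                          E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0:
        return dict(score=0, identities=0, length=0, identity=0.0, gaps=0)
    i, j, state = bi, bj, "H"
    identities = length = gaps = 0
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            diag = (H[i - 1][j - 1]
                    + _pair_score(query[i - 1], subject[j - 1]))
            if H[i][j] == diag:
                length += 1
                if (query[i - 1] == subject[j - 1]
                        and query[i - 1] != "*"):
                    identities += 1
                i, j = i - 1, j - 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "E":
            length += 1
            gaps += 1
            if E[i][j] == H[i][j - 1] - gap_open - gap_extend:
                state = "H"
            j -= 1
        else:
            length += 1
            gaps += 1
            if F[i][j] == H[i - 1][j] - gap_open - gap_extend:
                state = "H"
            i -= 1
    return dict(score=best, identities=identities, length=length,
                identity=identities / length, gaps=gaps)


# ---------------------------------------------------------------------------
# codon-dictionary six-frame translation

_BASES = "TCAG"
_AAS = ("FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG")
CODON_TABLE = {a + b + c: _AAS[16 * i + 4 * j + k]
               for i, a in enumerate(_BASES)
               for j, b in enumerate(_BASES)
               for k, c in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def translate_oracle(dna: str, offset: int = 0) -> str:
    dna = dna.upper()[offset:]
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i:i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def revcomp_oracle(dna: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(dna.upper()))


def six_frames_oracle(dna: str) -> dict:
    rc = revcomp_oracle(dna)
    return {
        "+1": translate_oracle(dna, 0), "+2": translate_oracle(dna, 1),
        "+3": translate_oracle(dna, 2), "-1": translate_oracle(rc, 0),
        "-2": translate_oracle(rc, 1), "-3": translate_oracle(rc, 2),
    }


# ---------------------------------------------------------------------------
# Ward clustering by explicit Lance-Williams updates

def ward_heights_oracle(rows) -> list:
    """Merge heights of Ward clustering via Lance-Williams, ascending."""
    clusters = {i: 1 for i in range(len(rows))}  # id -> size
    d2 = {}
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            d2[(i, j)] = sum((a - b) ** 2 for a, b in zip(rows[i], rows[j]))
    heights = []
    next_id = len(rows)
    while len(clusters) > 1:
        (i, j), dij2 = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(math.sqrt(dij2))
        ni, nj = clusters.pop(i), clusters.pop(j)
        new = next_id
        next_id += 1
        for k, nk in clusters.items():
            dik2 = d2.pop((min(i, k), max(i, k)))
            djk2 = d2.pop((min(j, k), max(j, k)))
            d2[(k, new)] = ((ni + nk) * dik2 + (nj + nk) * djk2
                            - nk * dij2) / (ni + nj + nk)
        d2.pop((i, j))
        clusters[new] = ni + nj
    return heights


# ---------------------------------------------------------------------------
# 2x2 chi-squared test from the closed form; p-value via erfc (df = 1)

def chi2_2x2_oracle(a: int, b: int, c: int, d: int) -> tuple:
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    stat = num / den
    p = math.erfc(math.sqrt(stat / 2.0))
    return stat, p
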