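"""Exhaustive affine-gap local alignment oracle for tiny sequences.

Independent of the package's aligner: a plain Gotoh dynamic program over
three state matrices, with a full traceback that enumerates every optimal
local alignment so co-optimal identity values can be compared.  Gap cost
convention matches BLAST: a gap of length k costs open + k * extend.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def score_pair(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def local_affine_dp(query: str, subject: str, gap_open=11, gap_extend=1):
    """Optimal local score plus the set of (matches, columns) of all
    optimal alignments.

    Returns (score, identities) where identities is a set of fractions
    matches/columns over every distinct optimal local alignment; empty when
    the optimal score is 0 (no alignment).
    """
    n, m = len(query), len(subject)
    first = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject row
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query row
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - first, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - first, F[i][j - 1] - gap_extend)
            diag = H[i - 1][j - 1] + score_pair(query[i - 1], subject[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    if best <= 0:
        return 0.0, set()

    identities: set[float] = set()

    def walk(i, j, state, matches, columns):
        # state: "H" main, "E" extending gap in subject, "F" gap in query
        if state == "H":
            if H[i][j] == 0:
                if columns:
                    identities.add(matches / columns)
                return
            sc = score_pair(query[i - 1], subject[j - 1])
            if H[i][j] == H[i - 1][j - 1] + sc:
                walk(i - 1, j - 1, "H",
                     matches + (query[i - 1] == subject[j - 1]), columns + 1)
            if H[i][j] == E[i][j]:
                walk(i, j, "E", matches, columns)
            if H[i][j] == F[i][j]:
                walk(i, j, "F", matches, columns)
        elif state == "E":
            if E[i][j] == H[i - 1][j] - first:
                walk(i - 1, j, "H", matches, columns + 1)
            if E[i][j] == E[i - 1][j] - gap_extend:
                walk(i - 1, j, "E", matches, columns + 1)
        else:
            if F[i][j] == H[i][j - 1] - first:
                walk(i, j - 1, "H", matches, columns + 1)
            if F[i][j] == F[i][j - 1] - gap_extend:
                walk(i, j - 1, "F", matches, columns + 1)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if H[i][j] == best:
                walk(i, j, "H", 0, 0)
    return best, identities
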