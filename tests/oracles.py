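"""Independent oracles used by the test suite.

The affine-gap dynamic program here is a deliberately plain, textbook Gotoh
implementation kept separate from the package's alignment code so the two
can disagree. Scores only — tracebacks are not needed for the checks.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_score(
    query: str,
    ref: str,
    pair_score,
    gap_open: int,
    gap_extend: int,
    mode: str = "global",
) -> int:
    """Optimal affine-gap alignment score; a gap of length L costs
    gap_open + L * gap_extend. Modes: local, global, semi_global (terminal
    gaps in either sequence free)."""
    n, m = len(query), len(ref)
    local = mode == "local"
    semi = mode == "semi_global"
    open_cost = gap_open + gap_extend

    # M: match/mismatch state; X: gap in ref (query consumed); Y: gap in query
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = 0 if (local or semi) else -(gap_open + i * gap_extend)
        if local:
            M[i][0] = 0
    for j in range(1, m + 1):
        Y[0][j] = 0 if (local or semi) else -(gap_open + j * gap_extend)
        if local:
            M[0][j] = 0

    best_local = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = pair_score(query[i - 1], ref[j - 1])
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = (diag + s) if diag != NEG else NEG
            if local:
                M[i][j] = max(M[i][j], s, 0)
            X[i][j] = max(
                (M[i - 1][j] - open_cost) if M[i - 1][j] != NEG else NEG,
                (X[i - 1][j] - gap_extend) if X[i - 1][j] != NEG else NEG,
                (Y[i - 1][j] - open_cost) if Y[i - 1][j] != NEG else NEG,
            )
            Y[i][j] = max(
                (M[i][j - 1] - open_cost) if M[i][j - 1] != NEG else NEG,
                (X[i][j - 1] - open_cost) if X[i][j - 1] != NEG else NEG,
                (Y[i][j - 1] - gap_extend) if Y[i][j - 1] != NEG else NEG,
            )
            if local:
                best_local = max(best_local, M[i][j])

    if local:
        return int(best_local)
    if semi:
        best = NEG
        for i in range(n + 1):
            best = max(best, M[i][m], X[i][m], Y[i][m])
        for j in range(m + 1):
            best = max(best, M[n][j], X[n][j], Y[n][j])
        return int(best)
    return int(max(M[n][m], X[n][m], Y[n][m]))
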