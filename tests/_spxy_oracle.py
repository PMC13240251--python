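"""Brute-force farthest-point SPXY oracle: plain-loop re-implementation
of the joint-X/Y Kennard-Stone sweep, independent of the package code."""

import math


def spxy_oracle_train_indices(X, y, n_train):
    n = len(y)
    dx = [[0.0] * n for _ in range(n)]
    dy = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            dx[i][j] = math.sqrt(sum((X[i][k] - X[j][k]) ** 2 for k in range(len(X[i]))))
            dy[i][j] = abs(y[i] - y[j])
    mx = max(max(row) for row in dx)
    my = max(max(row) for row in dy)
    d = [
        [
            (dx[i][j] / mx if mx > 0 else 0.0) + (dy[i][j] / my if my > 0 else 0.0)
            for j in range(n)
        ]
        for i in range(n)
    ]

    # seed: the pair at maximum combined distance (first encountered in
    # row-major order, matching argmax on the flattened matrix)
    best, bi, bj = -1.0, 0, 0
    for i in range(n):
        for j in range(n):
            if d[i][j] > best:
                best, bi, bj = d[i][j], i, j
    selected = [min(bi, bj), max(bi, bj)]
    remaining = [r for r in range(n) if r not in selected]

    while len(selected) < n_train:
        best_k, best_min = None, -1.0
        for r in remaining:
            mind = min(d[r][s] for s in selected)
            if mind > best_min:  # strict: ties keep the earliest (lowest) index
                best_min, best_k = mind, r
        selected.append(best_k)
        remaining.remove(best_k)
    return selected
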