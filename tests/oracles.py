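"""Independent brute-force (triple-loop) reference implementations.

These deliberately avoid any vectorized shortcut shared with the package so
that agreement is a meaningful check.
"""

import math


def brute_tom(a):
    n = len(a)
    omega = [[0.0] * n for _ in range(n)]
    for i in range(n):
        omega[i][i] = 1.0
        for j in range(n):
            if i == j:
                continue
            l_ij = 0.0
            for u in range(n):
                if u != i and u != j:
                    l_ij += a[i][u] * a[u][j]
            k_i = sum(a[i][u] for u in range(n) if u != i)
            k_j = sum(a[j][u] for u in range(n) if u != j)
            omega[i][j] = (l_ij + a[i][j]) / (min(k_i, k_j) + 1.0 - a[i][j])
    return omega


def brute_connectivity(a):
    n = len(a)
    return [sum(a[i][j] for j in range(n) if j != i) for i in range(n)]


def brute_mar(a):
    n = len(a)
    out = []
    for i in range(n):
        num = sum(a[i][j] ** 2 for j in range(n) if j != i)
        den = sum(a[i][j] for j in range(n) if j != i)
        out.append(num / den if den > 0 else float("nan"))
    return out


def brute_clustering(a):
    n = len(a)
    out = []
    for i in range(n):
        num = 0.0
        for j in range(n):
            if j == i:
                continue
            for q in range(n):
                if q != i and q != j:
                    num += a[i][j] * a[j][q] * a[q][i]
        k_i = sum(a[i][j] for j in range(n) if j != i)
        den = k_i**2 - sum(a[i][j] ** 2 for j in range(n) if j != i)
        out.append(num / den if den > 0 else 0.0)
    return out


def brute_density(a):
    n = len(a)
    total = sum(a[i][j] for i in range(n) for j in range(n) if i != j)
    return total / (n * (n - 1))


def brute_centralization(a):
    n = len(a)
    k = brute_connectivity(a)
    return (n / (n - 2)) * (max(k) / (n - 1) - brute_density(a))


def brute_heterogeneity(a):
    k = brute_connectivity(a)
    n = len(k)
    mean_k = sum(k) / n
    mean_k2 = sum(v * v for v in k) / n
    if mean_k <= 0:
        return 0.0
    return math.sqrt(max(mean_k2 / mean_k**2 - 1.0, 0.0))
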