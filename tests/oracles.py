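"""Independent brute-force oracles used to validate the implementation.

Everything here is written as plain loops, straight from the defining
formulas, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations

import numpy as np


# ---------------------------------------------------------------- quantize
def quantize_oracle(values, n_levels):
    lo, hi = min(values), max(values)
    if hi == lo:
        return [1 for _ in values]
    out = []
    width = (hi - lo) / n_levels
    for v in values:
        k = int((v - lo) // width) + 1
        out.append(min(max(k, 1), n_levels))
    return out


# ------------------------------------------------------------- first order
def first_order_oracle(values, n_bins=32):
    x = [float(v) for v in values]
    n = len(x)
    mean = sum(x) / n
    dev = [v - mean for v in x]
    m2 = sum(d**2 for d in dev) / n
    m3 = sum(d**3 for d in dev) / n
    m4 = sum(d**4 for d in dev) / n
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 if m2 > 0 else 0.0
    lo, hi = min(x), max(x)
    if hi > lo:
        counts = [0] * n_bins
        width = (hi - lo) / n_bins
        for v in x:
            k = int((v - lo) / width)
            counts[min(k, n_bins - 1)] += 1
        probs = [c / n for c in counts if c > 0]
        entropy = -sum(p * math.log2(p) for p in probs)
        uniformity = sum(p**2 for p in probs)
    else:
        entropy, uniformity = 0.0, 1.0
    var = sum(d**2 for d in dev) / (n - 1) if n > 1 else 0.0
    srt = sorted(x)
    median = (srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2)
    return {
        "firstorder_energy": sum(v**2 for v in x),
        "firstorder_entropy": entropy,
        "firstorder_kurtosis": kurt,
        "firstorder_maximum": hi,
        "firstorder_mean": mean,
        "firstorder_mad": sum(abs(d) for d in dev) / n,
        "firstorder_median": median,
        "firstorder_minimum": lo,
        "firstorder_range": hi - lo,
        "firstorder_rms": math.sqrt(sum(v**2 for v in x) / n),
        "firstorder_skewness": skew,
        "firstorder_std": math.sqrt(var),
        "firstorder_uniformity": uniformity,
        "firstorder_variance": var,
    }


# ------------------------------------------------------------------- GLCM
def glcm_counts_oracle(levels, mask, offset, n_levels):
    """Exhaustive in-region voxel-pair enumeration (symmetric)."""
    counts = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        nb = tuple(idx[k] + offset[k] for k in range(len(shape)))
        if all(0 <= nb[k] < shape[k] for k in range(len(shape))) and mask[nb]:
            a, b = levels[idx] - 1, levels[nb] - 1
            counts[a, b] += 1
            counts[b, a] += 1
    return counts


def glcm_features_oracle(p):
    """Direct double-loop evaluation of the 22 co-occurrence features."""
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))

    p_sum = {}
    p_diff = {}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + p[i, j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p[i, j]

    def ent(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    hxy = ent(p.ravel())
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(p[i, j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng)
                if p[i, j] > 0 and px[i] * py[j] > 0)
    hxy2 = ent([px[i] * py[j] for i in range(ng) for j in range(ng)])

    out = {}
    out["glcm_autocorrelation"] = sum((i + 1) * (j + 1) * p[i, j]
                                      for i in range(ng) for j in range(ng))
    for name, power in [("glcm_cluster_prominence", 4),
                        ("glcm_cluster_shade", 3),
                        ("glcm_cluster_tendency", 2)]:
        out[name] = sum((i + 1 + j + 1 - mu_x - mu_y) ** power * p[i, j]
                        for i in range(ng) for j in range(ng))
    out["glcm_contrast"] = sum((i - j) ** 2 * p[i, j]
                               for i in range(ng) for j in range(ng))
    out["glcm_correlation"] = ((out["glcm_autocorrelation"] - mu_x * mu_y)
                               / (sig_x * sig_y)) if sig_x > 0 and sig_y > 0 else 0.0
    out["glcm_difference_entropy"] = ent(p_diff.values())
    out["glcm_dissimilarity"] = sum(abs(i - j) * p[i, j]
                                    for i in range(ng) for j in range(ng))
    out["glcm_energy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    out["glcm_entropy"] = hxy
    out["glcm_homogeneity1"] = sum(p[i, j] / (1 + abs(i - j))
                                   for i in range(ng) for j in range(ng))
    out["glcm_homogeneity2"] = sum(p[i, j] / (1 + (i - j) ** 2)
                                   for i in range(ng) for j in range(ng))
    out["glcm_imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    arg = 1 - math.exp(-2 * (hxy2 - hxy))
    out["glcm_imc2"] = math.sqrt(arg) if arg > 0 else 0.0
    out["glcm_idmn"] = sum(p[i, j] / (1 + (i - j) ** 2 / ng**2)
                           for i in range(ng) for j in range(ng))
    out["glcm_idn"] = sum(p[i, j] / (1 + abs(i - j) / ng)
                          for i in range(ng) for j in range(ng))
    out["glcm_inverse_variance"] = sum(p[i, j] / (i - j) ** 2
                                       for i in range(ng) for j in range(ng)
                                       if i != j)
    out["glcm_maximum_probability"] = max(p[i, j] for i in range(ng)
                                          for j in range(ng))
    sa = sum(k * v for k, v in p_sum.items())
    out["glcm_sum_average"] = sa
    out["glcm_sum_entropy"] = ent(p_sum.values())
    out["glcm_sum_variance"] = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    out["glcm_variance"] = sum((i + 1 - mu_x) ** 2 * p[i, j]
                               for i in range(ng) for j in range(ng))
    return out


# ------------------------------------------------------------------ GLRLM
def glrlm_counts_oracle(levels, mask, direction):
    """Exhaustive run scanning: walk every maximal run along direction."""
    shape = levels.shape
    runs = {}
    d = tuple(int(v) for v in direction)

    def inside(idx):
        return all(0 <= idx[k] < shape[k] for k in range(3)) and mask[idx]

    for idx in np.ndindex(shape):
        if not inside(idx):
            continue
        prev = tuple(idx[k] - d[k] for k in range(3))
        # run start: predecessor absent or different level
        if inside(prev) and levels[prev] == levels[idx]:
            continue
        length = 1
        cur = idx
        while True:
            nxt = tuple(cur[k] + d[k] for k in range(3))
            if inside(nxt) and levels[nxt] == levels[cur]:
                length += 1
                cur = nxt
            else:
                break
        key = (int(levels[idx]), length)
        runs[key] = runs.get(key, 0) + 1
    return runs


def glrlm_features_oracle(counts, n_voxels):
    n_runs = counts.sum()
    out = {k: 0.0 for k in ["glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_rln",
                            "glrlm_lgre", "glrlm_hgre", "glrlm_srlge",
                            "glrlm_srhge", "glrlm_lrlge", "glrlm_lrhge"]}
    ng, nl = counts.shape
    for g in range(1, ng + 1):
        for l in range(1, nl + 1):
            c = counts[g - 1, l - 1]
            out["glrlm_sre"] += c / l**2
            out["glrlm_lre"] += c * l**2
            out["glrlm_lgre"] += c / g**2
            out["glrlm_hgre"] += c * g**2
            out["glrlm_srlge"] += c / (g**2 * l**2)
            out["glrlm_srhge"] += c * g**2 / l**2
            out["glrlm_lrlge"] += c * l**2 / g**2
            out["glrlm_lrhge"] += c * g**2 * l**2
    out["glrlm_gln"] = sum(counts[g].sum() ** 2 for g in range(ng))
    out["glrlm_rln"] = sum(counts[:, l].sum() ** 2 for l in range(nl))
    for k in out:
        out[k] /= n_runs
    out["glrlm_rp"] = n_runs / n_voxels
    return out


# ------------------------------------------------------------------ graphs
def bfs_distances(adj, source):
    n = len(adj)
    dist = [math.inf] * n
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u][v] and dist[v] == math.inf:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def graph_metrics_oracle(adj):
    """Degree, neighbor degree, clustering, C, L, sparseness, efficiency,
    raw+normalized betweenness — all by exhaustive enumeration."""
    n = len(adj)
    deg = [sum(adj[i]) for i in range(n)]
    nbr_deg = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        nbr_deg.append(sum(deg[j] for j in nbrs) / len(nbrs) if nbrs else 0.0)
    clustering = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            clustering.append(0.0)
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj[a][b])
        clustering.append(2.0 * links / (k * (k - 1)))
    C = sum(clustering) / n

    dists = [bfs_distances(adj, s) for s in range(n)]
    finite = [dists[i][j] for i in range(n) for j in range(n)
              if i != j and dists[i][j] < math.inf]
    L = sum(finite) / len(finite) if finite else math.nan
    inv = [1.0 / dists[i][j] if dists[i][j] < math.inf else 0.0
           for i in range(n) for j in range(n) if i != j]
    geff = sum(inv) / (n * (n - 1))
    m = sum(deg) // 2
    sparseness = 2.0 * m / (n * (n - 1))

    # betweenness by explicit shortest-path enumeration
    def all_shortest_paths(s, t):
        d = dists[s][t]
        if d == math.inf:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for v in range(n):
                if adj[u][v] and dists[s][v] == len(path) and dists[v][t] == d - len(path):
                    extend(path + [v])

        extend([s])
        return paths

    bc = [0.0] * n
    for s, t in combinations(range(n), 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    scale = (n - 1) * (n - 2) / 2.0
    bc_norm = [b / scale for b in bc]
    return {"degree": deg, "neighbor_degree": nbr_deg, "clustering": clustering,
            "C": C, "L": L, "sparseness": sparseness, "global_efficiency": geff,
            "betweenness_raw": bc, "betweenness": bc_norm}


# -------------------------------------------------------------- statistics
def pearson_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def pearson_p_oracle(r, n):
    from scipy import stats
    df = n - 2
    t = r * math.sqrt(df / (1 - r**2))
    return 2 * stats.t.sf(abs(t), df)


def icc_oracle(x):
    """One-way ANOVA ICC for a subjects x sessions table, by loops."""
    s = len(x)
    k = len(x[0])
    grand = sum(sum(row) for row in x) / (s * k)
    means = [sum(row) / k for row in x]
    ssb = k * sum((m - grand) ** 2 for m in means)
    ssw = sum((v - means[i]) ** 2 for i, row in enumerate(x) for v in row)
    bms = ssb / (s - 1)
    wms = ssw / (s * (k - 1))
    return (bms - wms) / bms
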