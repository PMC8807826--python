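"""Naive brute-force re-implementation of the DMR caller, used as oracle.

Everything here is written with explicit loops and direct formulas,
independently of the package's vectorized implementation.
"""

import numpy as np
from scipy.stats import norm


def naive_stouffer(p, sigma):
    z = [norm.isf(max(pi, 1e-300)) for pi in p]
    k = len(z)
    if k == 1:
        return float(p[0])
    var = 0.0
    for i in range(k):
        for j in range(k):
            var += 1.0 if i == j else sigma[i][j]
    return float(max(norm.sf(sum(z) / np.sqrt(var)), 1e-300))


def naive_acf_lookup(corr_by_bin, edges, d):
    for b in range(len(corr_by_bin)):
        if edges[b] <= d < edges[b + 1]:
            return min(max(corr_by_bin[b], 0.0), 1.0)
    return 0.0


def naive_acf(chrom, pos, p, bin_width, max_lag, min_pairs=10):
    edges = [1.0]
    while edges[-1] + bin_width <= max_lag + 1:
        edges.append(edges[-1] + bin_width)
    if edges[-1] < max_lag + 1:
        edges.append(max_lag + 1)
    n_bins = len(edges) - 1
    z = [norm.isf(max(pi, 1e-300)) for pi in p]
    buckets = [[] for _ in range(n_bins)]
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if chrom[i] != chrom[j]:
                continue
            d = abs(pos[j] - pos[i])
            for b in range(n_bins):
                if edges[b] <= d < edges[b + 1]:
                    buckets[b].append((z[i], z[j]))
    corr = [np.nan] * n_bins
    for b, pairs in enumerate(buckets):
        if len(pairs) >= min_pairs:
            a = np.array(pairs)
            if a[:, 0].std() > 0 and a[:, 1].std() > 0:
                corr[b] = float(np.corrcoef(a[:, 0], a[:, 1])[0, 1])
    good = [b for b in range(n_bins) if np.isfinite(corr[b])]
    if not good:
        corr = [0.0] * n_bins
    else:
        corr = list(np.interp(np.arange(n_bins), good,
                              [corr[b] for b in good]))
    return corr, edges


def naive_smooth(chrom, pos, p, corr, edges, window):
    half = window / 2.0
    out = []
    for i in range(len(pos)):
        members = [
            j for j in range(len(pos))
            if chrom[j] == chrom[i] and abs(pos[j] - pos[i]) <= half
        ]
        if len(members) == 1:
            out.append(p[i])
            continue
        sub_p = [p[j] for j in members]
        sigma = [
            [
                1.0 if a == b
                else naive_acf_lookup(corr, edges, abs(pos[members[a]] - pos[members[b]]))
                for b in range(len(members))
            ]
            for a in range(len(members))
        ]
        out.append(naive_stouffer(sub_p, sigma))
    return out


def naive_regions(chrom, pos, p, smoothed, corr, edges, seed_p, window,
                  min_probes):
    total_width = 0
    for c in sorted(set(chrom)):
        cp = [pos[i] for i in range(len(pos)) if chrom[i] == c]
        total_width += max(cp) - min(cp) + 1
    regions = []
    i = 0
    while i < len(pos):
        if smoothed[i] >= seed_p:
            i += 1
            continue
        j = i
        while (
            j + 1 < len(pos)
            and chrom[j + 1] == chrom[j]
            and smoothed[j + 1] < seed_p
            and pos[j + 1] - pos[j] <= window
        ):
            j += 1
        if j - i + 1 >= min_probes:
            members = list(range(i, j + 1))
            sigma = [
                [
                    1.0 if a == b
                    else naive_acf_lookup(corr, edges,
                                          abs(pos[members[a]] - pos[members[b]]))
                    for b in range(len(members))
                ]
                for a in range(len(members))
            ]
            rp = naive_stouffer([p[m] for m in members], sigma)
            width = pos[j] - pos[i] + 1
            sidak = 1.0 - (1.0 - rp) ** (total_width / width)
            regions.append(
                {"chrom": chrom[i], "start": pos[i], "end": pos[j],
                 "n_probes": j - i + 1, "region_p": rp,
                 "sidak_p": max(min(sidak, 1.0), rp)}
            )
        i = j + 1
    return regions


def naive_dmr_scan(chrom, pos, p, window=750, seed_p=0.05, min_probes=2,
                   bin_width=150):
    corr, edges = naive_acf(chrom, pos, p, bin_width, window)
    smoothed = naive_smooth(chrom, pos, p, corr, edges, window)
    return naive_regions(chrom, pos, p, smoothed, corr, edges, seed_p, window,
                         min_probes)
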