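"""Spatially aware DMR calling by correlation-adjusted p-value combination.

Re-implements the comb-p procedure: (1) estimate the autocorrelation of
probit-transformed p-values as a function of genomic distance, (2) smooth
each probe's p by a Stouffer-Liptak-Kechris combination over its
+/- window/2 neighborhood, (3) seed regions at sub-threshold smoothed
probes and extend over runs whose inter-probe gaps stay within the
window, (4) score each region by combining its original p-values with
the estimated correlations and apply a Sidak correction for the number
of independent region-sized windows in the covered track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

P_FLOOR = 1e-300
DEFAULT_WINDOW = 750
DEFAULT_SEED_P = 0.05
DEFAULT_MIN_PROBES = 2


def validate_track(track: pd.DataFrame) -> pd.DataFrame:
    """Sort and sanity-check a per-probe (chrom, pos, p) track."""
    track = track.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    p = track["p"].to_numpy(float)
    if ((p <= 0) | (p > 1)).any():
        if (p <= 0).any():
            raise ValueError("p = 0 in track; floor p-values upstream")
        raise ValueError("p-values must lie in (0, 1]")
    for chrom, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if (np.diff(pos) <= 0).any():
            raise ValueError(f"positions not strictly increasing on {chrom}")
    return track


@dataclass
class AcfEstimate:
    """Binned distance autocorrelation of probit-transformed p-values."""

    bin_edges: np.ndarray  # len n_bins+1, half-open [lo, hi) from 1 bp
    correlations: np.ndarray
    pair_counts: np.ndarray
    interpolated: np.ndarray  # bins with too few pairs, filled from neighbors

    def lookup(self, distance) -> np.ndarray:
        """Correlation for pairwise distances; 0 beyond the last bin.

        Correlations are clipped to [0, 1] for use in the combination
        variance (negative noisy estimates would be anti-conservative).
        """
        d = np.atleast_1d(np.asarray(distance, dtype=float))
        idx = np.searchsorted(self.bin_edges, d, side="right") - 1
        out = np.zeros(d.shape)
        ok = (idx >= 0) & (idx < len(self.correlations)) & (d >= self.bin_edges[0])
        out[ok] = np.clip(self.correlations[idx[ok]], 0.0, 1.0)
        return out


def _probit(p: np.ndarray) -> np.ndarray:
    return norm.isf(np.maximum(p, P_FLOOR))


def estimate_acf(track: pd.DataFrame, bin_width: int = 150,
                 max_lag: int = DEFAULT_WINDOW, min_pairs: int = 10) -> AcfEstimate:
    """Distance-binned Pearson autocorrelation of z = Phi^-1(1 - p).

    Pairs are intra-chromosome probe pairs with distance in (0, max_lag];
    bins are contiguous half-open intervals starting at 1 bp.  Bins with
    fewer than ``min_pairs`` pairs are flagged and linearly interpolated
    from their neighbors.
    """
    track = validate_track(track)
    if len(track) < 2:
        raise ValueError("need at least 2 probes to estimate an ACF")
    if max_lag < bin_width:
        raise ValueError("max_lag must be >= bin_width")
    edges = np.arange(1, max_lag + bin_width + 1, bin_width, dtype=float)
    edges = edges[edges <= max_lag + 1]
    if edges[-1] < max_lag + 1:
        edges = np.append(edges, max_lag + 1)
    n_bins = len(edges) - 1

    pairs: list[list[tuple[float, float]]] = [[] for _ in range(n_bins)]
    for _, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        z = _probit(sub["p"].to_numpy(float))
        for i in range(len(pos)):
            j = i + 1
            while j < len(pos) and pos[j] - pos[i] <= max_lag:
                b = int(np.searchsorted(edges, pos[j] - pos[i], side="right") - 1)
                if 0 <= b < n_bins:
                    pairs[b].append((z[i], z[j]))
                j += 1

    corr = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b, pp in enumerate(pairs):
        counts[b] = len(pp)
        if len(pp) >= min_pairs:
            a = np.asarray(pp)
            if a[:, 0].std() > 0 and a[:, 1].std() > 0:
                corr[b] = float(np.corrcoef(a[:, 0], a[:, 1])[0, 1])
    interpolated = ~np.isfinite(corr)
    if interpolated.all():
        corr[:] = 0.0
    elif interpolated.any():
        good = np.nonzero(~interpolated)[0]
        corr = np.interp(np.arange(n_bins), good, corr[good])
    return AcfEstimate(bin_edges=edges, correlations=corr,
                       pair_counts=counts, interpolated=interpolated)


def stouffer_liptak(p_values, pairwise_correlations=None) -> float:
    """Correlation-adjusted Stouffer combination of one-sided p-values.

    z_i = Phi^-1(1 - p_i); combined z = sum(z) / sqrt(k + 2 * sum_{i<j} sigma_ij);
    returns 1 - Phi(z_comb), floored at the smallest positive double.
    """
    p = np.asarray(p_values, dtype=float)
    if (p <= 0).any():
        raise ValueError("p = 0 input; floor p-values upstream")
    if (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    k = p.size
    if k == 1:
        return float(p[0])
    if pairwise_correlations is None:
        sigma = np.zeros((k, k))
    else:
        sigma = np.asarray(pairwise_correlations, dtype=float).copy()
    np.fill_diagonal(sigma, 1.0)
    if not np.allclose(sigma, sigma.T):
        raise ValueError("correlation matrix must be symmetric")
    var = float(sigma.sum())
    if var <= 0:
        raise ValueError("combination variance is non-positive (non-PSD matrix)")
    z = _probit(p)
    z_comb = z.sum() / np.sqrt(var)
    return float(max(norm.sf(z_comb), P_FLOOR))


def slk_smooth_track(track: pd.DataFrame, acf: AcfEstimate,
                     window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Replace each probe's p by the SLK combination of its neighborhood.

    The neighborhood is every probe within +/- window/2 bp on the same
    chromosome, itself included; pairwise correlations are looked up from
    the ACF by distance.  Isolated probes are returned unchanged.
    """
    track = validate_track(track)
    half = window / 2.0
    out = track.copy()
    smoothed = np.empty(len(track))
    row0 = 0
    for _, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        p = sub["p"].to_numpy(float)
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        for i in range(len(pos)):
            sel = slice(lo[i], hi[i])
            pp = p[sel]
            if pp.size == 1:
                smoothed[row0 + i] = p[i]
                continue
            d = np.abs(pos[sel][:, None] - pos[sel][None, :])
            sigma = acf.lookup(d)
            smoothed[row0 + i] = stouffer_liptak(pp, sigma)
        row0 += len(pos)
    out["p_smoothed"] = smoothed
    return out


def sidak_correct(region_p: float, region_width: int, total_width: int) -> float:
    """Sidak correction 1 - (1 - p)^(total_width / region_width)."""
    if region_width <= 0 or total_width <= 0:
        raise ValueError("widths must be positive")
    if not 0.0 < region_p <= 1.0:
        raise ValueError("region p must lie in (0, 1]")
    ratio = total_width / region_width
    return float(min(max(-np.expm1(ratio * np.log1p(-region_p)), region_p), 1.0))


def call_regions(smoothed: pd.DataFrame, acf: AcfEstimate,
                 seed_p: float = DEFAULT_SEED_P, window: int = DEFAULT_WINDOW,
                 min_probes: int = DEFAULT_MIN_PROBES,
                 total_width: int | None = None) -> pd.DataFrame:
    """Seed-and-extend region calls on a smoothed track.

    Regions are maximal runs of probes with smoothed p < seed_p whose
    inter-probe gaps stay within ``window``; runs with at least
    ``min_probes`` probes are emitted.  The region p combines the
    original (unsmoothed) p-values with ACF correlations; the Sidak
    correction uses total covered track extent over region width.
    """
    if smoothed.empty:
        return _empty_regions()
    track = smoothed.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    if total_width is None:
        total_width = int(
            sum(
                sub["pos"].max() - sub["pos"].min() + 1
                for _, sub in track.groupby("chrom", sort=False)
            )
        )
    rows = []
    for chrom, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        p_orig = sub["p"].to_numpy(float)
        p_sm = sub["p_smoothed"].to_numpy(float)
        probe_ids = (
            sub["probe_id"].to_numpy()
            if "probe_id" in sub.columns
            else np.array([f"{chrom}:{x}" for x in pos])
        )
        below = p_sm < seed_p
        i = 0
        while i < len(pos):
            if not below[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(pos) and below[j + 1] and pos[j + 1] - pos[j] <= window:
                j += 1
            if j - i + 1 >= min_probes:
                sel = slice(i, j + 1)
                d = np.abs(pos[sel][:, None] - pos[sel][None, :])
                sigma = acf.lookup(d)
                region_p = stouffer_liptak(p_orig[sel], sigma)
                width = int(pos[j] - pos[i] + 1)
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(pos[i]),
                        "end": int(pos[j]),
                        "n_probes": j - i + 1,
                        "probes": ",".join(map(str, probe_ids[sel])),
                        "region_p": region_p,
                        "sidak_p": sidak_correct(region_p, width, total_width),
                    }
                )
            i = j + 1
    return pd.DataFrame(rows) if rows else _empty_regions()


def _empty_regions() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "n_probes", "probes", "region_p", "sidak_p"]
    )


def dmr_scan(track: pd.DataFrame, window: int = DEFAULT_WINDOW,
             seed_p: float = DEFAULT_SEED_P, min_probes: int = DEFAULT_MIN_PROBES,
             bin_width: int = 150) -> pd.DataFrame:
    """End-to-end DMR call: ACF -> smoothing -> seed-and-extend -> Sidak."""
    track = validate_track(track)
    if len(track) < 2:
        return _empty_regions()
    acf = estimate_acf(track, bin_width=bin_width, max_lag=window)
    smoothed = slk_smooth_track(track, acf, window=window)
    return call_regions(smoothed, acf, seed_p=seed_p, window=window,
                        min_probes=min_probes)
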