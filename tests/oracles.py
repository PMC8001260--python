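"""Independent brute-force oracles used by the tests.

These deliberately avoid the vectorized implementation paths: plain
Python loops, per-peak linear scans over explicit bin-edge lists, and
``math``-module arithmetic only.
"""

from __future__ import annotations

import math

from agnospec.peaklist import Spectrum


def brute_force_feature_image(s: Spectrum, cfg) -> tuple[list, list]:
    """Naive (counts, transformed) tensors as nested Python lists."""
    ni, nj, nk = cfg.n_mz_bins, cfg.n_abund_bins, cfg.n_kmd_bins
    counts = [[[0] * nk for _ in range(nj)] for _ in range(ni)]

    mz_edges = [cfg.mz_range[0] + m * (cfg.mz_range[1] - cfg.mz_range[0]) / ni
                for m in range(ni + 1)]
    y_edges = [m * 1.0 / nj for m in range(nj + 1)]
    kmd_edges = [cfg.kmd_range_mDa[0]
                 + m * (cfg.kmd_range_mDa[1] - cfg.kmd_range_mDa[0]) / nk
                 for m in range(nk + 1)]

    def locate(v, edges):
        # half-open [lo, hi) bins, final bin closed at the top
        if v == edges[-1]:
            return len(edges) - 2
        for b in range(len(edges) - 1):
            if edges[b] <= v < edges[b + 1]:
                return b
        return None

    if len(s.peaks) > 0:
        mean_log = sum(math.log(p.intensity) for p in s.peaks) / len(s.peaks)
        for p in s.peaks:
            km = p.mz * 14.00000 / 14.01565
            nominal = math.floor(km + 0.5)
            kmd = (nominal - km) * 1000.0
            y = (math.log(p.intensity) - mean_log + cfg.abund_offset) / cfg.abund_scale
            bi = locate(p.mz, mz_edges)
            bj = locate(y, y_edges)
            bk = locate(kmd, kmd_edges)
            if bi is not None and bj is not None and bk is not None:
                counts[bi][bj][bk] += 1

    values = [[[0.0] * nk for _ in range(nj)] for _ in range(ni)]
    for j in range(nj):
        for k in range(nk):
            total = sum(counts[i][j][k] for i in range(ni))
            for i in range(ni):
                n_norm = counts[i][j][k] / (total + cfg.eps)
                values[i][j][k] = (
                    cfg.log_gain * math.log(cfg.log_floor + n_norm) + cfg.log_shift
                )
    return counts, values
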