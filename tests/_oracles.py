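"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's scanning implementations: regions
are found by enumerating every contiguous probe window and keeping the
maximal valid ones; interval mapping is O(n*m) containment.
"""

from __future__ import annotations

import numpy as np


def brute_force_regions(probes, min_probes=3, max_gap_bp=500, p_max=0.01,
                        min_mean_abs_delta=0.2):
    """Enumerate all maximal qualifying runs from a probe list.

    ``probes``: iterable of (probe_id, chrom, pos, delta_beta, p_value).
    Returns a sorted list of dicts with chrom/start/end/probe_ids/mean.
    """
    by_chrom: dict[str, list] = {}
    for p in probes:
        by_chrom.setdefault(p[1], []).append(p)
    out = []
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom], key=lambda r: (r[2], r[0]))
        n = len(ps)

        def qualifies(i):
            return ps[i][4] < p_max and ps[i][3] != 0

        def compatible(i, j):
            # adjacent probes i < j = i+1 within one run
            return (np.sign(ps[i][3]) == np.sign(ps[j][3])
                    and (ps[j][2] - ps[i][2]) < max_gap_bp)

        def valid(i, j):
            # window [i, j] inclusive
            if not all(qualifies(k) for k in range(i, j + 1)):
                return False
            return all(compatible(k, k + 1) for k in range(i, j))

        for i in range(n):
            for j in range(i, n):
                if not valid(i, j):
                    continue
                if i > 0 and valid(i - 1, j):
                    continue  # extendable left
                if j < n - 1 and valid(i, j + 1):
                    continue  # extendable right
                if j - i + 1 < min_probes:
                    continue
                mean_d = float(np.mean([ps[k][3] for k in range(i, j + 1)]))
                if abs(mean_d) <= min_mean_abs_delta:
                    continue
                out.append({
                    "chrom": chrom,
                    "start": ps[i][2],
                    "end": ps[j][2],
                    "probe_ids": tuple(ps[k][0] for k in range(i, j + 1)),
                    "mean_delta_beta": mean_d,
                })
    out.sort(key=lambda r: (r["chrom"], r["start"]))
    return out


def brute_force_probe_map(annotation, dmrs):
    """O(n*m) interval-containment probe-to-DMR mapping."""
    out = {}
    for d in dmrs:
        hits = [(int(row.pos), pid) for pid, row in annotation.iterrows()
                if row.chrom == d.chrom and d.start <= row.pos <= d.end]
        out[d.name] = [pid for _, pid in sorted(hits)]
    return out


def random_probe_instance(rng, n_max=25, n_chroms=2):
    """Random small probe-statistics instance for oracle comparisons."""
    n = int(rng.integers(1, n_max + 1))
    probes = []
    for chrom_i in range(n_chroms):
        chrom = f"chr{chrom_i + 1}"
        pos = 0
        for k in range(n):
            pos += int(rng.integers(10, 801))
            delta = float(rng.normal(0, 0.3))
            if rng.random() < 0.1:
                delta = 0.0
            p = float(rng.uniform(0, 0.02)) if rng.random() < 0.7 else float(rng.uniform(0, 1))
            probes.append((f"{chrom}_p{k:03d}", chrom, pos, delta, p))
    return probes
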