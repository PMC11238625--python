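"""Independent brute-force re-implementation of the profile-matching pipeline.

Pure-Python loops and the standard-library ``statistics`` module only — no
numpy/pandas — so it cannot share a code path (or a bug) with the package.
Used as the oracle for Z-scores, distances, and whole-pipeline recovery.
"""

from __future__ import annotations

import math
import statistics


def naive_zscore_row(values, sample_sd=True):
    mu = sum(values) / len(values)
    denom = len(values) - 1 if sample_sd else len(values)
    sd = math.sqrt(sum((v - mu) ** 2 for v in values) / denom)
    return [(v - mu) / sd for v in values]


def naive_euclid(x, y):
    assert len(x) == len(y)
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))


def naive_pipeline(rows, reference_ids, log2=False):
    """rows: dict protein_id -> list of abundances. Returns (distances, threshold,
    selected_ids) with auto thresholding (max reference distance, <= selection,
    reference excluded from the selection)."""
    if log2:
        rows = {pid: [math.log2(v) for v in vals] for pid, vals in rows.items()}
    z = {}
    for pid, vals in rows.items():
        mu = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / (len(vals) - 1))
        if sd == 0:
            continue
        z[pid] = [(v - mu) / sd for v in vals]
    n_samples = len(next(iter(z.values())))
    consensus = [
        statistics.median(z[r][j] for r in reference_ids) for j in range(n_samples)
    ]
    distances = {pid: naive_euclid(zrow, consensus) for pid, zrow in z.items()}
    threshold = max(distances[r] for r in reference_ids)
    ref = set(reference_ids)
    selected = sorted(
        (pid for pid, d in distances.items() if d <= threshold and pid not in ref),
        key=lambda pid: (distances[pid], pid),
    )
    return distances, threshold, selected
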