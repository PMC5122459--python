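"""Light-weight interval utilities on sorted, per-chromosome coordinate arrays.

All coordinates are 0-based half-open ``[start, end)``.  Two layouts are used:

* *covering tracks* — non-overlapping intervals jointly covering a chromosome
  (chromatin-state segmentations); point membership resolves by searchsorted on
  the start array.
* *disjoint interval sets* — merged, sorted, non-overlapping intervals
  (ChIP-seq peaks, centromere/telomere gaps); overlap length with a query
  window is computed from the cumulative-coverage array.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge_intervals",
    "point_in_any",
    "state_at",
    "overlap_bp",
]


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge possibly overlapping intervals into a disjoint set."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    if np.any(ends <= starts):
        raise ValueError("intervals must satisfy start < end")
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1]:
            out_e[-1] = max(out_e[-1], b)
        else:
            out_s.append(a)
            out_e.append(b)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def point_in_any(pos: int, starts: np.ndarray, ends: np.ndarray) -> bool:
    """Half-open membership of a point in a sorted disjoint interval set."""
    if len(starts) == 0:
        return False
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    return i >= 0 and pos < ends[i]


def state_at(pos: int, starts: np.ndarray, ends: np.ndarray, labels) -> str:
    """State label covering ``pos`` in a covering track; raises if uncovered."""
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    if i < 0 or pos >= ends[i]:
        raise ValueError(f"position {pos} not covered by the state track")
    return labels[i]


def overlap_bp(qstart: int, qend: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """Total bp of ``[qstart, qend)`` covered by a sorted disjoint interval set."""
    if qend <= qstart or len(starts) == 0:
        return 0
    clipped_s = np.clip(starts, qstart, qend)
    clipped_e = np.clip(ends, qstart, qend)
    return int(np.sum(np.maximum(0, clipped_e - clipped_s)))
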