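"""Half-open genomic interval helpers shared by layout and annotation.

All internal coordinates are 0-based half-open per chromosome; conversion
to/from 1-based inclusive text formats happens at the io boundary.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or touching [start, end) intervals; returns sorted arrays."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, s.size):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean membership of 0-based positions in merged [start, end) intervals."""
    pos = np.asarray(pos, dtype=np.int64)
    if starts.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    hit = idx >= 0
    hit[hit] = pos[hit] < ends[idx[hit]]
    return hit


def total_span(starts: np.ndarray, ends: np.ndarray) -> int:
    s, e = merge_intervals(starts, ends)
    return int(np.sum(e - s))
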