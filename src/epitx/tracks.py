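"""Per-base read-depth tracks with random access windows.

A :class:`DepthTrack` stores sparse blocks of per-base depth on each
chromosome; positions not covered by any block read as depth 0, including
negative coordinates and positions beyond the last block (windows that
overrun chromosome ends are zero-filled downstream).  Tracks come from two
places: the synthetic generator writes dense per-gene blocks, and
:func:`read_depth_track` loads a 4-column bedGraph (0-based, half-open).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np


@dataclass
class _Block:
    start: int
    values: np.ndarray  # per-base depth, length = block width

    @property
    def end(self) -> int:
        return self.start + len(self.values)


@dataclass
class DepthTrack:
    """Sparse per-base depth with zero default outside covered blocks."""

    _blocks: dict[str, list[_Block]] = field(default_factory=dict)

    def add_block(self, chrom: str, start: int, values: np.ndarray) -> None:
        values = np.asarray(values)
        if np.any(values < 0):
            raise ValueError("depth values must be non-negative")
        blocks = self._blocks.setdefault(chrom, [])
        new = _Block(int(start), values)
        idx = bisect.bisect_left([b.start for b in blocks], new.start)
        # reject overlap with neighbours
        if idx > 0 and blocks[idx - 1].end > new.start:
            raise ValueError(
                f"overlapping blocks on {chrom}: "
                f"[{blocks[idx - 1].start},{blocks[idx - 1].end}) vs "
                f"[{new.start},{new.end})"
            )
        if idx < len(blocks) and new.end > blocks[idx].start:
            raise ValueError(
                f"overlapping blocks on {chrom}: "
                f"[{new.start},{new.end}) vs "
                f"[{blocks[idx].start},{blocks[idx].end})"
            )
        blocks.insert(idx, new)

    def chroms(self) -> list[str]:
        return sorted(self._blocks)

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over [start, end); uncovered positions are 0.

        ``start`` may be negative and ``end`` may exceed the covered span;
        those positions are zero-filled.
        """
        if end <= start:
            raise ValueError(f"empty window [{start}, {end})")
        out = np.zeros(end - start, dtype=np.float64)
        blocks = self._blocks.get(chrom)
        if not blocks:
            return out
        starts = [b.start for b in blocks]
        idx = max(bisect.bisect_right(starts, start) - 1, 0)
        for b in blocks[idx:]:
            if b.start >= end:
                break
            lo = max(b.start, start)
            hi = min(b.end, end)
            if hi > lo:
                out[lo - start : hi - start] = b.values[lo - b.start : hi - b.start]
        return out

    def depth(self, chrom: str, pos: int) -> float:
        return float(self.window(chrom, pos, pos + 1)[0])

    def to_bedgraph(self, path) -> None:
        """Write non-zero runs as 4-column bedGraph (0-based half-open)."""
        with open(path, "w") as fh:
            for chrom in self.chroms():
                for b in self._blocks[chrom]:
                    vals = np.asarray(b.values)
                    if len(vals) == 0:
                        continue
                    change = np.flatnonzero(np.diff(vals)) + 1
                    bounds = np.concatenate(([0], change, [len(vals)]))
                    for lo, hi in zip(bounds[:-1], bounds[1:]):
                        v = vals[lo]
                        if v == 0:
                            continue
                        fh.write(
                            f"{chrom}\t{b.start + lo}\t{b.start + hi}\t{v:g}\n"
                        )


def read_depth_track(path) -> DepthTrack:
    """Load a 4-column bedGraph into a :class:`DepthTrack`.

    Raises on malformed lines (with the line number) and on overlapping
    intervals (listing the first collision).
    """
    records: dict[str, list[tuple[int, int, float, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            try:
                chrom, start, end, value = (
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    float(parts[3]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {line!r}") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative depth {value}")
            records.setdefault(chrom, []).append((start, end, value, lineno))

    track = DepthTrack()
    for chrom, recs in records.items():
        recs.sort(key=lambda r: r[0])
        for (s1, e1, _, l1), (s2, e2, _, l2) in zip(recs, recs[1:]):
            if e1 > s2:
                raise ValueError(
                    f"overlapping intervals on {chrom}: "
                    f"[{s1},{e1}) (line {l1}) and [{s2},{e2}) (line {l2})"
                )
        # merge contiguous records into blocks to keep block count low
        cur_start = None
        cur_vals: list[np.ndarray] = []
        prev_end = None
        for start, end, value, _ in recs:
            if cur_start is None:
                cur_start, prev_end = start, end
                cur_vals = [np.full(end - start, value)]
            elif start == prev_end:
                cur_vals.append(np.full(end - start, value))
                prev_end = end
            else:
                track.add_block(chrom, cur_start, np.concatenate(cur_vals))
                cur_start, prev_end = start, end
                cur_vals = [np.full(end - start, value)]
        if cur_start is not None:
            track.add_block(chrom, cur_start, np.concatenate(cur_vals))
    return track
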