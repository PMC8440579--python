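"""Spot detection, track linking and consensus positions.

Diffraction-limited spots are detected per frame as local maxima of a
scale-normalized Laplacian-of-Gaussian response (blob radius 1.5 px by
default), refined to subpixel precision by a local intensity centroid.
Detections are linked frame-to-frame into rough tracks by greedy
nearest-neighbour assignment (3-px linking distance, gaps up to 10 frames),
tracks within 3 px are combined into consensus spots with a track-length
weighted mean position, and consensus spots outside the cell masks are
discarded.  Downstream analysis uses only the consensus positions.

Coordinates are 0-based (row, col) with pixel centers at integers;
distances are Euclidean in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass(frozen=True)
class SpotDetection:
    frame_index: int
    position: tuple[float, float]  # (row, col), subpixel
    quality: float


@dataclass
class SpotTrack:
    track_id: int
    detections: list[SpotDetection] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.detections)

    @property
    def mean_position(self) -> tuple[float, float]:
        pos = np.array([d.position for d in self.detections])
        r, c = pos.mean(axis=0)
        return (float(r), float(c))


@dataclass
class ConsensusSpot:
    spot_id: int
    position: tuple[float, float]
    total_weight: int
    member_track_ids: list[int]
    cell_id: int | None = None


def detect_spots(
    frame: np.ndarray, radius_px: float = 1.5, threshold: float = 50.0
) -> list[SpotDetection]:
    """Detect diffraction-limited spots in one frame.

    The detector response is the scale-normalized negated LoG,
    ``-sigma^2 * gaussian_laplace(frame, sigma)`` with
    ``sigma = radius_px / sqrt(2)`` (the scale at which a blob of the given
    radius maximizes the response).  Local maxima above ``threshold`` are
    kept, refined by the intensity-weighted centroid of a 3x3 neighbourhood
    of background-offset-corrected intensity, and duplicates within one
    radius are suppressed keeping the higher response.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D image")
    sigma = radius_px / np.sqrt(2.0)
    resp = -(sigma**2) * ndimage.gaussian_laplace(frame, sigma)
    footprint = np.ones((3, 3), bool)
    local_max = (resp == ndimage.maximum_filter(resp, footprint=footprint)) & (resp > threshold)
    rows, cols = np.nonzero(local_max)
    order = np.argsort(-resp[rows, cols], kind="stable")
    detections: list[SpotDetection] = []
    taken: list[tuple[float, float]] = []
    h, w = frame.shape
    for idx in order:
        r, c = int(rows[idx]), int(cols[idx])
        if any((r - tr) ** 2 + (c - tc) ** 2 < radius_px**2 for tr, tc in taken):
            continue
        taken.append((r, c))
        r0, r1 = max(r - 1, 0), min(r + 2, h)
        c0, c1 = max(c - 1, 0), min(c + 2, w)
        patch = frame[r0:r1, c0:c1] - frame[r0:r1, c0:c1].min()
        total = patch.sum()
        if total > 0:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            pr = float((rr * patch).sum() / total)
            pc = float((cc * patch).sum() / total)
        else:
            pr, pc = float(r), float(c)
        detections.append(SpotDetection(frame_index=0, position=(pr, pc), quality=float(resp[r, c])))
    detections.sort(key=lambda d: d.position)
    return detections


def detect_spots_movie(
    movie: np.ndarray, radius_px: float = 1.5, threshold: float = 50.0
) -> list[list[SpotDetection]]:
    """Run :func:`detect_spots` on every frame, stamping frame indices."""
    per_frame = []
    for i, frame in enumerate(movie):
        dets = [
            SpotDetection(frame_index=i, position=d.position, quality=d.quality)
            for d in detect_spots(frame, radius_px, threshold)
        ]
        per_frame.append(dets)
    return per_frame


def link_spots(
    detections_per_frame: list[list[SpotDetection]],
    max_link_px: float = 3.0,
    max_gap_frames: int = 10,
) -> list[SpotTrack]:
    """Link per-frame detections into tracks.

    Greedy nearest-neighbour frame-to-frame assignment: candidate
    (track, detection) pairs within ``max_link_px`` are taken in order of
    ascending distance (ties by lower track id).  A track may bridge up to
    ``max_gap_frames`` consecutive frames with no detection; unmatched
    detections seed new tracks.  Every detection ends up in exactly one
    track.
    """
    tracks: list[SpotTrack] = []
    active: list[SpotTrack] = []
    for frame_idx, dets in enumerate(detections_per_frame):
        active = [
            t
            for t in active
            if frame_idx - t.detections[-1].frame_index - 1 <= max_gap_frames
        ]
        pairs = []
        for ti, t in enumerate(active):
            tr, tc = t.detections[-1].position
            for di, d in enumerate(dets):
                dr, dc = d.position
                dist = np.hypot(tr - dr, tc - dc)
                if dist <= max_link_px:
                    pairs.append((dist, t.track_id, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, _tid, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            active[ti].detections.append(dets[di])
            used_t.add(ti)
            used_d.add(di)
        for di, d in enumerate(dets):
            if di not in used_d:
                t = SpotTrack(track_id=len(tracks), detections=[d])
                tracks.append(t)
                active.append(t)
    return tracks


def merge_tracks(tracks: list[SpotTrack], merge_radius_px: float = 3.0) -> list[ConsensusSpot]:
    """Combine tracks within ``merge_radius_px`` into consensus spots.

    Single-pass single-linkage grouping of track mean positions; the
    consensus position is the track-length-weighted mean of member mean
    positions.  Processing order is deterministic by (row, col) of the
    track mean, so the partition is reproducible; it is exhaustive and
    disjoint.
    """
    if not tracks:
        return []
    means = np.array([t.mean_position for t in tracks])
    order = np.lexsort((means[:, 1], means[:, 0]))
    parent = list(range(len(tracks)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a_idx in range(len(order)):
        for b_idx in range(a_idx + 1, len(order)):
            i, j = order[a_idx], order[b_idx]
            if means[j, 0] - means[i, 0] > merge_radius_px:
                break
            if np.hypot(*(means[i] - means[j])) <= merge_radius_px:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(tracks)):
        groups.setdefault(find(i), []).append(i)
    consensus = []
    for members in groups.values():
        weights = np.array([tracks[i].length for i in members], dtype=float)
        pos = (means[members] * weights[:, None]).sum(axis=0) / weights.sum()
        consensus.append(
            ConsensusSpot(
                spot_id=0,
                position=(float(pos[0]), float(pos[1])),
                total_weight=int(weights.sum()),
                member_track_ids=sorted(tracks[i].track_id for i in members),
            )
        )
    consensus.sort(key=lambda s: s.position)
    for sid, s in enumerate(consensus):
        s.spot_id = sid
    return consensus


def filter_by_mask(spots: list[ConsensusSpot], mask: np.ndarray) -> list[ConsensusSpot]:
    """Keep spots whose rounded position lies on a nonzero mask label.

    Each kept spot is annotated with its cell label; boundary pixels count
    as inside (nonzero-label rule).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    kept = []
    for s in spots:
        r = int(round(s.position[0]))
        c = int(round(s.position[1]))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
            continue
        label = int(mask[r, c])
        if label > 0:
            kept.append(
                ConsensusSpot(
                    spot_id=s.spot_id,
                    position=s.position,
                    total_weight=s.total_weight,
                    member_track_ids=s.member_track_ids,
                    cell_id=label,
                )
            )
    return kept


def spots_to_frame(spots: list[ConsensusSpot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spot_id": s.spot_id,
                "cell_id": s.cell_id if s.cell_id is not None else 0,
                "row": s.position[0],
                "col": s.position[1],
                "total_weight": s.total_weight,
            }
            for s in spots
        ],
        columns=["spot_id", "cell_id", "row", "col", "total_weight"],
    )


def tracks_to_frame(tracks: list[SpotTrack]) -> pd.DataFrame:
    rows = [
        {"track_id": t.track_id, "frame": d.frame_index, "row": d.position[0], "col": d.position[1]}
        for t in tracks
        for d in t.detections
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "row", "col"])
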