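"""Linking per-slice root sections into individual-root tracks.

Scanning downward, each root's cross-section drifts smoothly in the image
plane; tracking is classic multi-object tracking with a constant-acceleration
Kalman filter per track (state x, y, vx, vy, ax, ay; the measurement is the
detection centroid) and globally optimal Hungarian assignment of predictions
to detections, gated by a maximum matching distance.  Unmatched detections
spawn tracks; a track missing for more than ``max_skip`` consecutive slices
terminates.  Identity through crossings comes from the velocity/acceleration
terms: two sections swapping positions are resolved by their predicted
motion, not proximity alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cross_section import CrossSectionComponent

# constant-acceleration transition, dt = 1 slice
_F = np.array([
    [1, 0, 1, 0, 0.5, 0],
    [0, 1, 0, 1, 0, 0.5],
    [0, 0, 1, 0, 1, 0],
    [0, 0, 0, 1, 0, 1],
    [0, 0, 0, 0, 1, 0],
    [0, 0, 0, 0, 0, 1],
], dtype=float)
_H = np.zeros((2, 6))
_H[0, 0] = _H[1, 1] = 1.0


@dataclass
class TrackingParams:
    process_noise: float = 0.1       # q, px^2
    measurement_noise: float = 1.0   # r, px^2
    initial_covariance: float = 10.0
    gate: float = 20.0               # px
    max_skip: int = 4                # slices
    min_track_length: int = 5        # detections required for acceptance
    occlusion_limit: int = 40        # max slices a track may coast inside fg


@dataclass
class KalmanState:
    """Constant-acceleration state (x, y, vx, vy, ax, ay) with covariance."""

    state: np.ndarray
    covariance: np.ndarray

    @classmethod
    def from_measurement(cls, xy, params: TrackingParams) -> "KalmanState":
        state = np.zeros(6)
        state[:2] = xy
        return cls(state=state, covariance=params.initial_covariance * np.eye(6))

    def predict(self, q: float) -> tuple[np.ndarray, np.ndarray]:
        state = _F @ self.state
        cov = _F @ self.covariance @ _F.T + q * np.eye(6)
        return state, cov

    def advance(self, q: float) -> None:
        self.state, self.covariance = self.predict(q)

    def update(self, xy, r: float) -> None:
        z = np.asarray(xy, dtype=float)
        y = z - _H @ self.state
        S = _H @ self.covariance @ _H.T + r * np.eye(2)
        K = self.covariance @ _H.T @ np.linalg.inv(S)
        self.state = self.state + K @ y
        self.covariance = (np.eye(6) - K @ _H) @ self.covariance


@dataclass
class RootTrack:
    """Depth-ordered detections of one individual root."""

    track_id: int
    detections: list[tuple[int, CrossSectionComponent]] = field(default_factory=list)
    kalman: KalmanState | None = None
    skipped: int = 0
    occluded: int = 0
    status: str = "active"

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def slice_indices(self) -> np.ndarray:
        return np.array([s for s, _ in self.detections])

    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for _, c in self.detections])

    def polyline_mm(self, pixel_mm: float, thickness: float,
                    origin=(0.0, 0.0), depth0: float = 0.0) -> np.ndarray:
        """3D polyline (x, y, depth) in mm through the detection centroids."""
        xy = self.centroids()
        out = np.empty((len(xy), 3))
        out[:, 0] = origin[0] + (xy[:, 0] + 0.5) * pixel_mm
        out[:, 1] = origin[1] + (xy[:, 1] + 0.5) * pixel_mm
        out[:, 2] = depth0 + self.slice_indices * thickness
        return out


def kalman_predict(track: RootTrack,
                   params: TrackingParams | None = None) -> tuple[float, float]:
    """One-step-ahead predicted centroid of a track (F applied to its state)."""
    if track.kalman is None or len(track) < 1:
        raise ValueError("track needs at least one detection")
    q = (params or TrackingParams()).process_noise
    state, _ = track.kalman.predict(q)
    return float(state[0]), float(state[1])


def associate(predictions: np.ndarray, detections: np.ndarray,
              gate: float) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Gated Hungarian assignment of predictions to detections.

    Returns (matches, unmatched_prediction_indices, unmatched_detection
    indices).  The cost matrix is Euclidean distance, padded to square with
    the gate cost so rows/columns can stay unmatched; any matched pair with
    cost above the gate is severed.
    """
    if gate <= 0:
        raise ValueError("gate must be positive")
    P, D = len(predictions), len(detections)
    if P == 0 or D == 0:
        return [], list(range(P)), list(range(D))
    pred = np.asarray(predictions, float).reshape(P, 2)
    det = np.asarray(detections, float).reshape(D, 2)
    cost = np.linalg.norm(pred[:, None, :] - det[None, :, :], axis=2)
    size = max(P, D)
    padded = np.full((size, size), float(gate))
    padded[:P, :D] = cost
    rows, cols = linear_sum_assignment(padded)
    matches = []
    unmatched_p = set(range(P))
    unmatched_d = set(range(D))
    for r, c in zip(rows, cols):
        if r < P and c < D and cost[r, c] <= gate:
            matches.append((int(r), int(c)))
            unmatched_p.discard(r)
            unmatched_d.discard(c)
    return matches, sorted(unmatched_p), sorted(unmatched_d)


def _inside_component(comp: CrossSectionComponent, xy) -> bool:
    r0, c0, r1, c1 = comp.bbox
    col, row = int(round(xy[0])), int(round(xy[1]))
    if not (r0 <= row < r1 and c0 <= col < c1):
        return False
    return bool(comp.mask[row - r0, col - c0])


def tracks_to_jsonl(tracks: list[RootTrack], path) -> None:
    """Dump tracks as JSON lines: one record per detection."""
    import json

    with open(path, "w") as fh:
        for t in tracks:
            for s, c in t.detections:
                fh.write(json.dumps({
                    "track_id": t.track_id, "slice": int(s),
                    "x": round(c.centroid[0], 3), "y": round(c.centroid[1], 3),
                    "area": c.area, "diameter": round(c.diameter, 4)}) + "\n")


def track_stack(slices: list[list[CrossSectionComponent]],
                params: TrackingParams | None = None) -> list[RootTrack]:
    """Track components through an ordered slice sequence.

    Every component joins at most one track; unmatched detections spawn new
    tracks; tracks unmatched for more than ``max_skip`` slices terminate.

    Entangled roots need two extra rules.  When an established track goes
    unmatched while its prediction lies inside a matched detection, that
    detection is a merged multi-root blob: no track absorbs its centroid,
    all involved tracks coast on their own dynamics, and the blob spawns
    nothing; at separation each track reacquires its own lane.  And a
    track whose prediction lies inside some component's support is
    occluded rather than lost, so it keeps coasting (up to
    ``occlusion_limit`` slices) without aging toward termination.

    Tracks shorter than ``min_track_length`` are flagged ``status="short"``
    so the structure stage can attempt back-track attachment.
    """
    if len(slices) < 1:
        raise ValueError("need at least one slice")
    params = params or TrackingParams()
    tracks: list[RootTrack] = []
    active: list[RootTrack] = []
    next_id = 0
    for slice_index, comps in enumerate(slices):
        preds = np.array([kalman_predict(t, params) for t in active]).reshape(-1, 2)
        dets = np.array([c.centroid for c in comps]).reshape(-1, 2)
        matches, unmatched_t, unmatched_d = associate(preds, dets, params.gate)
        for t in active:
            t.kalman.advance(params.process_noise)
        # shared-blob detection: if an established track went unmatched and
        # its prediction lies inside some matched detection, that detection
        # is an entangled multi-root blob -- neither track may absorb its
        # centroid, both coast on their own dynamics until separation
        shared: set[int] = set()
        for ti in unmatched_t:
            if len(active[ti].detections) < 10:
                continue
            for di, comp in enumerate(comps):
                if _inside_component(comp, preds[ti]):
                    shared.add(di)
        coasting: list[tuple[RootTrack, tuple[float, float]]] = []
        for ti, di in matches:
            t = active[ti]
            comp = comps[di]
            if di in shared and len(t.detections) >= 10:
                coasting.append((t, preds[ti]))
                continue
            t.kalman.update(comp.centroid, params.measurement_noise)
            t.detections.append((slice_index, comp))
            t.skipped = 0
            t.occluded = 0
        for ti in unmatched_t:
            coasting.append((active[ti], preds[ti]))
        for t, pred in coasting:
            covered = any(_inside_component(c, pred) for c in comps)
            if covered and t.occluded < params.occlusion_limit:
                t.occluded += 1
            else:
                t.skipped += 1
        for di in unmatched_d:
            if di in shared:
                continue  # merged blob: belongs to the coasting tracks
            t = RootTrack(track_id=next_id,
                          kalman=KalmanState.from_measurement(comps[di].centroid, params))
            t.detections.append((slice_index, comps[di]))
            tracks.append(t)
            active.append(t)
            next_id += 1
        still_active = []
        for t in active:
            if t.skipped > params.max_skip:
                t.status = "terminated"
            else:
                still_active.append(t)
        active = still_active
    for t in tracks:
        if t.status == "active":
            t.status = "terminated"
        if len(t) < params.min_track_length:
            t.status = "short"
    return tracks


def accepted_tracks(tracks: list[RootTrack],
                    params: TrackingParams | None = None) -> list[RootTrack]:
    params = params or TrackingParams()
    return [t for t in tracks if len(t) >= params.min_track_length]
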