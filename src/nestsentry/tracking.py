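"""Naive position-gated tracking with a 2-of-3 temporal constraint.

A detection joins an existing track when it lies within a box gate
(|dx| <= max_dx and |dy| <= max_dy) of the track's last position,
otherwise it starts a new track.  A track is confirmed as a nest once it
scores hits in two out of three consecutive frames; single-frame
detections at random positions therefore never confirm.  Tracks die after
three consecutive misses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fusion import Detection

__all__ = ["TrackerConfig", "Track", "Tracker", "associate", "advance_frame", "confirm"]


@dataclass(frozen=True)
class TrackerConfig:
    max_dx: float = 20.0
    max_dy: float = 20.0
    window: int = 3        # temporal window length
    required_hits: int = 2  # hits within the window needed to confirm
    max_misses: int = 3     # consecutive misses before retirement

    def __post_init__(self) -> None:
        if self.max_dx <= 0 or self.max_dy <= 0:
            raise ValueError("gate thresholds must be positive")


@dataclass
class Track:
    track_id: int
    last_position: tuple[float, float]
    created_frame: int
    history: list[bool] = field(default_factory=list)  # last `window` frames
    confirmed: bool = False
    retired: bool = False
    _hit_pending: bool = field(default=False, repr=False)
    positions: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def consecutive_misses(self) -> int:
        n = 0
        for h in reversed(self.history):
            if h:
                break
            n += 1
        return n


def associate(det: Detection, tracks: list[Track], cfg: TrackerConfig) -> int:
    """Assign a detection to a live track, or open a new one.

    ``tracks`` is the full track list (retired tracks are skipped but keep
    their ids reserved).  Eligible tracks are those whose last position
    lies within the box gate of the detection; among them the one at the
    smallest Chebyshev distance wins, ties going to the smaller track id.
    Returns the id of the matched or newly created track and marks the
    hit.
    """
    best: Track | None = None
    best_d = None
    for t in tracks:
        if t.retired or t._hit_pending:
            continue
        dx = abs(det.x - t.last_position[0])
        dy = abs(det.y - t.last_position[1])
        if dx <= cfg.max_dx and dy <= cfg.max_dy:
            d = max(dx, dy)
            if best is None or d < best_d or (d == best_d and t.track_id < best.track_id):
                best, best_d = t, d
    if best is None:
        new_id = max((t.track_id for t in tracks), default=-1) + 1
        best = Track(new_id, (det.x, det.y), det.frame_index)
        tracks.append(best)
    best.last_position = (det.x, det.y)
    best._hit_pending = True
    best.positions.append((det.frame_index, det.x, det.y))
    return best.track_id


def advance_frame(tracks: list[Track], cfg: TrackerConfig) -> list[Track]:
    """Close out one frame: commit hits/misses, confirm, retire.

    Every live track records a hit if it matched a detection this frame,
    else a miss; the hit/miss window is capped at ``cfg.window`` frames,
    and tracks reaching ``cfg.max_misses`` consecutive misses retire.
    Returns the still-live tracks.
    """
    live: list[Track] = []
    for t in tracks:
        if t.retired:
            continue
        t.history.append(t._hit_pending)
        t._hit_pending = False
        if len(t.history) > cfg.window:
            del t.history[0]
        if confirm(t, cfg):
            t.confirmed = True  # sticky
        if t.consecutive_misses >= cfg.max_misses:
            t.retired = True
        else:
            live.append(t)
    return live


def confirm(track: Track, cfg: TrackerConfig | None = None) -> bool:
    """2-of-3 rule: enough hits in the current window, or already confirmed."""
    cfg = cfg or TrackerConfig()
    if track.confirmed:
        return True
    return sum(track.history[-cfg.window:]) >= cfg.required_hits


class Tracker:
    """Per-frame driver keeping live and retired tracks.

    Call :meth:`observe` once per frame (detection may be None).  The
    confirmed detection stream — positions of confirmed tracks in the
    frames where they scored hits — accumulates in :attr:`confirmed_log`.
    """

    def __init__(self, cfg: TrackerConfig | None = None):
        self.cfg = cfg or TrackerConfig()
        self.all_tracks: list[Track] = []  # every track ever, retired included
        self.confirmed_log: list[tuple[int, int, float, float]] = []

    def observe(self, det: Detection | None, frame_index: int) -> None:
        matched_id = None
        if det is not None:
            matched_id = associate(det, self.all_tracks, self.cfg)
        advance_frame(self.all_tracks, self.cfg)
        if matched_id is not None:
            track = next(t for t in self.all_tracks if t.track_id == matched_id)
            if track.confirmed:
                self.confirmed_log.append((frame_index, matched_id, det.x, det.y))

    @property
    def tracks(self) -> list[Track]:
        """Live (non-retired) tracks."""
        return [t for t in self.all_tracks if not t.retired]

    @property
    def confirmed_tracks(self) -> list[Track]:
        return [t for t in self.all_tracks if t.confirmed]
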