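"""Frame-to-frame linking and immobile/mobile particle classification.

Localizations are linked by optimal nearest-neighbour assignment within a
per-frame displacement cap with gap closing; tracks are then classified as
immobile when their positional spread stays within a small multiple of the
localization precision for long enough, or mobile when above-noise steps
persist for the minimum mobile time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

__all__ = ["link_tracks", "MobilityClassifier", "classify_mobility"]


def link_tracks(
    locs: pd.DataFrame,
    max_disp_px: float = 3.0,
    max_gap_frames: int = 1,
) -> pd.DataFrame:
    """Link localizations into tracks by per-frame optimal assignment.

    Detections in consecutive frames are matched to open track ends by
    minimum-cost assignment, with matches farther than ``max_disp_px``
    forbidden; a track end left unmatched for more than ``max_gap_frames``
    frames is closed, and unmatched detections start new tracks.

    Returns a copy of ``locs`` with a ``track_id`` column, sorted by
    (track_id, frame).
    """
    if len(locs) == 0:
        out = locs.copy()
        out["track_id"] = pd.Series(dtype=int)
        return out
    df = locs.sort_values("frame", kind="stable").reset_index(drop=True)
    track_id = np.full(len(df), -1, dtype=int)
    next_id = 0
    # open tracks: id -> (last_x, last_y, last_frame)
    open_tracks: dict[int, tuple[float, float, int]] = {}
    big = 1e12
    for frame, idx in df.groupby("frame").groups.items():
        idx = np.asarray(idx)
        pts = df.loc[idx, ["x_px", "y_px"]].to_numpy(dtype=float)
        # close stale tracks
        open_tracks = {
            tid: st
            for tid, st in open_tracks.items()
            if frame - st[2] <= max_gap_frames + 1
        }
        tids = sorted(open_tracks)
        assigned = np.full(len(idx), -1, dtype=int)
        if tids:
            last = np.array([[open_tracks[t][0], open_tracks[t][1]] for t in tids])
            cost = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
            cost = np.where(cost <= max_disp_px, cost, big)
            ri, ci = linear_sum_assignment(cost)
            for r, c in zip(ri, ci):
                if cost[r, c] < big:
                    assigned[c] = tids[r]
        for j, tid in enumerate(assigned):
            if tid < 0:
                tid = next_id
                next_id += 1
            track_id[idx[j]] = tid
            open_tracks[tid] = (pts[j, 0], pts[j, 1], int(frame))
    df["track_id"] = track_id
    return df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)


class MobilityClassifier(BaseEstimator):
    """Immobile vs mobile classification of linked tracks.

    A track is *immobile* when it lasts at least ``min_immobile_frames`` and
    its root-mean-square radial deviation from its centroid stays within
    ``spread_multiple`` times the localization precision ("the same
    localization over time"); it is *mobile* when above-noise steps persist
    over at least ``min_mobile_frames`` consecutive frames; anything else is
    unclassified and excluded from the reported percentages.

    Parameters
    ----------
    precision_px : float
        Per-axis localization precision in pixels.
    spread_multiple : float
        Multiple of the precision bounding an immobile track's spread.
    min_immobile_frames, min_mobile_frames : int
        Minimum immobile time (default 10 frames) and mobile time (default 5).
    first_n_frames : int or None
        When set, only localizations with frame index below this are used
        (e.g. 100 to analyse the first 100 frames).
    """

    def __init__(
        self,
        precision_px: float = 0.25,
        spread_multiple: float = 2.0,
        min_immobile_frames: int = 10,
        min_mobile_frames: int = 5,
        first_n_frames: int | None = None,
    ):
        self.precision_px = precision_px
        self.spread_multiple = spread_multiple
        self.min_immobile_frames = min_immobile_frames
        self.min_mobile_frames = min_mobile_frames
        self.first_n_frames = first_n_frames

    def _classify_one(self, g: pd.DataFrame) -> str:
        if self.precision_px <= 0:
            raise ValueError("precision_px must be > 0")
        frames = g["frame"].to_numpy()
        x = g["x_px"].to_numpy(dtype=float)
        y = g["y_px"].to_numpy(dtype=float)
        duration = int(frames[-1] - frames[0] + 1)
        bound = self.spread_multiple * self.precision_px
        spread = float(np.sqrt(np.mean((x - x.mean()) ** 2 + (y - y.mean()) ** 2)))
        if duration >= self.min_immobile_frames and spread <= bound:
            return "immobile"
        steps = np.hypot(np.diff(x), np.diff(y))
        moving = steps > bound
        # longest run of consecutive above-noise steps, in frames spanned
        best = run = 0
        for m in moving:
            run = run + 1 if m else 0
            best = max(best, run)
        if best + 1 >= self.min_mobile_frames:
            return "mobile"
        return "unclassified"

    def predict(self, tracks: pd.DataFrame) -> pd.DataFrame:
        """Per-track mobility labels; returns (track_id, n_frames, mobility)."""
        df = tracks
        if self.first_n_frames is not None:
            df = df[df["frame"] < self.first_n_frames]
        rows = []
        for tid, g in df.sort_values("frame", kind="stable").groupby("track_id"):
            rows.append(
                {
                    "track_id": tid,
                    "n_frames": len(g),
                    "mobility": self._classify_one(g),
                }
            )
        return pd.DataFrame(rows, columns=["track_id", "n_frames", "mobility"])

    def fit(self, tracks: pd.DataFrame, y=None) -> "MobilityClassifier":
        """Classify and store summary percentages (``percent_immobile_`` etc.)."""
        labels = self.predict(tracks)
        classified = labels[labels["mobility"] != "unclassified"]
        if len(classified) == 0:
            raise ValueError("no classifiable tracks")
        n_imm = int((classified["mobility"] == "immobile").sum())
        n_mob = int((classified["mobility"] == "mobile").sum())
        self.labels_ = labels
        self.n_classified_ = len(classified)
        self.n_unclassified_ = int(len(labels) - len(classified))
        self.percent_immobile_ = 100.0 * n_imm / len(classified)
        self.percent_mobile_ = 100.0 * n_mob / len(classified)
        return self


def classify_mobility(
    tracks: pd.DataFrame,
    precision_px: float = 0.25,
    **params,
) -> dict:
    """Percentages of immobile vs mobile particles over classified tracks."""
    clf = MobilityClassifier(precision_px=precision_px, **params).fit(tracks)
    return {
        "percent_immobile": clf.percent_immobile_,
        "percent_mobile": clf.percent_mobile_,
        "n_classified": clf.n_classified_,
        "n_unclassified": clf.n_unclassified_,
    }
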