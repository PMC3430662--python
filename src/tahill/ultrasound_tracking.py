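"""Landmark tracking in B-mode ultrasound sequences and fascicle geometry.

The muscle-tendon junction and the endpoints of the superficial aponeurosis,
deep aponeurosis and muscle fascicles are tracked frame to frame by template
matching: the template around the current landmark is compared against every
integer-pixel displacement within a search window of the next frame using
normalized cross-correlation (NCC), and the best-scoring displacement becomes
the landmark's new position.  Because the whole fascicle rarely fits in the
imaging window, each aponeurosis is modelled as the line through its tracked
endpoints and the fascicle line is extended to its intersections with the two
aponeuroses; the distance between the intersections is the fascicle length and
the angle to the deep aponeurosis is the pennation angle.

Image convention: origin top-left, 0-based (row, col) indexing, intensities in
[0, 1].  Fascicle curvature is neglected.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateTemplateError, GeometryError, TrackLostError

__all__ = ["LandmarkName", "FrameSequence", "LandmarkTrack",
           "FascicleGeometry", "track_template_ncc", "fascicle_geometry",
           "tendon_length_from_landmarks"]

#: score assigned to zero-variance windows so they can never win
_INVALID_SCORE = -2.0
#: two NCC scores within this of each other count as tied
_TIE_TOL = 1e-12


class LandmarkName(str, Enum):
    MTJ = "MTJ"
    SUP_APO_PROX = "sup_apo_prox"
    SUP_APO_DIST = "sup_apo_dist"
    DEEP_APO_PROX = "deep_apo_prox"
    DEEP_APO_DIST = "deep_apo_dist"
    FASC_PROX = "fasc_prox"
    FASC_DIST = "fasc_dist"


@dataclass
class FrameSequence:
    """Grayscale ultrasound frame stack with its spatial/temporal scales."""

    frames: list            # 2-D float arrays, intensities in [0, 1]
    frame_rate: float = 30.0   # Hz
    mm_per_pixel: float = 0.1

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be > 0")
        shapes = {np.asarray(f).shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"all frames must share one shape, got {shapes}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self):
        return np.asarray(self.frames[0]).shape


@dataclass
class LandmarkTrack:
    """Per-frame integer pixel positions of one landmark with NCC confidence."""

    name: LandmarkName | str
    positions: np.ndarray   # (n_frames, 2) int (row, col)
    confidence: np.ndarray  # (n_frames,) peak NCC in [-1, 1]


@dataclass
class FascicleGeometry:
    """Per-frame fascicle length (mm) and pennation angle (rad)."""

    fascicle_length: np.ndarray
    pennation: np.ndarray


def _ncc_scores(template: np.ndarray, region: np.ndarray) -> np.ndarray:
    """NCC of ``template`` against every same-size window of ``region``.

    Zero-variance windows score ``_INVALID_SCORE``; a zero-variance template
    raises.
    """
    t = template.astype(float)
    tz = t - t.mean()
    tnorm = np.sqrt((tz**2).sum())
    if tnorm == 0.0:
        raise DegenerateTemplateError("template has zero intensity variance")
    windows = sliding_window_view(region.astype(float), t.shape)
    wmean = windows.mean(axis=(-2, -1), keepdims=True)
    wz = windows - wmean
    wnorm = np.sqrt((wz**2).sum(axis=(-2, -1)))
    num = (wz * tz).sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = num / (tnorm * wnorm)
    scores[wnorm == 0.0] = _INVALID_SCORE
    return scores


def _best_displacement(scores: np.ndarray, half: int) -> tuple[int, int, float]:
    """Argmax with deterministic tie-breaking: smallest displacement
    magnitude first, then row-major (dr, dc) order."""
    best = scores.max()
    cand = np.argwhere(scores >= best - _TIE_TOL)
    disp = cand - half
    order = np.lexsort((disp[:, 1], disp[:, 0], (disp**2).sum(axis=1)))
    dr, dc = disp[order[0]]
    return int(dr), int(dc), float(scores[dr + half, dc + half])


def track_template_ncc(seq: FrameSequence, initial_position,
                       template_half_size: int = 5,
                       search_half_size: int = 10,
                       name: LandmarkName | str = LandmarkName.MTJ,
                       refresh_template: bool = True) -> LandmarkTrack:
    """Track a landmark through a frame sequence by NCC template matching.

    Parameters
    ----------
    initial_position : (row, col)
        Integer pixel position of the landmark in frame 0.
    template_half_size, search_half_size : int
        The template is ``(2h+1) x (2h+1)`` pixels; candidate displacements
        span ``[-s, s]`` pixels in each axis.
    refresh_template : bool
        Re-extract the template from each newly matched frame (default, the
        frame-to-frame scheme); ``False`` keeps the frame-0 template.

    Raises
    ------
    TrackLostError
        When a template or search window would leave the image; carries the
        last frame index with a valid position.
    DegenerateTemplateError
        When the template window has zero variance.
    """
    h, s = int(template_half_size), int(search_half_size)
    if h < 1 or s < 1:
        raise ValueError("template and search half-sizes must be >= 1")
    nrows, ncols = seq.shape
    r, c = (int(round(x)) for x in initial_position)
    if not (h <= r < nrows - h and h <= c < ncols - h):
        raise TrackLostError("initial template window leaves the image",
                             last_valid_frame=-1)
    positions = [(r, c)]
    confidence = [1.0]
    frames = [np.asarray(f, dtype=float) for f in seq.frames]
    template = frames[0][r - h:r + h + 1, c - h:c + h + 1]
    for i in range(1, len(frames)):
        lo_r, hi_r = r - h - s, r + h + s + 1
        lo_c, hi_c = c - h - s, c + h + s + 1
        if lo_r < 0 or lo_c < 0 or hi_r > nrows or hi_c > ncols:
            raise TrackLostError(
                f"search window leaves the image at frame {i}",
                last_valid_frame=i - 1)
        region = frames[i][lo_r:hi_r, lo_c:hi_c]
        scores = _ncc_scores(template, region)
        dr, dc, conf = _best_displacement(scores, s)
        r, c = r + dr, c + dc
        positions.append((r, c))
        confidence.append(conf)
        if refresh_template:
            template = frames[i][r - h:r + h + 1, c - h:c + h + 1]
    return LandmarkTrack(name=name, positions=np.asarray(positions, dtype=int),
                         confidence=np.asarray(confidence, dtype=float))


def _line_intersection(p1, d1, p2, d2, frame: int):
    """Intersection of lines p1 + t*d1 and p2 + u*d2 (2-D)."""
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    scale = max(np.linalg.norm(d1) * np.linalg.norm(d2), 1e-30)
    if abs(cross) < 1e-12 * scale:
        raise GeometryError(f"parallel lines (no intersection) at frame {frame}")
    dp = p2 - p1
    t = (dp[0] * d2[1] - dp[1] * d2[0]) / cross
    return p1 + t * d1


def _angle_between(d1, d2) -> float:
    """Acute angle between two line directions, in [0, pi/2)."""
    cosang = abs(float(np.dot(d1, d2))) / (np.linalg.norm(d1) * np.linalg.norm(d2))
    return float(np.arccos(np.clip(cosang, 0.0, 1.0)))


def fascicle_geometry(tracks: dict, mm_per_pixel: float) -> FascicleGeometry:
    """Fascicle length and pennation from aponeurosis and fascicle tracks.

    ``tracks`` maps landmark names (:class:`LandmarkName` or strings) to
    :class:`LandmarkTrack`; the four aponeurosis endpoints plus one or two
    fascicles (``fasc_prox``/``fasc_dist`` and optionally ``fasc2_prox``/
    ``fasc2_dist``) must be present and time-aligned.  Each aponeurosis is the
    line through its endpoints; the fascicle line is extended to both
    aponeuroses and measured between the intersections.  With two fascicles
    the per-frame values are averaged.
    """
    def pos(key):
        k = key if key in tracks else LandmarkName(key)
        return np.asarray(tracks[k].positions, dtype=float)

    sup_p, sup_d = pos("sup_apo_prox"), pos("sup_apo_dist")
    deep_p, deep_d = pos("deep_apo_prox"), pos("deep_apo_dist")
    fascicle_sets = [("fasc_prox", "fasc_dist")]
    key_names = {getattr(k, "value", k) for k in tracks}
    if {"fasc2_prox", "fasc2_dist"} <= key_names:
        fascicle_sets.append(("fasc2_prox", "fasc2_dist"))
    n = sup_p.shape[0]
    for arr in (sup_d, deep_p, deep_d):
        if arr.shape[0] != n:
            raise ValueError("tracks are not time-aligned")

    lengths = np.zeros(n)
    angles = np.zeros(n)
    for fp_key, fd_key in fascicle_sets:
        fp, fd = pos(fp_key), pos(fd_key)
        for i in range(n):
            d_sup = sup_d[i] - sup_p[i]
            d_deep = deep_d[i] - deep_p[i]
            d_fas = fd[i] - fp[i]
            p_sup = _line_intersection(fp[i], d_fas, sup_p[i], d_sup, i)
            p_deep = _line_intersection(fp[i], d_fas, deep_p[i], d_deep, i)
            lengths[i] += np.linalg.norm(p_sup - p_deep) * mm_per_pixel
            angles[i] += _angle_between(d_fas, d_deep)
    k = len(fascicle_sets)
    return FascicleGeometry(fascicle_length=lengths / k, pennation=angles / k)


def tendon_length_from_landmarks(mtj_position, insertion_marker) -> np.ndarray:
    """Tendon length per frame: Euclidean distance between the tracked MTJ and
    the tendon-insertion marker, both in global mm coordinates."""
    mtj = np.atleast_2d(np.asarray(mtj_position, dtype=float))
    ins = np.atleast_2d(np.asarray(insertion_marker, dtype=float))
    if mtj.shape != ins.shape:
        raise ValueError("landmark series must be time-aligned")
    d = np.linalg.norm(mtj - ins, axis=-1)
    if np.any(d <= 0):
        i = int(np.nonzero(d <= 0)[0][0])
        raise GeometryError(f"coincident landmarks at frame {i}")
    return d
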