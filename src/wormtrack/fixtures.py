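"""Seeded synthetic dish sequences with ground-truth skeletons.

Emulates the tracker's imaging conditions at fixture scale: dark worms
(all body pixels below gray 35, tail lighter than head) on a bright dish
interior (above 48) surrounded by a dark border, captured at 1 Hz for 30
frames.  Worms are smooth undulating tubes 20-60 px long and 3-5 px
wide; scenarios script contact events — end contact, partial overlap,
parallel bodies, crossing — into the middle of the sequence so that the
first and last frames always show every worm separated.

Everything is a deterministic function of the scenario seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FixtureError
from .segmentation import GraySequence
from .skeleton import SkeletonPath, path_from_points

EVENTS = ("none", "end_contact", "partial_overlap", "parallel_bodies", "cross")

DISH_BACKGROUND = 120  # gray level of the dish interior (> 48)
OUTSIDE_LEVEL = 15     # gray level outside the dish rim


@dataclass
class WormSpec:
    """One worm's rendering parameters for a single frame."""

    control_points: np.ndarray   # (m, 2) float (row, col) along the midline
    width_profile: np.ndarray    # half-width (px) at each control point
    head_intensity: int
    tail_intensity: int
    length: float                # midline arclength, px

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, float)
        self.width_profile = np.asarray(self.width_profile, float)
        if not (self.head_intensity < self.tail_intensity < 35):
            raise FixtureError("need head_intensity < tail_intensity < 35")
        if self.length <= 0 or (self.width_profile <= 0).any():
            raise FixtureError("length and widths must be positive")


@dataclass
class NoiseBlob:
    """Static dark plate artifact (opaque waste)."""

    center: tuple[float, float]
    radius: float = 4.5
    intensity: int = 26


@dataclass
class ScenarioSpec:
    n_worms: int
    n_frames: int = 30
    dish_radius: float = 90.0
    noise_blobs: tuple[NoiseBlob, ...] = ()
    event: str = "none"
    seed: int = 0
    margin: int = 10

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise FixtureError("n_frames must be >= 2")
        if self.event not in EVENTS:
            raise FixtureError(f"unknown event {self.event!r}")
        if self.event != "none" and self.n_worms < 2:
            raise FixtureError("contact events need >= 2 worms")

    @property
    def canvas(self) -> int:
        return int(2 * self.dish_radius + 2 * self.margin)

    @property
    def center(self) -> float:
        return self.canvas / 2.0


@dataclass
class _WormTrajectory:
    """Analytic midline generator: straight axis + travelling sine wave."""

    pos0: np.ndarray          # body center at t=0 (row, col)
    velocity: np.ndarray      # px / frame
    heading: float            # axis angle, radians (0 = +col)
    length: float
    half_width: float
    amplitude: float
    wavelength: float
    phase0: float
    phase_speed: float
    head_intensity: int
    tail_intensity: int
    wobble: float = 0.05
    wobble_freq: float = 0.35
    wobble_phase: float = 0.0
    # optional override for the body-center path (used by event scripts)
    center_fn: object = None

    def centerline(self, t: int, ds: float = 0.25) -> np.ndarray:
        """Dense (m, 2) midline samples at frame t, tail -> head order."""
        if self.center_fn is not None:
            pos = np.asarray(self.center_fn(t), float)
        else:
            pos = self.pos0 + self.velocity * t
        theta = self.heading + self.wobble * np.sin(
            self.wobble_freq * t + self.wobble_phase)
        u = np.array([np.sin(theta), np.cos(theta)])   # axis (row, col)
        nvec = np.array([-u[1], u[0]])
        s = np.arange(-self.length / 2, self.length / 2 + ds, ds)
        sway = self.amplitude * np.sin(
            2 * np.pi * s / self.wavelength + self.phase0 + self.phase_speed * t)
        return pos + np.outer(s, u) + np.outer(sway, nvec)

    def spec(self, t: int) -> WormSpec:
        pts = self.centerline(t)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        frac = np.linspace(0, 1, len(pts))
        taper = np.clip(np.minimum(frac, 1 - frac) / 0.15, 0.45, 1.0)
        return WormSpec(pts, self.half_width * taper,
                        self.head_intensity, self.tail_intensity, float(seg))


def _base_worm(rng: np.random.Generator, **overrides) -> dict:
    head = int(rng.integers(12, 19))
    params = dict(
        length=float(rng.uniform(38, 50)),
        half_width=float(rng.uniform(1.6, 2.3)),
        amplitude=float(rng.uniform(1.5, 2.5)),
        phase0=float(rng.uniform(0, 2 * np.pi)),
        phase_speed=float(rng.uniform(0.7, 1.0)),
        head_intensity=head,
        tail_intensity=head + int(rng.integers(9, 13)),
        wobble_phase=float(rng.uniform(0, 2 * np.pi)),
    )
    params["wavelength"] = params["length"] * 0.9
    params.update(overrides)
    return params


def _event_trajectories(spec: ScenarioSpec,
                        rng: np.random.Generator) -> list[_WormTrajectory]:
    c = spec.center
    T = spec.n_frames - 1
    worms: list[_WormTrajectory] = []

    def traj(pos0, vel, heading, **ov):
        p = _base_worm(rng, **ov)
        return _WormTrajectory(np.asarray(pos0, float), np.asarray(vel, float),
                               heading, **p)

    if spec.event == "none":
        worms.append(traj((c - 30, c - 32), (0.0, 2.2), 0.0))
        if spec.n_worms > 1:
            worms.append(traj((c + 30, c + 32), (0.0, -2.2), np.pi))
    elif spec.event == "cross":
        # worm0 rides left->right, worm1 top->bottom; seeded offsets keep
        # the crossing generic (a perfectly concentric, simultaneous X is
        # a degenerate, genuinely ambiguous configuration)
        v = 66.0 / T
        e0 = float(rng.uniform(-8, 8))
        e1 = float(rng.uniform(-8, 8))
        dt = float(rng.uniform(-1.5, 1.5))
        worms.append(traj((c + e0, c - 33), (0.0, v), 0.0))
        worms.append(traj((c - 33 + dt * v, c + e1), (v, 0.0), np.pi / 2,
                          amplitude=1.6))
    elif spec.event == "partial_overlap":
        # worm1 crosses worm0's mid-body at a shallow angle
        v = 64.0 / T
        ang = np.deg2rad(35)
        d = np.array([np.sin(ang), np.cos(ang)])
        worms.append(traj((c, c - 32), (0.0, v), 0.0))
        worms.append(traj(np.array([c, c]) - d * 32 + np.array([4.0, 0.0]),
                          d * v, ang, amplitude=1.5))
    elif spec.event == "end_contact":
        # heads approach tip-to-tip at mid-sequence, then retreat
        def gap(t):
            return 1.0 + 52.0 * abs(2.0 * t / T - 1.0)

        L = 44.0
        worms.append(traj((c, 0), (0, 0), 0.0, length=L, amplitude=1.2,
                          wobble=0.0))
        worms[-1].center_fn = lambda t: (c - 1.5, c - gap(t) / 2 - L / 2)
        worms.append(traj((c, 0), (0, 0), np.pi, length=L, amplitude=1.2,
                          wobble=0.0))
        worms[-1].center_fn = lambda t: (c + 1.5, c + gap(t) / 2 + L / 2)
    elif spec.event == "parallel_bodies":
        # side-by-side travel, gap closing to body contact at mid-sequence
        p0 = _base_worm(rng)
        p1 = _base_worm(rng)
        # identical undulation keeps the bodies parallel while merged
        for key in ("length", "amplitude", "wavelength", "phase0", "phase_speed"):
            p1[key] = p0[key]
        # pressed together: shallow enough that thinning alone cannot
        # separate the bodies (the situation the event exists to pose)
        touch = 0.6 * (p0["half_width"] + p1["half_width"])

        def delta(t):
            return touch + 22.0 * abs(2.0 * t / T - 1.0)

        w0 = _WormTrajectory(np.zeros(2), np.zeros(2), 0.0, **p0)
        w0.center_fn = lambda t: (c - delta(t) / 2, c - 28 + 2.0 * t)
        w1 = _WormTrajectory(np.zeros(2), np.zeros(2), 0.0, **p1)
        w1.center_fn = lambda t: (c + delta(t) / 2, c - 28 + 2.0 * t)
        worms.extend([w0, w1])

    # extra worms beyond the scripted pair circle the dish rim region
    n_extra = spec.n_worms - len(worms)
    for i in range(max(0, n_extra)):
        ang = 2 * np.pi * (i + 0.5) / max(1, n_extra) + 0.4
        r0 = spec.dish_radius * 0.55
        pos = np.array([c + r0 * np.sin(ang), c + r0 * np.cos(ang)])
        tang = ang + np.pi / 2
        vel = 1.0 * np.array([np.sin(tang), np.cos(tang)])
        worms.append(traj(pos, vel, tang))
    return worms[:spec.n_worms]


def _stamp_worm(img: np.ndarray, wspec: WormSpec) -> None:
    pts = wspec.control_points
    widths = wspec.width_profile
    frac = np.linspace(0, 1, len(pts))
    # tail -> head order; head (end of motion direction) is darker
    levels = wspec.tail_intensity + (wspec.head_intensity
                                     - wspec.tail_intensity) * frac
    H, W = img.shape
    for (r, c), w, lv in zip(pts, widths, levels):
        rad = int(np.ceil(w))
        r0, c0 = int(np.floor(r)) - rad, int(np.floor(c)) - rad
        rr, cc = np.mgrid[r0:r0 + 2 * rad + 2, c0:c0 + 2 * rad + 2]
        inside = (rr - r) ** 2 + (cc - c) ** 2 <= w ** 2
        rr, cc = rr[inside], cc[inside]
        keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        rr, cc = rr[keep], cc[keep]
        np.minimum.at(img, (rr, cc), lv)


def render_sequence(spec: ScenarioSpec
                    ) -> tuple[GraySequence, dict[int, dict[int, SkeletonPath]]]:
    """Render a scenario.

    Returns the image sequence and ground truth as
    ``truth[frame][worm_id] -> SkeletonPath`` (head-first).  Raises
    :class:`FixtureError` if any worm body leaves the dish region.
    """
    rng = np.random.default_rng(spec.seed)
    worms = _event_trajectories(spec, rng)

    size, c = spec.canvas, spec.center
    rr, cc = np.mgrid[0:size, 0:size]
    dish = (rr - c) ** 2 + (cc - c) ** 2 <= spec.dish_radius ** 2

    frames = np.empty((spec.n_frames, size, size), np.uint8)
    truth: dict[int, dict[int, SkeletonPath]] = {}
    for t in range(spec.n_frames):
        img = np.full((size, size), float(DISH_BACKGROUND))
        img[~dish] = OUTSIDE_LEVEL
        for blob in spec.noise_blobs:
            br, bc = blob.center
            inside = (rr - br) ** 2 + (cc - bc) ** 2 <= blob.radius ** 2
            img[inside] = np.minimum(img[inside], float(blob.intensity))
        truth[t] = {}
        for wid, worm in enumerate(worms):
            wspec = worm.spec(t)
            radial = np.linalg.norm(wspec.control_points - c, axis=1)
            if (radial + wspec.width_profile > spec.dish_radius - 2).any():
                raise FixtureError(
                    f"worm {wid} leaves the dish region at frame {t}")
            _stamp_worm(img, wspec)
            # ground truth is head-first: reverse the tail->head samples
            truth[t][wid] = path_from_points(wspec.control_points[::-1])
        frames[t] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return GraySequence(frames, frame_period=1.0), truth


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def truth_to_json(truth: dict[int, dict[int, SkeletonPath]]) -> str:
    payload = {
        str(f): {str(w): p.as_list() for w, p in sorted(worms.items())}
        for f, worms in sorted(truth.items())
    }
    return json.dumps(payload, sort_keys=True)


def truth_from_json(text: str) -> dict[int, dict[int, SkeletonPath]]:
    raw = json.loads(text)
    return {
        int(f): {int(w): SkeletonPath(np.array(px, int))
                 for w, px in worms.items()}
        for f, worms in raw.items()
    }


def write_scenario(spec: ScenarioSpec, out_dir: str | Path) -> Path:
    """Write numbered PNG frames plus ground_truth.json; return the dir."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq, truth = render_sequence(spec)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(out / f"frame_{i:03d}.png", frame)
    (out / "ground_truth.json").write_text(truth_to_json(truth))
    return out
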