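"""Image stimulus codec: 30x30 binary patterns on the 900 L2/3 pyramidal cells.

A binary image drives the column: pixel (row r, col c), 1-based and
row-major, maps to L2/3 PC id 30*(r-1)+c.  ON pixels receive a current
injection during the stimulation window; after the stimulus, the network's
persistent activity is decoded back into an image (pixel ON iff its neuron
spiked at least once in the decode window), so input and output live in the
same 30x30 space and can be compared pixelwise.

Two stimulus modes are provided.  ``pulse`` (default) injects a
deterministic rectangular current into every target for the whole window.
``poisson50`` draws, per target, independent Poisson pulse times at the
configured rate and injects one-step rectangles — the literal
rate-coded variant, useful with stimulation windows long enough for a
50 Hz process to produce pulses.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "BinaryPattern",
    "PATTERN_NAMES",
    "generate_pattern",
    "load_pattern",
    "encode_image",
    "decode_output",
    "add_salt_pepper",
    "ImageStimulus",
    "read_pbm",
    "write_pbm",
]

GRID = 30
N_PIXELS = GRID * GRID
PATTERN_NAMES = ("star", "circle", "square", "triangle")


@dataclass(frozen=True)
class BinaryPattern:
    """A 30x30 binary image with a label."""

    pixels: np.ndarray
    name: str = ""

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=np.uint8)
        if arr.shape != (GRID, GRID):
            raise ValueError(f"pattern must be {GRID}x{GRID}, got {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("pattern pixels must be 0 or 1")
        object.__setattr__(self, "pixels", arr)

    @property
    def n_on(self) -> int:
        return int(self.pixels.sum())

    def hamming(self, other: "BinaryPattern") -> int:
        return int(np.count_nonzero(self.pixels != other.pixels))

    def __eq__(self, other) -> bool:
        return isinstance(other, BinaryPattern) and np.array_equal(self.pixels, other.pixels)


def _point_in_polygon(px: float, py: float, poly: Sequence[tuple[float, float]]) -> bool:
    """Even-odd ray casting test."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def generate_pattern(name: str) -> BinaryPattern:
    """Deterministic full-field test patterns: star, circle, square, triangle.

    All shapes are centered on the grid and filled; each covers between
    roughly 200 and 400 of the 900 pixels.
    """
    if name not in PATTERN_NAMES:
        raise ValueError(f"unknown pattern {name!r}; expected one of {PATTERN_NAMES}")
    px = np.zeros((GRID, GRID), dtype=np.uint8)
    cx = cy = (GRID - 1) / 2.0  # 14.5
    if name == "square":
        px[5:25, 5:25] = 1
    elif name == "circle":
        r, c = np.mgrid[0:GRID, 0:GRID]
        px[(r - cy) ** 2 + (c - cx) ** 2 <= 10.0**2] = 1
    elif name == "triangle":
        # apex at row 4, base at row 25 spanning half-width 10.5
        for row in range(4, 26):
            hw = (row - 4) / 21.0 * 10.5
            for col in range(GRID):
                if abs(col - cx) <= hw:
                    px[row, col] = 1
    elif name == "star":
        # five-pointed star, apex up, outer radius 13, inner radius 5.5
        poly = []
        for k in range(10):
            radius = 13.0 if k % 2 == 0 else 5.5
            theta = -math.pi / 2 + k * math.pi / 5
            poly.append((cx + radius * math.cos(theta), cy + radius * math.sin(theta)))
        for row in range(GRID):
            for col in range(GRID):
                if _point_in_polygon(float(col), float(row), poly):
                    px[row, col] = 1
    return BinaryPattern(pixels=px, name=name)


def load_pattern(name: str) -> BinaryPattern:
    """Load one of the four frozen pattern fixtures bundled with the package."""
    ref = importlib.resources.files("neocolumn.data") / "patterns" / f"{name}.pbm"
    return read_pbm_text(ref.read_text(), name=name)


def encode_image(pattern: BinaryPattern) -> set[int]:
    """ON-pixel neuron ids: pixel (r, c) (1-based) -> L2/3 PC id 30*(r-1)+c."""
    rows, cols = np.nonzero(pattern.pixels)
    return set((rows * GRID + cols + 1).tolist())


def decode_output(raster, window: tuple[float, float] = (202.0, 300.0)) -> BinaryPattern:
    """Decode a spike raster into a 30x30 image: pixel k is ON iff L2/3 PC
    id k fired at least once inside the closed window."""
    t0, t1 = window
    sel = (raster.times >= t0) & (raster.times <= t1) & (raster.neuron_ids <= N_PIXELS)
    ids = np.unique(raster.neuron_ids[sel])
    px = np.zeros(N_PIXELS, dtype=np.uint8)
    px[ids - 1] = 1
    return BinaryPattern(pixels=px.reshape(GRID, GRID), name="decoded")


def add_salt_pepper(
    pattern: BinaryPattern,
    proportion: float,
    seed: int,
    *,
    mode: str = "flip",
) -> BinaryPattern:
    """Corrupt a pattern with salt-and-pepper noise.

    ``flip`` (default) inverts exactly round(proportion * 900) distinct,
    uniformly chosen pixels, so the corruption level is guaranteed.
    ``random_extreme`` instead sets each chosen pixel to 0 or 1 with equal
    probability (the classic variant; the realized Hamming change is then
    random).
    """
    if not 0 <= proportion <= 1:
        raise ValueError(f"proportion must be in [0, 1], got {proportion}")
    n_flip = int(round(proportion * N_PIXELS))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.choice(N_PIXELS, size=n_flip, replace=False)
    flat = pattern.pixels.flatten()
    if mode == "flip":
        flat[idx] ^= 1
    elif mode == "random_extreme":
        flat[idx] = rng.integers(0, 2, size=n_flip, dtype=np.uint8)
    else:
        raise ValueError(f"unknown noise mode {mode!r}")
    label = f"{pattern.name}+sp{proportion:g}" if pattern.name else "noisy"
    return BinaryPattern(pixels=flat.reshape(GRID, GRID), name=label)


@dataclass
class ImageStimulus:
    """Current injection into a target set of L2/3 PCs.

    In ``pulse`` mode every target receives ``pulse_amplitude`` pA over
    [onset, onset + stim_duration).  In ``poisson50`` mode every target
    receives independent Poisson-timed one-step pulses at ``poisson_rate``
    Hz inside the window.
    """

    targets: set[int] = field(default_factory=set)
    onset: float = 200.0
    stim_duration: float = 1.0
    mode: str = "pulse"
    pulse_amplitude: float = 500.0
    poisson_rate: float = 50.0
    pulse_width: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        bad = [t for t in self.targets if not 1 <= t <= N_PIXELS]
        if bad:
            raise ValueError(f"stimulus targets outside 1..{N_PIXELS}: {sorted(bad)[:5]}")
        if self.mode not in ("pulse", "poisson50"):
            raise ValueError(f"unknown stimulus mode {self.mode!r}")

    def current_events(self, dt: float, n_steps: int, rng: np.random.Generator):
        """Render to (step, neuron_index_0based, amplitude) event arrays."""
        if self.seed is not None:
            rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        targets = np.array(sorted(self.targets), dtype=np.int64) - 1
        k0 = int(round(self.onset / dt))
        k1 = int(round((self.onset + self.stim_duration) / dt))
        k1 = min(k1, n_steps)
        if len(targets) == 0 or k1 <= k0:
            z = np.empty(0, dtype=np.int64)
            return z, z.copy(), np.empty(0, dtype=np.float64)
        if self.mode == "pulse":
            steps = np.repeat(np.arange(k0, k1, dtype=np.int64), len(targets))
            neurons = np.tile(targets, k1 - k0)
            amps = np.full(len(steps), self.pulse_amplitude)
            return steps, neurons, amps
        # poisson50: per-target homogeneous Poisson pulse times in the window,
        # each pulse a rectangle of pulse_width ms (overlaps simply add)
        duration_s = (k1 - k0) * dt / 1000.0
        counts = rng.poisson(self.poisson_rate * duration_s, size=len(targets))
        w_steps = max(1, int(round(self.pulse_width / dt)))
        step_chunks = []
        neuron_chunks = []
        for tgt, cnt in zip(targets, counts):
            if cnt == 0:
                continue
            times = rng.uniform(k0 * dt, k1 * dt, size=cnt)
            onsets = np.floor(times / dt).astype(np.int64)
            span = (onsets[:, None] + np.arange(w_steps)[None, :]).ravel()
            span = span[span < n_steps]
            step_chunks.append(span)
            neuron_chunks.append(np.full(len(span), tgt, dtype=np.int64))
        if not step_chunks:
            z = np.empty(0, dtype=np.int64)
            return z, z.copy(), np.empty(0, dtype=np.float64)
        steps = np.concatenate(step_chunks)
        neurons = np.concatenate(neuron_chunks)
        amps = np.full(len(steps), self.pulse_amplitude)
        return steps, neurons, amps


def read_pbm(path: str | Path, name: str = "") -> BinaryPattern:
    """Read a plain-text PBM (P1) image as a pattern."""
    return read_pbm_text(Path(path).read_text(), name=name or Path(path).stem)


def read_pbm_text(text: str, name: str = "") -> BinaryPattern:
    tokens: list[str] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0]
        tokens.extend(line.split())
    if not tokens or tokens[0] != "P1":
        raise ValueError("not a plain PBM (P1) image")
    width, height = int(tokens[1]), int(tokens[2])
    bits = [int(t) for t in "".join(tokens[3:])]
    if width != GRID or height != GRID or len(bits) != N_PIXELS:
        raise ValueError(f"expected a {GRID}x{GRID} PBM, got {width}x{height}")
    return BinaryPattern(pixels=np.array(bits, dtype=np.uint8).reshape(GRID, GRID), name=name)


def write_pbm(pattern: BinaryPattern, path: str | Path) -> None:
    lines = ["P1", f"{GRID} {GRID}"]
    for row in pattern.pixels:
        lines.append(" ".join(str(int(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
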