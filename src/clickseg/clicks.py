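"""Click encoding and simulated user interaction.

A user guides the segmentation network by clicking pixels: *positive* clicks
assert foreground, *negative* clicks assert background. Each polarity's click
set S is encoded as a guidance map D of the same height and width as the
image,

    D(i, j) = min over s in S of the Euclidean distance from (i, j) to s,

truncated at a configurable ceiling (255 by default, the convention of the
click-based interactive-segmentation literature). The two maps are
concatenated with the RGB image as the 5-channel network input.

During training and validation real users are unavailable, so clicks are
simulated. Positive clicks are drawn from the candidate set

    Cp = { p in Gp : phi(p, Gn) > P1  and  phi(p, A*) > P2 },

where Gp/Gn are the foreground/background pixel sets, A* is the set of
already placed positive clicks and phi(p, S) is the shortest Euclidean
distance from p to the region S. Negative clicks come from

    Cn = { p in Gn : phi(p, Gp) in (N1, N2)  and  phi(p, B*) > N3 },

with B* the already placed negative clicks. The margin parameters are drawn
per instance from the pools {5,10,15,20}, {7,10,20}, {15,40,60}, {80} and
{10,15,25} for P1, P2, N1, N2 and N3 respectively. Counts are capped at
1-10 positive and 0-10 negative clicks per instance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "Click",
    "ClickSet",
    "ClickGenParams",
    "UnclickableInstanceError",
    "DEFAULT_TRUNCATION",
    "encode_clicks",
    "encode_click_set",
    "phi",
    "positive_candidates",
    "negative_candidates",
    "simulate_clicks",
    "centered_click",
    "next_correction_click",
    "save_click_set",
    "load_click_set",
]

DEFAULT_TRUNCATION = 255.0

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)

P1_POOL = (5, 10, 15, 20)
P2_POOL = (7, 10, 20)
N1_POOL = (15, 40, 60)
N2_POOL = (80,)
N3_POOL = (10, 15, 25)


class UnclickableInstanceError(RuntimeError):
    """No positive candidate exists before the first click (P1 too strict)."""


@dataclasses.dataclass(frozen=True)
class Click:
    row: int
    col: int
    polarity: str  # "positive" | "negative"

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")


@dataclasses.dataclass
class ClickSet:
    """Ordered positive (A*) and negative (B*) clicks."""

    positives: list[Click] = dataclasses.field(default_factory=list)
    negatives: list[Click] = dataclasses.field(default_factory=list)
    truncated: bool = False  # simulator ran out of candidates early

    def add(self, click: Click) -> None:
        (self.positives if click.polarity == "positive" else self.negatives).append(click)

    def coords(self, polarity: str) -> np.ndarray:
        clicks = self.positives if polarity == "positive" else self.negatives
        if not clicks:
            return np.empty((0, 2), dtype=np.int64)
        return np.array([[c.row, c.col] for c in clicks], dtype=np.int64)


@dataclasses.dataclass(frozen=True)
class ClickGenParams:
    """Margins of the click simulator (all in pixels)."""

    p1: int
    p2: int
    n1: int
    n2: int
    n3: int

    def __post_init__(self):
        if not self.n1 < self.n2:
            raise ValueError(f"require N1 < N2, got {self.n1} >= {self.n2}")

    @classmethod
    def draw(cls, rng: np.random.Generator) -> "ClickGenParams":
        """Draw one value per margin from its pool (per-instance draw)."""
        return cls(
            p1=int(rng.choice(P1_POOL)),
            p2=int(rng.choice(P2_POOL)),
            n1=int(rng.choice(N1_POOL)),
            n2=int(rng.choice(N2_POOL)),
            n3=int(rng.choice(N3_POOL)),
        )


def _validate_bounds(coords: np.ndarray, height: int, width: int) -> None:
    if coords.size == 0:
        return
    if (
        coords[:, 0].min() < 0
        or coords[:, 0].max() >= height
        or coords[:, 1].min() < 0
        or coords[:, 1].max() >= width
    ):
        raise ValueError(
            f"click out of bounds for {height}x{width} image: {coords.tolist()}"
        )


def encode_clicks(
    clicks: list[Click] | np.ndarray,
    height: int,
    width: int,
    truncation: float = DEFAULT_TRUNCATION,
) -> np.ndarray:
    """Distance map of one click polarity.

    Every entry is the Euclidean distance to the nearest click, clipped at
    ``truncation``. An empty click list gives a map filled with the truncation
    value (the no-information convention).
    """
    if isinstance(clicks, np.ndarray):
        coords = clicks.reshape(-1, 2).astype(np.int64)
    else:
        coords = (
            np.array([[c.row, c.col] for c in clicks], dtype=np.int64)
            if clicks
            else np.empty((0, 2), dtype=np.int64)
        )
    _validate_bounds(coords, height, width)
    if coords.shape[0] == 0:
        return np.full((height, width), truncation, dtype=np.float64)
    indicator = np.ones((height, width), dtype=bool)
    indicator[coords[:, 0], coords[:, 1]] = False
    dist = ndimage.distance_transform_edt(indicator)
    return np.minimum(dist, truncation)


def encode_click_set(
    clicks: ClickSet,
    height: int,
    width: int,
    truncation: float = DEFAULT_TRUNCATION,
) -> tuple[np.ndarray, np.ndarray]:
    """(positive map, negative map) for a full click set."""
    d_pos = encode_clicks(clicks.positives, height, width, truncation)
    d_neg = encode_clicks(clicks.negatives, height, width, truncation)
    return d_pos, d_neg


def phi(p: tuple[int, int], region: np.ndarray) -> float:
    """Shortest Euclidean distance from pixel ``p`` to a region.

    ``region`` is either a boolean mask or an (M, 2) array of coordinates.
    Empty region returns +inf so distance constraints against an empty click
    set are vacuously satisfied (needed before the first click).
    """
    if region.ndim == 2 and region.shape[1] == 2 and region.dtype != bool:
        coords = region
    else:
        coords = np.argwhere(region)
    if coords.shape[0] == 0:
        return float("inf")
    d = np.hypot(coords[:, 0] - p[0], coords[:, 1] - p[1])
    return float(d.min())


def _dist_to_points(shape: tuple[int, int], coords: np.ndarray) -> np.ndarray:
    """H x W map of distance to the nearest of a small set of points."""
    if coords.shape[0] == 0:
        return np.full(shape, np.inf)
    indicator = np.ones(shape, dtype=bool)
    indicator[coords[:, 0], coords[:, 1]] = False
    return ndimage.distance_transform_edt(indicator)


def positive_candidates(
    mask: np.ndarray, p1: float, p2: float, existing: ClickSet | None = None
) -> np.ndarray:
    """Boolean map of valid positions for the next positive click.

    Foreground pixels farther than ``p1`` from every background pixel and
    farther than ``p2`` from every existing positive click (strict
    inequalities). The exact Euclidean distance transform makes both
    constraints exact.
    """
    fg = mask.astype(bool)
    if not fg.any() or fg.all():
        raise ValueError("mask must contain both foreground and background pixels")
    dist_to_bg = ndimage.distance_transform_edt(fg)  # 0 on background
    cand = fg & (dist_to_bg > p1)
    if existing is not None:
        coords = existing.coords("positive")
        if coords.shape[0] > 0:
            cand &= _dist_to_points(mask.shape, coords) > p2
    return cand


def negative_candidates(
    mask: np.ndarray,
    n1: float,
    n2: float,
    n3: float,
    existing: ClickSet | None = None,
) -> np.ndarray:
    """Boolean map of valid positions for the next negative click.

    Background pixels whose distance to the foreground lies strictly inside
    (n1, n2), farther than ``n3`` from every existing negative click.
    """
    fg = mask.astype(bool)
    if not fg.any() or fg.all():
        raise ValueError("mask must contain both foreground and background pixels")
    dist_to_fg = ndimage.distance_transform_edt(~fg)  # 0 on foreground
    cand = (~fg) & (dist_to_fg > n1) & (dist_to_fg < n2)
    if existing is not None:
        coords = existing.coords("negative")
        if coords.shape[0] > 0:
            cand &= _dist_to_points(mask.shape, coords) > n3
    return cand


def simulate_clicks(
    mask: np.ndarray,
    params: ClickGenParams,
    n_pos: int,
    n_neg: int,
    rng: np.random.Generator,
) -> ClickSet:
    """Sequentially sample a click set for one instance.

    Each click is drawn uniformly from the current candidate set; the set is
    recomputed after every draw. If a candidate set empties before the
    requested count is reached the set is returned short with
    ``truncated=True``. An empty positive candidate set before the first
    click raises :class:`UnclickableInstanceError`.
    """
    if not (1 <= n_pos <= 10):
        raise ValueError(f"n_pos must be in [1, 10], got {n_pos}")
    if not (0 <= n_neg <= 10):
        raise ValueError(f"n_neg must be in [0, 10], got {n_neg}")

    clicks = ClickSet()
    for k in range(n_pos):
        cand = positive_candidates(mask, params.p1, params.p2, clicks)
        coords = np.argwhere(cand)
        if coords.shape[0] == 0:
            if k == 0:
                raise UnclickableInstanceError(
                    f"no foreground pixel is more than P1={params.p1} px from the "
                    "background; relax P1 or enlarge the object"
                )
            clicks.truncated = True
            break
        r, c = coords[rng.integers(coords.shape[0])]
        clicks.add(Click(int(r), int(c), "positive"))

    for _ in range(n_neg):
        cand = negative_candidates(mask, params.n1, params.n2, params.n3, clicks)
        coords = np.argwhere(cand)
        if coords.shape[0] == 0:
            clicks.truncated = True
            break
        r, c = coords[rng.integers(coords.shape[0])]
        clicks.add(Click(int(r), int(c), "negative"))

    return clicks


def centered_click(mask: np.ndarray) -> ClickSet:
    """One positive click at the interior-most foreground pixel.

    The deterministic stand-in for a user's first click "at the object":
    the foreground pixel maximising distance to the background (first in
    raster order on ties).
    """
    dist = ndimage.distance_transform_edt(mask.astype(bool))
    r, c = np.unravel_index(int(np.argmax(dist)), mask.shape)
    cs = ClickSet()
    cs.add(Click(int(r), int(c), "positive"))
    return cs


def next_correction_click(
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    exclude: set[tuple[int, int]] | None = None,
) -> Click:
    """Place the next corrective click on the largest error region.

    The larger of the biggest false-negative and biggest false-positive
    4-connected component is chosen (ties favour the false negative); the
    click lands on the pixel of that component farthest from the component's
    complement (its interior-most point), positive for missed foreground,
    negative for spurious foreground. This is the de-facto standard placement
    rule of click-based evaluation protocols.

    ``exclude`` lists pixels already clicked; they are skipped so a frozen
    model cannot force the evaluation loop to repeat a click. Components are
    tried largest-first; only if every error pixel is excluded does the rule
    fall back to repeating the interior-most pixel of the largest component.
    """
    pred = pred_mask.astype(bool)
    gt = gt_mask.astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, gt {gt.shape}")
    if np.array_equal(pred, gt):
        raise ValueError("masks are identical; no correction click is defined")

    def components(err: np.ndarray, polarity: str):
        labels, n = ndimage.label(err, structure=_FOUR_CONNECTED)
        out = []
        for lab in range(1, n + 1):
            comp = labels == lab
            out.append((int(comp.sum()), polarity, comp))
        return out

    cands = components(gt & ~pred, "positive") + components(pred & ~gt, "negative")
    # Largest first; ties favour false negatives (positive polarity).
    cands.sort(key=lambda t: (-t[0], t[1] != "positive"))

    fallback = None
    for _, polarity, comp in cands:
        dist = ndimage.distance_transform_edt(comp)
        if fallback is None:
            r, c = np.unravel_index(int(np.argmax(dist)), comp.shape)
            fallback = Click(int(r), int(c), polarity)
        if exclude:
            for rr, cc in exclude:
                if comp[rr, cc]:
                    dist[rr, cc] = -1.0
        r, c = np.unravel_index(int(np.argmax(dist)), comp.shape)
        if dist[r, c] > 0:
            return Click(int(r), int(c), polarity)
    return fallback


# ---------------------------------------------------------------------------
# JSON round-trip of click sets


def save_click_set(clicks: ClickSet, path: str | Path) -> None:
    payload = {
        "positives": [[c.row, c.col] for c in clicks.positives],
        "negatives": [[c.row, c.col] for c in clicks.negatives],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_click_set(path: str | Path) -> ClickSet:
    with open(path) as fh:
        payload = json.load(fh)
    cs = ClickSet()
    for r, c in payload.get("positives", []):
        cs.add(Click(int(r), int(c), "positive"))
    for r, c in payload.get("negatives", []):
        cs.add(Click(int(r), int(c), "negative"))
    return cs
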