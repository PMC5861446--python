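"""Chromatic registration, two-channel spot pairing and chance colocalization.

The red (RNA) and green (protein) channels are related by a small chromatic
aberration modelled as an affine (linear + translation) map fitted by least
squares to fiducial coordinate pairs from a dual-labelled test molecule.
Spots are paired greedily in ascending order of mapped distance; apparent
colocalization expected from random coincidence is estimated per image and
reported alongside — but, matching assay practice, never subtracted by
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import Spot

__all__ = ["ChromaticMap", "ColocResult", "ColocSummary", "fit_chromatic_map",
           "colocalize", "estimate_coincidence", "summarize_colocalization"]


@dataclass
class ChromaticMap:
    """Affine map from red-channel to green-channel coordinates."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    rms_residual: float = 0.0
    translation_only: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float).reshape(2, 2)
        self.translation = np.asarray(self.translation, float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("linear part must be invertible")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "ChromaticMap":
        inv = np.linalg.inv(self.matrix)
        return ChromaticMap(matrix=inv, translation=-inv @ self.translation,
                            rms_residual=self.rms_residual,
                            translation_only=self.translation_only)

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(),
                "translation": self.translation.tolist(),
                "rms_residual": self.rms_residual,
                "translation_only": self.translation_only}

    @classmethod
    def from_dict(cls, d: dict) -> "ChromaticMap":
        return cls(matrix=np.array(d["matrix"]), translation=np.array(d["translation"]),
                   rms_residual=d.get("rms_residual", 0.0),
                   translation_only=d.get("translation_only", False))


def _pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        red = pairs[["x_red", "y_red"]].to_numpy(float)
        green = pairs[["x_green", "y_green"]].to_numpy(float)
    else:
        arr = np.asarray(pairs, float)
        red, green = arr[:, 0:2], arr[:, 2:4]
    return red, green


def fit_chromatic_map(pairs, allow_translation_only: bool = True) -> ChromaticMap:
    """Least-squares affine fit to fiducial pairs (x_red, y_red, x_green, y_green).

    With at least three non-collinear pairs a full affine map is fitted;
    with fewer (and ``allow_translation_only``) the fit falls back to a pure
    translation and is flagged as such.
    """
    red, green = _pairs_to_arrays(pairs)
    n = red.shape[0]
    if n < 1:
        raise ValueError("need at least one fiducial pair")

    centered = red - red.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-9) if n >= 3 else 0
    if n < 3 or rank < 2:
        if not allow_translation_only:
            raise ValueError("need >= 3 non-collinear pairs for an affine map")
        t = (green - red).mean(axis=0)
        resid = green - (red + t)
        return ChromaticMap(matrix=np.eye(2), translation=t,
                            rms_residual=float(np.sqrt((resid ** 2).sum(axis=1).mean())),
                            translation_only=True)

    design = np.hstack([red, np.ones((n, 1))])
    coef, *_ = np.linalg.lstsq(design, green, rcond=None)
    matrix = coef[:2].T
    translation = coef[2]
    resid = green - (red @ matrix.T + translation)
    return ChromaticMap(matrix=matrix, translation=translation,
                        rms_residual=float(np.sqrt((resid ** 2).sum(axis=1).mean())))


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

@dataclass
class ColocResult:
    """Greedy nearest-neighbour pairing of red and green spots."""

    pairs: list[tuple[int, int, float]]
    unpaired_red: list[int]
    unpaired_green: list[int]
    coincidence_estimate: float | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def colocalized_fraction(self, n_red: int | None = None) -> float:
        """Percent of red (RNA) spots with a paired green spot."""
        n = n_red if n_red is not None else len(self.pairs) + len(self.unpaired_red)
        if n == 0:
            return 0.0
        return 100.0 * len(self.pairs) / n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["red_id", "green_id", "distance"])


def _spot_coords(spots: Sequence[Spot] | np.ndarray) -> np.ndarray:
    if len(spots) == 0:
        return np.zeros((0, 2))
    if isinstance(spots, np.ndarray):
        return np.atleast_2d(spots.astype(float))
    return np.array([[s.x, s.y] for s in spots], float)


def colocalize(red: Sequence[Spot], green: Sequence[Spot],
               chromatic_map: ChromaticMap | None = None,
               radius: float = 2.0) -> ColocResult:
    """Pair red and green spots after chromatic correction.

    Candidate pairs within ``radius`` of each other (red coordinates mapped
    into the green frame) are accepted greedily in ascending distance
    order, each spot used at most once; ties are broken by lower red then
    green index.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    cmap = chromatic_map or ChromaticMap()
    red_xy = _spot_coords(red)
    green_xy = _spot_coords(green)
    if red_xy.shape[0] == 0 or green_xy.shape[0] == 0:
        return ColocResult(pairs=[], unpaired_red=list(range(red_xy.shape[0])),
                           unpaired_green=list(range(green_xy.shape[0])))

    mapped = cmap.apply(red_xy)
    d = np.sqrt(((mapped[:, None, :] - green_xy[None, :, :]) ** 2).sum(axis=2))
    ri, gi = np.nonzero(d <= radius)
    candidates = sorted(zip(d[ri, gi], ri, gi))

    used_r: set[int] = set()
    used_g: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for dist, r, g in candidates:
        if r in used_r or g in used_g:
            continue
        used_r.add(int(r))
        used_g.add(int(g))
        pairs.append((int(r), int(g), float(dist)))
    return ColocResult(
        pairs=pairs,
        unpaired_red=[i for i in range(red_xy.shape[0]) if i not in used_r],
        unpaired_green=[i for i in range(green_xy.shape[0]) if i not in used_g])


# ---------------------------------------------------------------------------
# random coincidence
# ---------------------------------------------------------------------------

def estimate_coincidence(red: Sequence[Spot], green: Sequence[Spot],
                         image_area: float, radius: float = 2.0,
                         mode: str = "analytic",
                         image_shape: tuple[int, int] | None = None,
                         n_translations: int = 100,
                         rng: np.random.Generator | None = None) -> float:
    """Fraction of red spots expected colocalized by chance alone.

    Analytic mode treats green spots as a spatial Poisson process of
    density rho = n_green / area, giving 1 - exp(-rho * pi * radius^2) per
    red spot.  Empirical mode measures the colocalized fraction over random
    torus translations of the green channel, which preserves within-channel
    structure; the two agree for Poisson-scattered spots.
    """
    if image_area <= 0:
        raise ValueError("image_area must be positive")
    green_xy = _spot_coords(green)
    if green_xy.shape[0] == 0:
        return 0.0
    if mode == "analytic":
        rho = green_xy.shape[0] / image_area
        return float(1.0 - math.exp(-rho * math.pi * radius ** 2))
    if mode != "empirical":
        raise ValueError(f"unknown mode {mode!r}")

    if image_shape is None:
        side = math.sqrt(image_area)
        image_shape = (side, side)
    red_xy = _spot_coords(red)
    if red_xy.shape[0] == 0:
        return 0.0
    rng = rng or np.random.default_rng()
    h, w = image_shape
    fractions = np.empty(n_translations)
    for i in range(n_translations):
        shift = rng.uniform(0, [w, h])
        shifted = np.mod(green_xy + shift, [w, h])
        d2 = ((red_xy[:, None, :] - shifted[None, :, :]) ** 2).sum(axis=2)
        fractions[i] = np.mean(d2.min(axis=1) <= radius ** 2)
    return float(fractions.mean())


@dataclass
class ColocSummary:
    """Colocalized fraction summarized over replicate experiments."""

    per_experiment: list[float]
    mean: float
    sem: float
    single_experiment: bool = False

    def to_dict(self) -> dict:
        return {"per_experiment_percent": self.per_experiment,
                "mean_percent": self.mean, "sem_percent": self.sem,
                "single_experiment": self.single_experiment}


def summarize_colocalization(per_experiment_fractions: Sequence[float]) -> ColocSummary:
    """Mean and SEM (sample SD / sqrt(n)) of per-experiment percentages.

    With a single experiment the SEM is reported as 0 and flagged.
    """
    fracs = [float(f) for f in per_experiment_fractions]
    if len(fracs) == 0:
        raise ValueError("need at least one experiment")
    if len(fracs) == 1:
        return ColocSummary(per_experiment=fracs, mean=fracs[0], sem=0.0,
                            single_experiment=True)
    arr = np.asarray(fracs)
    return ColocSummary(per_experiment=fracs, mean=float(arr.mean()),
                        sem=float(arr.std(ddof=1) / math.sqrt(arr.size)))
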