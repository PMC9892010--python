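"""Co-migration similarity between profile components via regions of interest.

Fitted Gaussian components define seed regions of interest (ROIs): profile
segments clipped at 2.5 standard deviations around the component mean.
Each seed is compared against the same slice window of every other
protein's profile; highly correlating segments (Pearson r >= 0.95) become
additional ROIs.  ROIs from the same profile with near-identical boundaries
are merged.  Every ROI is summarised by a 4-value vector (left boundary,
right boundary, maximum abundance, correlation with its seed), the boundary
coordinates square-root-transformed after min/max normalization so that
location differences dominate.  The distance between two ROIs is the
Euclidean distance of their vectors extended by their mutual profile
correlation; dividing by the fixed theoretical maximum turns it into a
similarity score in [0, 1].  A t-SNE embedding of the distance matrix
serves as the presentation layer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .model import ProfileSet
from .peakfit import PeakList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROI:
    """A bounded segment of one protein's profile (1-based inclusive slices)."""

    protein_id: str
    left: int
    right: int
    max_abundance: float
    r_seed: float = 1.0
    origin: str = "seed"  # seed | correlate | merged

    def __post_init__(self) -> None:
        if not (1 <= self.left <= self.right):
            raise ValueError(f"invalid ROI bounds [{self.left}, {self.right}]")
        if self.max_abundance < 0:
            raise ValueError("max_abundance must be >= 0")


@dataclass(frozen=True)
class RoiVector:
    v1: float  # sqrt-transformed normalized left boundary
    v2: float  # sqrt-transformed normalized right boundary
    v3: float  # normalized max abundance
    v4: float  # normalized r_seed

    def as_array(self) -> np.ndarray:
        return np.array([self.v1, self.v2, self.v3, self.v4])


@dataclass(frozen=True)
class SimilarityResult:
    roi_a: int
    roi_b: int
    distance: float
    similarity: float
    d_max: float


@dataclass(frozen=True)
class SimilarityConfig:
    r_min: float = 0.95
    max_sigma: float = 20.0
    clip_sd: float = 2.5
    merge_tolerance: int = 3
    boundary_transform: str = "sqrt"       # sqrt | linear
    correlation_interval: str = "union"    # union | intersection
    correlation_mode: str = "euclidean"    # euclidean | multiplicative


D_MAX = math.sqrt(5.0)


# ---------------------------------------------------------------------------
# ROI construction


def seed_rois(
    peaklists: list[PeakList],
    profiles: ProfileSet,
    config: SimilarityConfig | None = None,
) -> list[ROI]:
    """Seed ROIs from fitted components, clipped at 2.5 s.d.

    Components wider than ``max_sigma`` slices or whose FWHM is not fully
    inside the gel are excluded; surviving component intervals
    ``mean +/- clip_sd * sigma`` are rounded to slice indices and clipped
    to the gel range.
    """
    cfg = config or SimilarityConfig()
    n = profiles.n_slices
    rois: list[ROI] = []
    for pl in peaklists:
        if pl.protein_id not in profiles:
            continue
        prof = profiles.profile(pl.protein_id)
        for c in pl.components:
            if c.sigma > cfg.max_sigma:
                continue
            half_fwhm = c.fwhm_slices / 2.0
            if c.mean_slice - half_fwhm < 1 or c.mean_slice + half_fwhm > n:
                continue
            left = max(1, int(round(c.mean_slice - cfg.clip_sd * c.sigma)))
            right = min(n, int(round(c.mean_slice + cfg.clip_sd * c.sigma)))
            if left > right:
                continue
            rois.append(
                ROI(
                    pl.protein_id, left, right,
                    float(np.max(prof[left - 1 : right])),
                    r_seed=1.0, origin="seed",
                )
            )
    return rois


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def expand_rois(
    seeds: list[ROI],
    profiles: ProfileSet,
    r_min: float = 0.95,
) -> list[ROI]:
    """Correlation expansion: segments of other profiles matching a seed.

    For every seed, the seed protein's profile over [left, right] is
    Pearson-correlated with every other protein's profile over the same
    slices; segments with r >= ``r_min`` become ROIs of those proteins.
    Zero-variance segments are skipped (correlation undefined).
    """
    out: list[ROI] = []
    for seed in seeds:
        ref = profiles.profile(seed.protein_id)[seed.left - 1 : seed.right]
        for pid in profiles.protein_ids:
            if pid == seed.protein_id:
                continue
            seg = profiles.profile(pid)[seed.left - 1 : seed.right]
            r = _pearson(ref, seg)
            if r is not None and r >= r_min:
                out.append(
                    ROI(pid, seed.left, seed.right, float(np.max(seg)), r, "correlate")
                )
    return out


def merge_rois(
    rois: list[ROI],
    profiles: ProfileSet | None = None,
    tolerance: int = 3,
) -> list[ROI]:
    """Merge same-profile ROIs with boundaries within ``tolerance`` slices.

    Merging is transitive (single linkage over the boundary-proximity
    relation) and order-independent; merged boundaries are the rounded
    means of the member boundaries, the seed correlation is averaged, and
    the maximum abundance is re-read from the profile inside the merged
    interval when profiles are available.
    """
    by_protein: dict[str, list[ROI]] = {}
    for roi in rois:
        by_protein.setdefault(roi.protein_id, []).append(roi)

    merged: list[ROI] = []
    for pid in sorted(by_protein):
        group = sorted(by_protein[pid], key=lambda r: (r.left, r.right, -r.r_seed))
        n = len(group)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if (
                    abs(group[i].left - group[j].left) <= tolerance
                    and abs(group[i].right - group[j].right) <= tolerance
                ):
                    parent[find(i)] = find(j)
        clusters: dict[int, list[ROI]] = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(group[i])
        for members in clusters.values():
            if len(members) == 1:
                merged.append(members[0])
                continue
            left = int(round(float(np.mean([m.left for m in members]))))
            right = int(round(float(np.mean([m.right for m in members]))))
            r_seed = float(np.mean([m.r_seed for m in members]))
            if profiles is not None and pid in profiles:
                max_ab = float(np.max(profiles.profile(pid)[left - 1 : right]))
            else:
                max_ab = float(np.max([m.max_abundance for m in members]))
            merged.append(ROI(pid, left, right, max_ab, r_seed, "merged"))
    return merged


def build_rois(
    peaklists: list[PeakList],
    profiles: ProfileSet,
    config: SimilarityConfig | None = None,
) -> list[ROI]:
    """seed -> correlate -> merge, the full ROI construction chain."""
    cfg = config or SimilarityConfig()
    seeds = seed_rois(peaklists, profiles, cfg)
    correlates = expand_rois(seeds, profiles, cfg.r_min)
    return merge_rois(seeds + correlates, profiles, cfg.merge_tolerance)


# ---------------------------------------------------------------------------
# distance metric


@dataclass
class RoiNormalizer:
    """Dataset min/max ranges turning ROIs into comparable unit vectors."""

    left_range: tuple[float, float]
    right_range: tuple[float, float]
    abundance_range: tuple[float, float]
    r_range: tuple[float, float]
    boundary_transform: str = "sqrt"

    @classmethod
    def from_rois(
        cls, rois: list[ROI], boundary_transform: str = "sqrt"
    ) -> "RoiNormalizer":
        if not rois:
            raise ValueError("cannot normalize an empty ROI set")

        def rng(vals: list[float]) -> tuple[float, float]:
            lo, hi = float(min(vals)), float(max(vals))
            if lo == hi:
                logger.warning("degenerate ROI value range [%g, %g]; coordinate set to 0", lo, hi)
            return lo, hi

        return cls(
            rng([r.left for r in rois]),
            rng([r.right for r in rois]),
            rng([r.max_abundance for r in rois]),
            rng([r.r_seed for r in rois]),
            boundary_transform,
        )

    @staticmethod
    def _norm(x: float, rng: tuple[float, float]) -> float:
        lo, hi = rng
        if hi == lo:
            return 0.0
        return min(max((x - lo) / (hi - lo), 0.0), 1.0)

    def vector(self, roi: ROI) -> RoiVector:
        v1 = self._norm(roi.left, self.left_range)
        v2 = self._norm(roi.right, self.right_range)
        if self.boundary_transform == "sqrt":
            v1, v2 = math.sqrt(v1), math.sqrt(v2)
        return RoiVector(
            v1, v2,
            self._norm(roi.max_abundance, self.abundance_range),
            self._norm(roi.r_seed, self.r_range),
        )


def mutual_correlation(
    a: ROI, b: ROI, profiles: ProfileSet, interval: str = "union"
) -> float:
    """Pearson correlation of the two ROI profiles over the union interval.

    Zero-variance segments yield r = 0 (no co-migration information).
    """
    if interval == "union":
        left, right = min(a.left, b.left), max(a.right, b.right)
    elif interval == "intersection":
        left, right = max(a.left, b.left), min(a.right, b.right)
        if left > right:
            return 0.0
    else:
        raise ValueError(f"unknown interval mode '{interval}'")
    pa = profiles.profile(a.protein_id)[left - 1 : right]
    pb = profiles.profile(b.protein_id)[left - 1 : right]
    r = _pearson(pa, pb)
    return 0.0 if r is None else r


def roi_distance(
    a: ROI,
    b: ROI,
    profiles: ProfileSet,
    normalizer: RoiNormalizer,
    config: SimilarityConfig | None = None,
    index_a: int = 0,
    index_b: int = 1,
) -> SimilarityResult:
    """Distance and similarity of two ROIs.

    The default metric appends ``(1 - r_ab) / 2`` (mutual profile
    correlation mapped to [0, 1]) as a fifth Euclidean coordinate to the
    4-value vector difference, so the theoretical maximum distance is the
    fixed sqrt(5) and ``similarity = 1 - distance / sqrt(5)``.  The
    multiplicative alternative scales the 4-vector distance by
    ``(1 - r_ab) / 2`` instead (d_max = 2).
    """
    cfg = config or SimilarityConfig()
    va = normalizer.vector(a).as_array()
    vb = normalizer.vector(b).as_array()
    r_ab = mutual_correlation(a, b, profiles, cfg.correlation_interval)
    if cfg.correlation_mode == "euclidean":
        diff = np.append(va - vb, (1.0 - r_ab) / 2.0)
        dist = float(np.linalg.norm(diff))
        d_max = D_MAX
    elif cfg.correlation_mode == "multiplicative":
        dist = float(np.linalg.norm(va - vb)) * (1.0 + (1.0 - r_ab) / 2.0)
        d_max = 2.0 * 2.0
    else:
        raise ValueError(f"unknown correlation_mode '{cfg.correlation_mode}'")
    sim = 1.0 - dist / d_max
    return SimilarityResult(index_a, index_b, dist, min(max(sim, 0.0), 1.0), d_max)


def pairwise_distances(
    rois: list[ROI],
    profiles: ProfileSet,
    config: SimilarityConfig | None = None,
) -> np.ndarray:
    """Symmetric all-pairs distance matrix over the ROI set."""
    cfg = config or SimilarityConfig()
    normalizer = RoiNormalizer.from_rois(rois, cfg.boundary_transform)
    n = len(rois)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = roi_distance(rois[i], rois[j], profiles, normalizer, cfg, i, j)
            dist[i, j] = dist[j, i] = res.distance
    return dist


def similarity_matrix(
    rois: list[ROI],
    profiles: ProfileSet,
    config: SimilarityConfig | None = None,
) -> np.ndarray:
    cfg = config or SimilarityConfig()
    d_max = D_MAX if cfg.correlation_mode == "euclidean" else 4.0
    sim = 1.0 - pairwise_distances(rois, profiles, cfg) / d_max
    return np.clip(sim, 0.0, 1.0)


def roi_table(rois: list[ROI]):
    """Flatten ROIs into the canonical table layout (one row per ROI)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in rois],
            "left": [r.left for r in rois],
            "right": [r.right for r in rois],
            "max_abundance": [r.max_abundance for r in rois],
            "r_seed": [r.r_seed for r in rois],
            "origin": [r.origin for r in rois],
        }
    )


# ---------------------------------------------------------------------------
# embedding (presentation layer)


def embed_components(
    distance_matrix: np.ndarray,
    seed: int,
    perplexity: float = 30.0,
) -> np.ndarray:
    """2-D t-SNE embedding of the precomputed ROI distance matrix.

    Deterministic for a fixed seed; perplexity is capped at n / 4 so small
    ROI sets remain embeddable.  Purely for visualization -- no quantitative
    conclusion should rest on embedded coordinates.
    """
    from sklearn.manifold import TSNE

    n = distance_matrix.shape[0]
    if n < 5:
        raise ValueError(f"too few points to embed ({n} < 5)")
    perplexity = min(perplexity, n / 4.0)
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        random_state=seed,
        perplexity=perplexity,
    )
    return tsne.fit_transform(distance_matrix)
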