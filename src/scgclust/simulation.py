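"""Noise-robustness benchmark on planar Gaussian blobs.

The experiment measures how clustering methods degrade when the distance
measurement itself is noisy.  Four point clouds of 20 points each are drawn
around the centers (0, 8), (0, -8), (8, 0), (-8, 0) with independent N(0, 1)
offsets; all pairwise Euclidean distances are then perturbed with one
N(0, sd^2) draw per unordered pair (symmetry preserved, diagonal untouched),
for a grid of perturbation SDs.  Each method is scored per replicate by the
number of clusters it reports (singletons included) and by the number of
incorrect within-cluster pairs against the generating centers.

Perturbed distances may go negative; that is deliberate — SCG consumes
ranks, which depend only on the ordering, and clamping would manufacture
ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .baselines import LinkageSpec, linkage_partition
from .core import scg_a2
from .evaluation import count_pair_errors
from .forest import Partition
from .ranking import ScoreMatrix, build_rank_matrix

__all__ = [
    "NoiseExperimentConfig",
    "NoiseExperimentResult",
    "generate_blob_dataset",
    "perturb_distances",
    "run_noise_experiment",
    "plot_noise_curves",
]

DEFAULT_CENTERS = ((0.0, 8.0), (0.0, -8.0), (8.0, 0.0), (-8.0, 0.0))


@dataclass(frozen=True)
class NoiseExperimentConfig:
    """Study conditions for the noise-robustness experiment.

    Defaults reproduce the benchmark design: 80 points (20 per center,
    N(0, 1) offsets), perturbation SD swept from 0 to 3 in steps of 0.25,
    100 perturbation replicates per SD on a fixed point set, SCG compared
    against CL/AL/SL at distance cut-offs 2 and 4.
    """

    centers: tuple[tuple[float, float], ...] = DEFAULT_CENTERS
    points_per_center: int = 20
    point_noise_sd: float = 1.0
    sd_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 3.0 + 1e-9, 0.25), 2))
    replicates: int = 100
    methods: tuple[str, ...] = ("scg", "cl", "al", "sl")
    cutoffs: tuple[float, ...] = (2.0, 4.0)
    redraw_points: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.points_per_center < 1:
            raise ValueError("points_per_center must be >= 1")
        if any(sd < 0 for sd in self.sd_grid):
            raise ValueError("perturbation SDs must be >= 0")
        unknown = set(self.methods) - {"scg", "cl", "al", "sl"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @property
    def n_points(self) -> int:
        return len(self.centers) * self.points_per_center


@dataclass
class NoiseExperimentResult:
    """Tidy per-replicate records plus the configuration that produced them."""

    records: pd.DataFrame  # method, cutoff, sd, replicate, n_clusters, incorrect_pairs
    config: NoiseExperimentConfig

    def aggregate(self) -> pd.DataFrame:
        """Mean and SD over replicates per (method, cutoff, sd)."""
        agg = (
            self.records.groupby(["method", "cutoff", "sd"], dropna=False)
            .agg(
                n_clusters_mean=("n_clusters", "mean"),
                n_clusters_sd=("n_clusters", "std"),
                incorrect_pairs_mean=("incorrect_pairs", "mean"),
                incorrect_pairs_sd=("incorrect_pairs", "std"),
            )
            .reset_index()
        )
        return agg.sort_values(["method", "cutoff", "sd"]).reset_index(drop=True)


def generate_blob_dataset(
    config: NoiseExperimentConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, Partition]:
    """Draw the planar point set and its reference partition.

    Returns an ``(n, 2)`` coordinate array (points grouped by center, in
    center order) and the partition assigning each point to its generating
    center.
    """
    config = config or NoiseExperimentConfig()
    rng = np.random.default_rng(rng)
    centers = np.asarray(config.centers, dtype=float)
    k, per = len(centers), config.points_per_center
    offsets = rng.normal(0.0, config.point_noise_sd, size=(k * per, 2))
    points = np.repeat(centers, per, axis=0) + offsets
    groups = [range(c * per + 1, (c + 1) * per + 1) for c in range(k)]
    return points, Partition(groups, n=k * per)


def perturb_distances(
    D: ScoreMatrix | np.ndarray,
    sd: float,
    rng: np.random.Generator | int | None = None,
) -> ScoreMatrix | np.ndarray:
    """Add one N(0, sd^2) draw per unordered pair of a symmetric distance matrix.

    Both orientations of a pair receive the same draw, so symmetry is
    preserved; the diagonal is untouched and ``sd=0`` returns an unchanged
    copy.  Negative results are kept (see module docstring).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    wrap = isinstance(D, ScoreMatrix)
    values = D.values if wrap else np.asarray(D, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T, rtol=1e-9, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    out = values.copy()
    if sd > 0:
        rng = np.random.default_rng(rng)
        iu = np.triu_indices(values.shape[0], k=1)
        noise = rng.normal(0.0, sd, size=iu[0].size)
        out[iu] += noise
        out[(iu[1], iu[0])] += noise
    if wrap:
        return ScoreMatrix(out, orientation="distance", objects=D.objects)
    return out


def _method_runs(config: NoiseExperimentConfig) -> list[tuple[str, float | None]]:
    runs: list[tuple[str, float | None]] = []
    for m in config.methods:
        if m == "scg":
            runs.append(("scg", None))
        else:
            runs.extend((m, c) for c in config.cutoffs)
    return runs

_LINKAGE_NAME = {"cl": "complete", "al": "average", "sl": "single"}


def _cluster_once(method: str, cutoff: float | None, dist: np.ndarray) -> Partition:
    if method == "scg":
        rm = build_rank_matrix(ScoreMatrix(dist, orientation="distance"))
        return scg_a2(rm).independent_clusters
    return linkage_partition(dist, LinkageSpec(_LINKAGE_NAME[method], cutoff=cutoff))


def run_noise_experiment(config: NoiseExperimentConfig | None = None) -> NoiseExperimentResult:
    """Sweep every (method, cutoff, SD, replicate) cell; fully seeded.

    By default the point set is drawn once and each replicate redraws only
    the distance perturbation; with ``redraw_points`` the points (and hence
    the reference) are regenerated per replicate as well.
    """
    config = config or NoiseExperimentConfig()
    ss = np.random.SeedSequence(config.seed)
    points_ss, *cell_ss = ss.spawn(1 + len(config.sd_grid) * config.replicates)
    base_points, base_ref = generate_blob_dataset(config, np.random.default_rng(points_ss))
    base_dist = squareform(pdist(base_points))
    runs = _method_runs(config)
    rows: list[dict] = []
    cell = 0
    for sd in config.sd_grid:
        for rep in range(config.replicates):
            rng = np.random.default_rng(cell_ss[cell])
            cell += 1
            if config.redraw_points:
                points, ref = generate_blob_dataset(config, rng)
                dist = squareform(pdist(points))
            else:
                ref, dist = base_ref, base_dist
            noisy = perturb_distances(dist, sd, rng)
            for method, cutoff in runs:
                part = _cluster_once(method, cutoff, noisy)
                _, incorrect = count_pair_errors(part, ref)
                rows.append(
                    {
                        "method": method,
                        "cutoff": cutoff,
                        "sd": sd,
                        "replicate": rep,
                        "n_clusters": part.n_groups,
                        "incorrect_pairs": incorrect,
                    }
                )
    records = pd.DataFrame(rows)
    return NoiseExperimentResult(records=records, config=config)


def plot_noise_curves(result: NoiseExperimentResult, value: str = "n_clusters", ax=None):
    """Mean +- SD curves of *value* against perturbation SD, one per method/cutoff."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    agg = result.aggregate()
    for (method, cutoff), sub in agg.groupby(["method", "cutoff"], dropna=False):
        label = method if pd.isna(cutoff) else f"{method}/{cutoff:g}"
        ax.errorbar(sub["sd"], sub[f"{value}_mean"], yerr=sub[f"{value}_sd"], label=label)
    ax.set_xlabel("perturbation SD")
    ax.set_ylabel(value.replace("_", " "))
    ax.legend()
    return ax
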