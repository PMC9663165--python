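"""Synthetic-data generators with ground truth.

Every input class the quantification pipeline consumes can be simulated
here with known latent parameters: two-population flow-cytometry mixtures
(cell-conjugation assays), Hill-shaped titration curves, dendrite images
with controllable MAP2 fragmentation and synaptic-puncta density, grouped
Golgi spine-count tables, and noisy mutant binding screens.

All generators are deterministic given their parameters and seed, and each
returns a :class:`GroundTruth` that is sufficient to score any downstream
estimate (event labels, per-pixel masks, puncta centroids, true densities)
without re-running the generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FlowSimParams",
    "TitrationSimParams",
    "DendriteSimParams",
    "SpineSimParams",
    "GroundTruth",
    "gen_flow_events",
    "gen_titration",
    "gen_dendrite_image",
    "gen_spine_counts",
    "gen_mutant_screen",
    "hill_response",
]


@dataclass(frozen=True)
class GroundTruth:
    """Latent truth behind a simulated dataset.

    ``labels`` holds per-object ground truth (which events are conjugates,
    the per-pixel MAP2 mask, puncta centroids, per-neuron true densities)
    keyed by name; ``params`` records the latent parameters actually used.
    """

    generator: str
    params: dict[str, Any]
    labels: dict[str, Any] = field(default_factory=dict)


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite, got {v!r}")


# ---------------------------------------------------------------------------
# Flow cytometry conjugation events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowSimParams:
    """Two-population log-normal mixture for a two-colour conjugation assay.

    A fraction ``p_conjugate`` of events are cell-cell conjugates, bright in
    both the green and red channels; the remainder are single cells, bright
    in one channel only (split evenly between colours).  Intensities are
    log-normal per channel in arbitrary fluorescence units.
    """

    n_events: int = 10_000
    p_conjugate: float = 0.1
    pos_mean: float = 5_000.0   # median AFU of a positive channel
    pos_sd: float = 0.5         # sigma of log intensity
    neg_mean: float = 50.0
    neg_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 0.0 <= self.p_conjugate <= 1.0:
            raise ValueError("p_conjugate must lie in [0, 1]")
        if self.pos_sd <= 0 or self.neg_sd <= 0:
            raise ValueError("channel sds must be > 0")
        _require_finite(
            "FlowSimParams", self.p_conjugate, self.pos_mean, self.pos_sd,
            self.neg_mean, self.neg_sd,
        )


def gen_flow_events(params: FlowSimParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-event (green, red) intensities for a conjugation assay.

    Returns an event table with columns ``green`` and ``red`` (AFU) and a
    ground truth whose ``is_conjugate`` label marks the double-positive
    events; the realized conjugate fraction is recorded in the params.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_events
    is_conj = rng.random(n) < params.p_conjugate
    # non-conjugate events are single-positive in one colour
    green_cell = rng.random(n) < 0.5

    def lognorm(median: float, sigma: float, size: int) -> np.ndarray:
        return median * np.exp(sigma * rng.standard_normal(size))

    green_pos = is_conj | green_cell
    red_pos = is_conj | ~green_cell
    green = np.where(green_pos, lognorm(params.pos_mean, params.pos_sd, n),
                     lognorm(params.neg_mean, params.neg_sd, n))
    red = np.where(red_pos, lognorm(params.pos_mean, params.pos_sd, n),
                   lognorm(params.neg_mean, params.neg_sd, n))
    events = pd.DataFrame({"green": green, "red": red})
    truth = GroundTruth(
        generator="flow",
        params={"p_conjugate": params.p_conjugate, "n_events": n,
                "seed": params.seed,
                "realized_fraction": float(is_conj.mean())},
        labels={"is_conjugate": is_conj},
    )
    return events, truth


# ---------------------------------------------------------------------------
# Hill titrations
# ---------------------------------------------------------------------------

def hill_response(x: np.ndarray | float, bmax: float, kd: float, h: float):
    """Hill binding model Y = Bmax * X^h / (Kd^h + X^h); Y(0) = 0."""
    x = np.asarray(x, dtype=float)
    xh = np.zeros_like(x)
    pos = x > 0
    xh[pos] = np.power(x[pos], h)
    return bmax * xh / (kd**h + xh)


@dataclass(frozen=True)
class TitrationSimParams:
    """Hill-curve titration with multiplicative (CV) noise.

    ``kd`` is the half-saturation concentration in nM (reported downstream
    as EC50), ``h`` the Hill coefficient, ``bmax`` the saturating response.
    """

    bmax: float = 100.0
    kd: float = 16.0
    h: float = 2.3
    concentrations: tuple[float, ...] = (0.0, 0.5, 1, 2, 4, 8, 16, 32, 64, 100)
    cv_noise: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.h <= 0 or self.bmax <= 0:
            raise ValueError("bmax, kd and h must all be > 0")
        if len(self.concentrations) < 1:
            raise ValueError("at least one concentration is required")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be >= 0")
        _require_finite("TitrationSimParams", self.bmax, self.kd, self.h,
                        self.cv_noise, *self.concentrations)


def gen_titration(params: TitrationSimParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a concentration-response table from a Hill curve.

    Response Y_i = Bmax*X_i^h/(Kd^h+X_i^h) * (1 + eps_i) with
    eps_i ~ Normal(0, cv_noise); ``cv_noise=0`` gives the exact curve.
    Returns columns ``conc_nM``, ``response``, ``replicate``.
    """
    rng = np.random.default_rng(params.seed)
    x = np.tile(np.asarray(params.concentrations, float), params.n_replicates)
    rep = np.repeat(np.arange(params.n_replicates), len(params.concentrations))
    y_true = hill_response(x, params.bmax, params.kd, params.h)
    y = y_true * (1.0 + params.cv_noise * rng.standard_normal(x.size))
    data = pd.DataFrame({"conc_nM": x, "response": y, "replicate": rep})
    truth = GroundTruth(
        generator="titration",
        params={"bmax": params.bmax, "kd": params.kd, "h": params.h,
                "cv_noise": params.cv_noise, "seed": params.seed},
        labels={"response_true": y_true},
    )
    return data, truth


# ---------------------------------------------------------------------------
# Dendrite images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DendriteSimParams:
    """Synthetic multi-channel dendrite image with known fragmentation.

    Dendrites are random-walk polylines drawn into an 8-bit MAP2 channel at
    ``foreground`` intensity.  A fraction ``map2_gap_fraction`` of each
    path's length is erased in contiguous gaps (fragmented, punctate MAP2 —
    the dystrophic phenotype).  Each puncta channel gets a Poisson number
    (rate ``puncta_density`` per µm of path) of disks at uniform positions
    along the paths, kept a minimum distance apart because synaptic puncta
    are discrete non-overlapping objects.  Gaussian background noise is
    added and clipped to [0, 255].
    """

    shape: tuple[int, int] = (288, 288)
    pixel_size_um: float = 0.1
    n_paths: int = 1
    path_length_px: int = 600
    step_sigma: float = 0.25        # radians; direction jitter per step
    map2_gap_fraction: float = 0.0
    n_gaps: int = 4
    puncta_density: Mapping[str, float] = field(
        default_factory=lambda: {"PSD95": 0.5})
    puncta_radius_px: int = 1
    # minimum centre-to-centre separation between puncta of one marker;
    # None -> just beyond the blob-merge distance (2*radius + 2)
    puncta_min_separation_px: float | None = None
    background_mean: float = 10.0
    background_sd: float = 3.0
    foreground: int = 220
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.map2_gap_fraction <= 1.0:
            raise ValueError("map2_gap_fraction must lie in [0, 1]")
        if any(lam < 0 for lam in self.puncta_density.values()):
            raise ValueError("puncta densities must be >= 0")
        if not 0 < self.foreground <= 255:
            raise ValueError("foreground must lie in (0, 255] (8-bit)")
        if self.foreground <= self.background_mean:
            raise ValueError("foreground must exceed background mean")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.n_paths < 1 or self.path_length_px < 2:
            raise ValueError("need at least one path of >= 2 samples")


def _random_walk_path(rng: np.random.Generator, shape: tuple[int, int],
                      n_steps: int, step_sigma: float) -> np.ndarray:
    """Unit-step random walk polyline (x, y float vertices) kept in bounds."""
    h, w = shape
    margin = 8
    pos = np.array([rng.uniform(margin, w - margin),
                    rng.uniform(margin, h - margin)])
    theta = rng.uniform(0, 2 * math.pi)
    pts = [pos.copy()]
    for _ in range(n_steps - 1):
        theta += rng.normal(0.0, step_sigma)
        step = np.array([math.cos(theta), math.sin(theta)])
        nxt = pos + step
        # reflect off borders to stay inside the frame
        if not margin <= nxt[0] <= w - margin:
            theta = math.pi - theta
            nxt = pos + np.array([math.cos(theta), math.sin(theta)])
        if not margin <= nxt[1] <= h - margin:
            theta = -theta
            nxt = pos + np.array([math.cos(theta), math.sin(theta)])
        pos = np.clip(nxt, margin, [w - margin, h - margin])
        pts.append(pos.copy())
    return np.asarray(pts)


def _gap_intervals(rng: np.random.Generator, n_samples: int, g: float,
                   n_gaps: int) -> np.ndarray:
    """Boolean keep-mask over path samples with fraction g removed in
    contiguous gaps."""
    keep = np.ones(n_samples, dtype=bool)
    total_gap = int(round(g * n_samples))
    if total_gap <= 0:
        return keep
    if total_gap >= n_samples:
        return np.zeros(n_samples, dtype=bool)
    k = max(1, min(n_gaps, total_gap))
    # split the total gap length into k contiguous pieces
    cuts = np.sort(rng.choice(np.arange(1, total_gap), size=k - 1,
                              replace=False)) if k > 1 else np.array([], int)
    pieces = np.diff(np.concatenate(([0], cuts, [total_gap])))
    starts = np.sort(rng.choice(n_samples - total_gap + 1, size=k,
                                replace=True))
    offset = 0
    for start, length in zip(starts, pieces):
        s = min(start + offset, n_samples - length)
        keep[s:s + length] = False
        offset += length
    # exact fraction may be off when pieces overlap; re-trim to the quantum
    deficit = total_gap - int((~keep).sum())
    if deficit > 0:
        on = np.flatnonzero(keep)
        keep[on[:deficit]] = False
    return keep


def gen_dendrite_image(
    params: DendriteSimParams,
) -> tuple[dict[str, np.ndarray], list[np.ndarray], GroundTruth]:
    """Simulate a dendrite image bundle.

    Returns ``(channels, paths, truth)`` where ``channels`` maps marker name
    (``MAP2`` plus one key per puncta marker) to an 8-bit image, ``paths``
    is a list of (n, 2) float arrays of (x, y) polyline vertices, and the
    ground truth carries the per-pixel MAP2 mask, the kept-sample mask per
    path, and puncta centroids per marker.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    map2 = np.zeros((h, w), dtype=float)
    paths: list[np.ndarray] = []
    keep_masks: list[np.ndarray] = []
    map2_mask = np.zeros((h, w), dtype=bool)
    centroids: dict[str, list[tuple[float, float]]] = {
        m: [] for m in params.puncta_density
    }
    puncta_imgs = {m: np.zeros((h, w), float) for m in params.puncta_density}
    n_merged = 0
    n_placed = 0

    for _ in range(params.n_paths):
        path = _random_walk_path(rng, params.shape, params.path_length_px,
                                 params.step_sigma)
        paths.append(path)
        cols = np.clip(np.round(path[:, 0]).astype(int), 0, w - 1)
        rows = np.clip(np.round(path[:, 1]).astype(int), 0, h - 1)
        keep = _gap_intervals(rng, len(path), params.map2_gap_fraction,
                              params.n_gaps)
        keep_masks.append(keep)
        map2[rows[keep], cols[keep]] = params.foreground
        map2_mask[rows[keep], cols[keep]] = True

        # unit-step walk => arc length in µm is (n-1) * pixel size
        length_um = (len(path) - 1) * params.pixel_size_um
        rad = params.puncta_radius_px
        min_sep = (params.puncta_min_separation_px
                   if params.puncta_min_separation_px is not None
                   else 2 * rad + 2)
        for marker, lam in params.puncta_density.items():
            # Poisson number of discrete puncta; positions drawn uniformly
            # along the path under a minimum-separation constraint, since
            # synapses are non-overlapping physical objects.  If a punctum
            # cannot be placed the constraint is dropped for it and the
            # collision counts toward the merge warning.
            n_puncta = rng.poisson(lam * length_um)
            existing = centroids[marker]
            for _ in range(n_puncta):
                n_placed += 1
                for attempt in range(50):
                    cx, cy = path[rng.integers(0, len(path))]
                    if all((cx - ox) ** 2 + (cy - oy) ** 2 >= min_sep ** 2
                           for ox, oy in existing):
                        break
                else:
                    n_merged += 1
                x0, x1 = max(0, int(cx) - rad - 1), min(w, int(cx) + rad + 2)
                y0, y1 = max(0, int(cy) - rad - 1), min(h, int(cy) + rad + 2)
                sub_y, sub_x = np.mgrid[y0:y1, x0:x1]
                disk = (sub_x - cx) ** 2 + (sub_y - cy) ** 2 <= rad ** 2
                puncta_imgs[marker][y0:y1, x0:x1][disk] = params.foreground
                existing.append((float(cx), float(cy)))

    channels: dict[str, np.ndarray] = {}
    for name, img in [("MAP2", map2)] + list(puncta_imgs.items()):
        noisy = img + rng.normal(params.background_mean, params.background_sd,
                                 size=img.shape)
        channels[name] = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

    merge_warning = n_placed > 0 and n_merged / n_placed > 0.5
    truth = GroundTruth(
        generator="dendrite_image",
        params={"map2_gap_fraction": params.map2_gap_fraction,
                "puncta_density": dict(params.puncta_density),
                "pixel_size_um": params.pixel_size_um, "seed": params.seed,
                "merge_warning": merge_warning},
        labels={"map2_mask": map2_mask,
                "path_keep_masks": keep_masks,
                "puncta_centroids": {m: np.asarray(c).reshape(-1, 2)
                                     for m, c in centroids.items()}},
    )
    return channels, paths, truth


# ---------------------------------------------------------------------------
# Golgi spine counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpineSimParams:
    """Grouped Poisson spine counts on fixed-length dendrite segments.

    Each neuron contributes one segment; counts ~ Poisson(length x
    multiplier x base density).  Group multipliers encode treatment effects
    on mean spine density (e.g. control 1.0, treated 0.6 for a 40%
    reduction).  The base density default of 1.0 spines/µm is a typical
    pyramidal-cell apical value and is fully configurable.
    """

    group_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"control": 1.0, "treated": 0.6})
    base_density: float = 1.0      # spines per µm
    segment_length_um: float = 100.0
    neurons_per_group: int = 72    # e.g. 4 animals x 18 neurons
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.group_multipliers.values()):
            raise ValueError("group multipliers must be >= 0")
        if self.segment_length_um <= 0 or self.base_density < 0:
            raise ValueError("segment length must be > 0 and density >= 0")
        if self.neurons_per_group < 1:
            raise ValueError("neurons_per_group must be >= 1")


def gen_spine_counts(params: SpineSimParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a per-neuron spine-count table.

    Returns columns ``group``, ``neuron_id``, ``count``, ``length_um``.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    true_density = {}
    for group, mult in params.group_multipliers.items():
        dens = params.base_density * mult
        true_density[group] = dens
        counts = rng.poisson(dens * params.segment_length_um,
                             size=params.neurons_per_group)
        for i, c in enumerate(counts):
            rows.append((group, f"{group}_{i:03d}", int(c),
                         params.segment_length_um))
    table = pd.DataFrame(rows, columns=["group", "neuron_id", "count",
                                        "length_um"])
    truth = GroundTruth(
        generator="spines",
        params={"group_multipliers": dict(params.group_multipliers),
                "base_density": params.base_density, "seed": params.seed},
        labels={"true_density": true_density},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Mutant binding screens
# ---------------------------------------------------------------------------

def gen_mutant_screen(
    truth_table: Mapping[str, Mapping[str, float]],
    cv_noise: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an observed mutant x partner binding screen.

    ``truth_table`` maps mutant id -> partner -> true relative binding in %
    (wild type = 100).  A ``WT`` row at exactly 100 for every partner is
    added before noise if absent.  Observed values get multiplicative
    Normal(0, cv) noise and are floored at 0.

    Returns columns ``mutant``, ``partner``, ``percent_bound``.
    """
    if cv_noise < 0:
        raise ValueError("cv_noise must be >= 0")
    partners = sorted({p for row in truth_table.values() for p in row})
    table: dict[str, dict[str, float]] = {
        m: dict(row) for m, row in truth_table.items()
    }
    table.setdefault("WT", {})
    for p in partners:
        table["WT"].setdefault(p, 100.0)
    for m, row in table.items():
        for p, v in row.items():
            if v < 0:
                raise ValueError(f"relative binding must be >= 0 ({m}/{p})")

    rng = np.random.default_rng(seed)
    rows = []
    for mutant in table:
        for partner in sorted(table[mutant]):
            true_val = table[mutant][partner]
            obs = true_val * (1.0 + cv_noise * rng.standard_normal())
            rows.append((mutant, partner, max(obs, 0.0)))
    screen = pd.DataFrame(rows, columns=["mutant", "partner", "percent_bound"])
    gt = GroundTruth(
        generator="mutant_screen",
        params={"cv_noise": cv_noise, "seed": seed},
        labels={"true_relative_binding": table},
    )
    return screen, gt
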