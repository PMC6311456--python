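"""Fiber-bundle geometry, neuron population, and the mixing matrix.

A splayed bundle is modeled as fiber tips scattered by a bivariate normal in
xy (the splay observed in histology) and a normal depth jitter in z, all
axes parallel to z. Neurons are uniform point sources over a box large
enough to contain every region of non-negligible sensitivity.

The interface is summarized by the non-negative mixing matrix

    M[i, j] = h[i, j] * sum_k g[j, k]

where g[j, k] is the excitation that fiber k delivers to neuron j (490-nm
profile) and h[i, j] is the fraction of neuron j's emission collected by
fiber i (512-nm profile, by optical reciprocity). Excitation is static over
time. M is reported normalized by the round-trip brightness of a cell
immediately under a single fiber, so entries are comparable across bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .optics import FluenceProfile

__all__ = [
    "FiberBundleLayout",
    "NeuronPopulation",
    "MixingMatrix",
    "sample_fiber_positions",
    "sample_neuron_positions",
    "profile_lookup",
    "build_mixing_matrix",
    "visibility_stats",
    "fiber_contribution_curve",
    "neuron_collection_curve",
    "brightness_dominance",
    "round_trip_peak",
    "scale_fluence",
    "iso_contour_volume",
]

SIGMA_XY_DEFAULT = 0.150  # mm, xy splay SD at ~2 mm depth
SIGMA_Z_DEFAULT = 0.015   # mm, tip-depth SD set by how the bundle is cut
NEURON_DENSITY_DEFAULT = 250_000.0  # neurons / mm^3
BOX_DEFAULT = ((-0.53135, 0.53135), (-0.53135, 0.53135), (-0.53135, 0.53135))
# ~1.2 mm^3 cube centered on the nominal tip plane; covers >3.5 sigma of
# splay plus the full 1-mm sensitivity grid reach in z.


@dataclass
class FiberBundleLayout:
    """Sampled fiber-tip positions (mm); all fiber axes parallel to +z."""

    positions: np.ndarray  # (n_fibers, 3)
    sigma_xy: float
    sigma_z: float
    seed: int

    @property
    def n_fibers(self) -> int:
        return self.positions.shape[0]


@dataclass
class NeuronPopulation:
    """Uniformly distributed point-source neurons (mm)."""

    positions: np.ndarray  # (n_neurons, 3)
    density: float
    box: tuple
    seed: int

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]


@dataclass
class MixingMatrix:
    """Excitation/collection mixing matrix M with its factors.

    ``M`` is (n_fibers, n_neurons), non-negative, in raw profile units;
    ``normalization`` is the peak single-fiber round-trip brightness so that
    ``M / normalization`` puts a cell immediately under a lone fiber at 1.
    ``h`` is (n_fibers, n_neurons); ``g`` is (n_neurons, n_fibers) and may be
    dropped (None) for very large instances — ``excitation_sums`` (the per-
    neuron sum of g over fibers) is always kept, and M = h * excitation_sums.
    """

    M: np.ndarray
    h: np.ndarray | None
    g: np.ndarray | None
    excitation_sums: np.ndarray
    normalization: float
    meta: dict = field(default_factory=dict)

    @property
    def n_fibers(self) -> int:
        return self.M.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.M.shape[1]

    @property
    def normalized(self) -> np.ndarray:
        return self.M / self.normalization


def sample_fiber_positions(n_fibers: int, sigma_xy: float = SIGMA_XY_DEFAULT,
                           sigma_z: float = SIGMA_Z_DEFAULT,
                           seed: int = 0) -> FiberBundleLayout:
    """Draw fiber-tip positions: bivariate normal xy splay, normal z jitter."""
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    if sigma_xy < 0 or sigma_z < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    xy = rng.normal(0.0, sigma_xy, size=(n_fibers, 2)) if sigma_xy > 0 \
        else np.zeros((n_fibers, 2))
    z = rng.normal(0.0, sigma_z, size=(n_fibers, 1)) if sigma_z > 0 \
        else np.zeros((n_fibers, 1))
    return FiberBundleLayout(positions=np.hstack([xy, z]), sigma_xy=sigma_xy,
                             sigma_z=sigma_z, seed=int(seed))


def sample_neuron_positions(density: float = NEURON_DENSITY_DEFAULT,
                            box: tuple = BOX_DEFAULT,
                            seed: int = 0) -> NeuronPopulation:
    """Uniform neuron positions; count = round(density x box volume)."""
    if density < 0:
        raise ValueError("density must be non-negative")
    lo = np.array([b[0] for b in box], dtype=float)
    hi = np.array([b[1] for b in box], dtype=float)
    volume = float(np.prod(hi - lo))
    if volume <= 0:
        raise ValueError("box must have positive volume")
    n = int(round(density * volume))
    rng = np.random.default_rng(seed)
    pos = lo + rng.random((n, 3)) * (hi - lo)
    return NeuronPopulation(positions=pos, density=density,
                            box=tuple(tuple(b) for b in box), seed=int(seed))


def profile_lookup(profile: FluenceProfile, fiber_tip: np.ndarray,
                   points: np.ndarray) -> np.ndarray:
    """Sensitivity of a fiber at ``points`` (mm, lab frame).

    Trilinear interpolation of the tip-centered profile; zero outside the
    grid. ``fiber_tip`` is the fiber's tip position in lab coordinates.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return profile.lookup(pts - np.asarray(fiber_tip, dtype=float))


def _pairwise(profile: FluenceProfile, fibers: np.ndarray,
              neurons: np.ndarray) -> np.ndarray:
    out = np.empty((fibers.shape[0], neurons.shape[0]), dtype=np.float64)
    _kernels.sensitivity_pairs(profile.values, profile.grid.voxel_size,
                               profile.grid.origin,
                               np.ascontiguousarray(fibers, dtype=np.float64),
                               np.ascontiguousarray(neurons, dtype=np.float64),
                               out)
    return out


def round_trip_peak(excitation_profile: FluenceProfile,
                    collection_profile: FluenceProfile) -> float:
    """Peak single-fiber round-trip brightness h_peak*g_peak.

    The maximum over voxels of the product of excitation and collection
    sensitivity: the signal of a cell placed immediately under one fiber,
    used as the brightness normalization anchor.
    """
    return float(np.max(excitation_profile.values * collection_profile.values))


def build_mixing_matrix(layout: FiberBundleLayout,
                        population: NeuronPopulation,
                        excitation_profile: FluenceProfile,
                        collection_profile: FluenceProfile,
                        keep_g: bool | None = None) -> MixingMatrix:
    """Assemble M[i, j] = h[i, j] * sum_k g[j, k] for the sampled geometry.

    g uses the excitation-wavelength profile, h the emission-wavelength
    profile (collection by reciprocity). ``keep_g`` controls whether the full
    (n_neurons, n_fibers) g factor is retained (defaults to yes below 4e7
    entries).
    """
    if excitation_profile.grid.dims != collection_profile.grid.dims or \
            excitation_profile.grid.voxel_size != collection_profile.grid.voxel_size:
        raise ValueError("excitation and collection profiles need the same grid")
    fibers = layout.positions
    neurons = population.positions
    n_fib, n_neu = fibers.shape[0], neurons.shape[0]
    if keep_g is None:
        keep_g = n_fib * n_neu <= 40_000_000
    if n_neu == 0:
        z = np.zeros((n_fib, 0))
        return MixingMatrix(M=z, h=z.copy(), g=np.zeros((0, n_fib)),
                            excitation_sums=np.zeros(0),
                            normalization=round_trip_peak(excitation_profile,
                                                          collection_profile))
    g_fk = _pairwise(excitation_profile, fibers, neurons)  # (fiber k, neuron j)
    excitation_sums = g_fk.sum(axis=0)                     # per neuron
    g = np.ascontiguousarray(g_fk.T) if keep_g else None
    del g_fk
    h = _pairwise(collection_profile, fibers, neurons)     # (fiber i, neuron j)
    M = h * excitation_sums[None, :]
    norm = round_trip_peak(excitation_profile, collection_profile)
    return MixingMatrix(M=M, h=h, g=g, excitation_sums=excitation_sums,
                        normalization=norm,
                        meta={"layout_seed": layout.seed,
                              "population_seed": population.seed})


def visibility_stats(mix: MixingMatrix, thresholds=(0.005, 0.01, 0.02, 0.05)):
    """Neuron-visibility counts at normalized-brightness thresholds.

    For each threshold: how many neurons contribute above it to at least one
    fiber, to at least two fibers, and the mean per-fiber count of visible
    neurons. Returns a list of dicts (one per threshold).
    """
    Mn = mix.normalized
    out = []
    for thr in thresholds:
        vis = Mn >= thr                     # (fibers, neurons)
        per_neuron = vis.sum(axis=0)
        out.append({
            "threshold": float(thr),
            "n_ge1": int(np.count_nonzero(per_neuron >= 1)),
            "n_ge2": int(np.count_nonzero(per_neuron >= 2)),
            "mean_per_fiber": float(vis.sum(axis=1).mean()) if mix.n_fibers else 0.0,
        })
    return out


def fiber_contribution_curve(mix: MixingMatrix, n_top: int = 50) -> np.ndarray:
    """Mean sorted neuron-contribution curve per fiber.

    Each fiber's neuron contributions are sorted descending and normalized to
    its brightest neuron; curves are averaged over fibers with a nonzero
    brightest neuron. Entry 0 is 1 by construction.
    """
    M = mix.M
    if M.size == 0 or not np.any(M.max(axis=1) > 0):
        raise ValueError("need at least one fiber with a nonzero contribution")
    rows = []
    for i in range(M.shape[0]):
        row = M[i]
        top = row[np.argpartition(row, -min(n_top, row.size))[-min(n_top, row.size):]]
        top = np.sort(top)[::-1]
        if top[0] <= 0:
            continue
        curve = np.zeros(n_top)
        curve[:top.size] = top / top[0]
        rows.append(curve)
    return np.mean(rows, axis=0)


def neuron_collection_curve(mix: MixingMatrix, n_neurons: int = 50,
                            n_fibers_shown: int = 10) -> np.ndarray:
    """Per-neuron sorted fiber contributions for the brightest neurons, %.

    Selects the ``n_neurons`` neurons with the largest single-fiber
    round-trip signal, sorts each one's per-fiber contributions descending,
    normalizes to its strongest fiber (=100%), and averages. Returns a
    (n_fibers_shown,) percentage curve starting at 100.
    """
    M = mix.M
    if M.size == 0:
        raise ValueError("empty mixing matrix")
    best = M.max(axis=0)
    order = np.argsort(best)[::-1][:n_neurons]
    order = order[best[order] > 0]
    if order.size == 0:
        raise ValueError("no neuron has a nonzero contribution")
    curves = []
    for j in order:
        col = np.sort(M[:, j])[::-1]
        curve = np.zeros(n_fibers_shown)
        k = min(n_fibers_shown, col.size)
        curve[:k] = 100.0 * col[:k] / col[0]
        curves.append(curve)
    return np.mean(curves, axis=0)


def brightness_dominance(mix: MixingMatrix) -> float:
    """Mean % by which each fiber's brightest neuron exceeds its second.

    100 * (M_first / M_second - 1), averaged over fibers with at least two
    nonzero contributions.
    """
    M = mix.M
    vals = []
    for i in range(M.shape[0]):
        row = M[i]
        if row.size < 2:
            continue
        idx = np.argpartition(row, -2)[-2:]
        second, first = np.sort(row[idx])
        if second > 0:
            vals.append(100.0 * (first / second - 1.0))
    if not vals:
        raise ValueError("no fiber has two nonzero neuron contributions")
    return float(np.mean(vals))


def scale_fluence(profile: FluenceProfile, coupled_power_uw: float) -> np.ndarray:
    """Physical excitation intensity map, mW/mm^2.

    The per-packet fluence (mm^-2) times the optical power coupled into the
    fiber (uW -> mW) gives the local excitation power density.
    """
    if coupled_power_uw <= 0:
        raise ValueError("coupled_power_uw must be positive")
    return profile.values * (coupled_power_uw * 1e-3)


def iso_contour_volume(intensity: np.ndarray, voxel_size: float,
                       level: float) -> float:
    """Volume (mm^3) of the region at or above an intensity level."""
    return float(np.count_nonzero(intensity >= level)) * voxel_size ** 3
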