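"""End-to-end scenario orchestration.

``run_scenario`` wires the stages together — single-fiber fluence profiles,
bundle + neuron sampling, mixing matrix, population activity, mixing,
separation, evaluation — repeats over iterations with deterministically
split seeds, and aggregates the separated-vs-raw accuracy comparison.

Neurons whose normalized round-trip contribution to every fiber falls below
``neuron_floor`` are not tracked as individual candidate sources: their
spikes are still Bernoulli-sampled and their contribution mixed into the
fiber signals *exactly* (via a sparse weighted accumulation of spike
events), but they are excluded from the matching pool. The mixing of the
full population is therefore exact at desk-scale memory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import sparse

import yaml

from . import _kernels
from . import bundle as bnd
from . import evaluation as ev
from . import neural as nr
from . import optics as opt
from . import separation as sep

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "ToyFixture",
    "compute_profiles",
    "run_scenario",
    "make_toy_fixture",
    "run_toy",
    "sweep_fibers",
]

# seed-stream tags, so stages can be re-run independently
_STAGE_PROFILE_EXC = 0
_STAGE_PROFILE_COL = 1
_STAGE_LAYOUT = 2
_STAGE_NEURONS = 3
_STAGE_SPIKES = 4
_STAGE_ICA = 5
_STAGE_CONTROL = 6


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of a full simulated experiment.

    Desk-scale defaults: 1e6 photon packets, 100 fibers, 600-s recordings at
    20 Hz. ``paper_scale=True`` switches to 1e7 packets.
    """

    # optics
    n_packets: int = 1_000_000
    paper_scale: bool = False
    voxel_size: float = 0.005
    grid_dims: tuple = (200, 200, 200)
    numerical_aperture: float = 0.377
    core_diameter: float = 0.0051
    # bundle
    n_fibers: int = 100
    sigma_xy: float = bnd.SIGMA_XY_DEFAULT
    sigma_z: float = bnd.SIGMA_Z_DEFAULT
    density: float = bnd.NEURON_DENSITY_DEFAULT
    box: tuple = bnd.BOX_DEFAULT
    neuron_floor: float = 1e-4
    # activity
    rate: float = nr.RATE_DEFAULT
    duration: float = 600.0
    frame_rate: float = nr.FRAME_RATE_DEFAULT
    dt: float = nr.DT_DEFAULT
    t_peak: float = nr.T_PEAK_DEFAULT
    t_half: float = nr.T_HALF_DEFAULT
    # separation
    n_components: int | None = None
    ica_max_iter: int = 700
    ica_tol: float = 1e-9
    ica_restarts: int = 1
    deconv_reg: float = 0.01
    # evaluation
    r2_threshold: float = 0.6
    r2_sweep: tuple = (0.2, 0.4, 0.6, 0.8)
    tolerance_frames: int = 2
    n_random: int | None = None
    # orchestration
    n_iterations: int = 5
    master_seed: int = 0

    def packets(self) -> int:
        return 10_000_000 if self.paper_scale else self.n_packets

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("grid_dims", "r2_sweep"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "box" in d and d["box"] is not None:
            d["box"] = tuple(tuple(b) for b in d["box"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: int, iteration: int = 0) -> int:
        ss = np.random.SeedSequence([self.master_seed, stage, iteration])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def kernel(self) -> nr.IndicatorKernel:
        return nr.gcamp_kernel(self.t_peak, self.t_half, self.dt)

    def grid(self) -> opt.VoxelGrid:
        return opt.VoxelGrid(self.voxel_size, tuple(self.grid_dims))

    def launch(self) -> opt.LaunchSpec:
        return opt.LaunchSpec(self.numerical_aperture, self.core_diameter)


@dataclass
class IterationResult:
    """Per-iteration metrics of a scenario run."""

    iteration: int
    n_foreground: int
    separated_accuracy: float
    raw_accuracy: float
    control_accuracy: float
    control_auc: float
    matched_auc: float
    sweep: list
    ica_objective: float
    ica_converged: bool


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    iterations: list
    t_stat: float
    p_value: float
    config_hash: str = ""
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [{
            "iteration": it.iteration,
            "n_foreground": it.n_foreground,
            "separated_accuracy": it.separated_accuracy,
            "raw_accuracy": it.raw_accuracy,
            "control_accuracy": it.control_accuracy,
            "control_auc": it.control_auc,
            "matched_auc": it.matched_auc,
        } for it in self.iterations]
        return pd.DataFrame(rows)

    def accuracy_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        s = np.array([it.separated_accuracy for it in self.iterations])
        r = np.array([it.raw_accuracy for it in self.iterations])
        return s, r


def compute_profiles(config: ScenarioConfig
                     ) -> tuple[opt.FluenceProfile, opt.FluenceProfile]:
    """Excitation (490 nm) and collection (512 nm) single-fiber profiles.

    Collection reuses the Monte Carlo fluence computed with the emission-
    wavelength absorption, by optical reciprocity.
    """
    grid, launch = config.grid(), config.launch()
    exc = opt.simulate_fluence(config.packets(), launch, opt.TISSUE_490, grid,
                               seed=config.stage_seed(_STAGE_PROFILE_EXC),
                               wavelength="490nm")
    col = opt.simulate_fluence(config.packets(), launch, opt.TISSUE_512, grid,
                               seed=config.stage_seed(_STAGE_PROFILE_COL),
                               wavelength="512nm")
    return exc, col


def _simulate_mixture(config: ScenarioConfig, mix: bnd.MixingMatrix,
                      iteration: int):
    """Fiber signals Y plus the foreground truth pool.

    Returns (Y TraceMatrix, X_fg TraceMatrix, fg_index).
    Foreground = neurons whose normalized column max >= neuron_floor.
    Background neurons are mixed exactly through a sparse event product.
    """
    kernel = config.kernel()
    n_bins = int(round(config.duration / config.dt))
    decim = int(round((1.0 / config.dt) / config.frame_rate))
    n_frames = n_bins // decim

    Mn = mix.normalized
    col_max = Mn.max(axis=0)
    fg = np.nonzero(col_max >= config.neuron_floor)[0]
    bg = np.nonzero(col_max < config.neuron_floor)[0]

    rng = np.random.default_rng(
        np.random.SeedSequence([config.master_seed, _STAGE_SPIKES, iteration]))

    # foreground: individually tracked sources
    src, bins = nr.sample_spike_events(fg.size, config.rate, config.duration,
                                       config.dt, rng)
    X_fg = nr.frames_from_events(src, bins, fg.size, n_bins, kernel,
                                 config.frame_rate, dtype=np.float32)
    Y = mix.M[:, fg].astype(np.float64) @ X_fg.values.astype(np.float64)

    # background: exact sparse mixing of every below-floor neuron
    if bg.size:
        M_bg = mix.M[:, bg].copy()
        M_bg[M_bg < 1e-8 * mix.normalization] = 0.0  # drop negligible weights
        csc = sparse.csc_matrix(M_bg)  # columns = background neurons
        drive_t = np.zeros((n_bins, Y.shape[0]))
        bg_seed = int(np.random.SeedSequence(
            [config.master_seed, _STAGE_SPIKES, iteration, 1]
        ).generate_state(1)[0] % (2 ** 31))
        _kernels.background_drive(bg_seed, bg.size, n_bins,
                                  config.rate * config.dt, csc.indptr,
                                  csc.indices, csc.data, drive_t)
        flor = sps.fftconvolve(drive_t.T, kernel.samples[None, :],
                               axes=1)[:, :n_bins]
        Y += flor[:, :n_frames * decim].reshape(Y.shape[0], n_frames, decim) \
            .mean(axis=2)

    Y_tm = nr.TraceMatrix(values=Y, frame_rate=config.frame_rate, role="fiber")
    return Y_tm, X_fg, fg


def run_iteration(config: ScenarioConfig,
                  profiles: tuple,
                  iteration: int) -> IterationResult:
    """One seeded realization: geometry -> mixing -> traces -> separation."""
    exc, col = profiles
    layout = bnd.sample_fiber_positions(
        config.n_fibers, config.sigma_xy, config.sigma_z,
        seed=config.stage_seed(_STAGE_LAYOUT, iteration))
    pop = bnd.sample_neuron_positions(
        config.density, config.box,
        seed=config.stage_seed(_STAGE_NEURONS, iteration))
    mix = bnd.build_mixing_matrix(layout, pop, exc, col, keep_g=False)
    mix.h = None  # recoverable as M / excitation_sums; frees desk-scale memory

    Y, X_fg, fg = _simulate_mixture(config, mix, iteration)
    kernel = config.kernel()
    n_comp = config.n_components or config.n_fibers
    res = sep.separate_sources(Y, kernel, n_components=n_comp,
                               max_iter=config.ica_max_iter,
                               tol=config.ica_tol,
                               seed=config.stage_seed(_STAGE_ICA, iteration),
                               restarts=config.ica_restarts,
                               deconv_reg=config.deconv_reg)

    sep_match = ev.match_components(res.traces, X_fg, config.r2_threshold)
    raw_match = ev.raw_fiber_accuracy(Y, X_fg, config.r2_threshold)
    ctrl_match, ctrl_aucs = ev.random_control(
        res.traces, config.rate, config.duration, config.frame_rate, kernel,
        tolerance_frames=config.tolerance_frames,
        r2_threshold=config.r2_threshold, n_random=config.n_random,
        seed=config.stage_seed(_STAGE_CONTROL, iteration))
    sweep = ev.threshold_sweep_roc(res.traces, X_fg, kernel,
                                   config.frame_rate, config.r2_sweep,
                                   tolerance_frames=config.tolerance_frames)
    matched_aucs = [row["mean_auc"] for row in sweep
                    if row["r2_threshold"] == config.r2_threshold]
    matched_auc = matched_aucs[0] if matched_aucs else float("nan")
    return IterationResult(
        iteration=iteration, n_foreground=int(fg.size),
        separated_accuracy=sep_match.accuracy,
        raw_accuracy=raw_match.accuracy,
        control_accuracy=ctrl_match.accuracy,
        control_auc=float(np.mean(ctrl_aucs)) if ctrl_aucs.size else float("nan"),
        matched_auc=matched_auc, sweep=sweep,
        ica_objective=float(res.objective[-1]),
        ica_converged=bool(res.converged))


def run_scenario(config: ScenarioConfig, profiles: tuple | None = None,
                 outdir=None) -> ScenarioResult:
    """Run ``config.n_iterations`` seeded realizations and aggregate.

    ``profiles`` may carry precomputed (excitation, collection) fluence
    profiles to reuse across scenarios. With ``outdir`` set, the per-
    iteration summary and the config are written there as text artifacts.
    """
    if profiles is None:
        profiles = compute_profiles(config)
    iterations = [run_iteration(config, profiles, i)
                  for i in range(config.n_iterations)]
    s_acc = [it.separated_accuracy for it in iterations]
    r_acc = [it.raw_accuracy for it in iterations]
    if len(iterations) >= 2:
        t, p = ev.paired_improvement_test(s_acc, r_acc)
    else:
        t, p = float("nan"), float("nan")
    result = ScenarioResult(config=config, iterations=iterations, t_stat=t,
                            p_value=p, config_hash=config.config_hash(),
                            meta={"master_seed": config.master_seed})
    if outdir is not None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        result.summary().to_csv(out / "iterations.csv", index=False)
        config.save(out / "config.yaml")
        with open(out / "aggregate.json", "w") as fh:
            json.dump({"t_stat": t, "p_value": p,
                       "mean_separated_accuracy": float(np.mean(s_acc)),
                       "sd_separated_accuracy": float(np.std(s_acc, ddof=1))
                       if len(s_acc) > 1 else 0.0,
                       "mean_raw_accuracy": float(np.mean(r_acc)),
                       "config_hash": result.config_hash,
                       "master_seed": config.master_seed}, fh, indent=1)
    return result


# ---------------------------------------------------------------------------
# Toy fixture: a deterministic three-fiber / three-neuron demonstration with
# an analytic Gaussian sensitivity falloff standing in for the Monte Carlo
# profile, so the whole separation path runs in seconds.

@dataclass
class ToyFixture:
    fiber_positions: np.ndarray      # (3, 3) mm
    neuron_positions: np.ndarray     # (3, 3) mm, foreground
    background_positions: np.ndarray
    mixing: bnd.MixingMatrix


def _toy_sensitivity(tips: np.ndarray, points: np.ndarray,
                     sigma: float = 0.04, z_offset: float = 0.03) -> np.ndarray:
    """Analytic Gaussian falloff ahead of each tip; (n_tips, n_points)."""
    d = points[None, :, :] - tips[:, None, :]
    d = d - np.array([0.0, 0.0, z_offset])
    return np.exp(-np.sum(d * d, axis=2) / (2 * sigma ** 2))


def make_toy_fixture(n_background: int = 60) -> ToyFixture:
    """Three fibers, three nearby neurons, and a distant background cloud."""
    fibers = np.array([[-0.06, 0.0, 0.0], [0.0, 0.0, 0.01], [0.06, 0.0, -0.01]])
    neurons = np.array([[-0.065, 0.01, 0.035], [0.005, -0.01, 0.045],
                        [0.06, 0.005, 0.025]])
    rng = np.random.default_rng(1234)
    bg = np.empty((n_background, 3))
    bg[:, 0] = rng.uniform(-0.35, 0.35, n_background)
    bg[:, 1] = rng.uniform(-0.35, 0.35, n_background)
    bg[:, 2] = rng.uniform(0.18, 0.45, n_background)
    pts = np.vstack([neurons, bg])
    g = _toy_sensitivity(fibers, pts).T          # (neurons, fibers)
    h = _toy_sensitivity(fibers, pts)            # (fibers, neurons)
    M = h * g.sum(axis=1)[None, :]
    mix = bnd.MixingMatrix(M=M, h=h, g=g, excitation_sums=g.sum(axis=1),
                           normalization=1.0, meta={"toy": True})
    return ToyFixture(fiber_positions=fibers, neuron_positions=neurons,
                      background_positions=bg, mixing=mix)


def run_toy(duration: float = 120.0, seed: int = 0,
            frame_rate: float = nr.FRAME_RATE_DEFAULT):
    """Simulate and separate the toy configuration.

    Returns (separation result, match result, true foreground TraceMatrix).
    """
    toy = make_toy_fixture()
    kernel = nr.gcamp_kernel()
    n_all = toy.mixing.n_neurons
    spikes = nr.simulate_spike_trains(n_all, nr.RATE_DEFAULT, duration,
                                      kernel.dt, seed=seed)
    X = nr.convolve_and_frame(spikes, kernel, frame_rate)
    Y = nr.mix_traces(toy.mixing, X)
    res = sep.separate_sources(Y, kernel, n_components=3, seed=seed,
                               restarts=3)
    X_fg = nr.TraceMatrix(values=X.values[:3], frame_rate=frame_rate,
                          role="neural")
    match = ev.match_components(res.traces, X_fg)
    return res, match, X_fg


def sweep_fibers(config: ScenarioConfig, fiber_counts,
                 profiles: tuple | None = None, n_seeds: int = 5,
                 thresholds=(0.005, 0.01, 0.02, 0.05)) -> pd.DataFrame:
    """Interface visibility versus bundle size.

    For each fiber count, averages the visibility statistics over
    ``n_seeds`` independently sampled bundle layouts (neuron population
    re-sampled per seed as well). Returns a tidy DataFrame with one row per
    (fiber count, threshold).
    """
    fiber_counts = list(fiber_counts)
    if len(fiber_counts) < 2:
        raise ValueError("need at least two fiber counts to sweep")
    if profiles is None:
        profiles = compute_profiles(config)
    exc, col = profiles
    rows = []
    for n_fib in fiber_counts:
        acc = {thr: {"n_ge1": [], "n_ge2": [], "per_fiber": []}
               for thr in thresholds}
        for s in range(n_seeds):
            layout = bnd.sample_fiber_positions(
                n_fib, config.sigma_xy, config.sigma_z,
                seed=config.stage_seed(_STAGE_LAYOUT, 1000 * s + n_fib))
            pop = bnd.sample_neuron_positions(
                config.density, config.box,
                seed=config.stage_seed(_STAGE_NEURONS, 1000 * s + n_fib))
            mix = bnd.build_mixing_matrix(layout, pop, exc, col, keep_g=False)
            for st in bnd.visibility_stats(mix, thresholds):
                a = acc[st["threshold"]]
                a["n_ge1"].append(st["n_ge1"])
                a["n_ge2"].append(st["n_ge2"])
                a["per_fiber"].append(st["mean_per_fiber"])
        for thr in thresholds:
            a = acc[thr]
            rows.append({"n_fibers": n_fib, "threshold": thr,
                         "mean_n_ge1": float(np.mean(a["n_ge1"])),
                         "mean_n_ge2": float(np.mean(a["n_ge2"])),
                         "mean_per_fiber": float(np.mean(a["per_fiber"])),
                         "n_seeds": n_seeds})
    return pd.DataFrame(rows)
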