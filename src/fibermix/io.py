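"""HDF5 persistence for the simulation artifacts.

Each container maps to one HDF5 group/file with named datasets and the
metadata (seeds, parameters) stored as attributes, so every artifact is
traceable to the configuration that produced it.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .bundle import FiberBundleLayout, MixingMatrix, NeuronPopulation
from .neural import TraceMatrix
from .optics import FluenceProfile, VoxelGrid
from .separation import SeparationResult

__all__ = [
    "save_profile", "load_profile",
    "save_layout", "load_layout",
    "save_population", "load_population",
    "save_mixing", "load_mixing",
    "save_traces", "load_traces",
    "save_separation", "load_separation",
]


def save_profile(path, profile: FluenceProfile) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=profile.values, compression="gzip")
        f.attrs["voxel_size"] = profile.grid.voxel_size
        f.attrs["dims"] = profile.grid.dims
        f.attrs["extent"] = profile.grid.extent
        f.attrs["wavelength"] = profile.wavelength
        f.attrs["n_packets"] = profile.n_packets
        f.attrs["seed"] = profile.seed
        f.attrs["bookkeeping"] = json.dumps(profile.bookkeeping)


def load_profile(path) -> FluenceProfile:
    with h5py.File(path, "r") as f:
        grid = VoxelGrid(float(f.attrs["voxel_size"]),
                         tuple(int(d) for d in f.attrs["dims"]))
        return FluenceProfile(
            grid=grid, values=f["values"][...],
            wavelength=str(f.attrs["wavelength"]),
            n_packets=int(f.attrs["n_packets"]), seed=int(f.attrs["seed"]),
            bookkeeping=json.loads(f.attrs.get("bookkeeping", "{}")))


def save_layout(path, layout: FiberBundleLayout) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=layout.positions)
        f.attrs["sigma_xy"] = layout.sigma_xy
        f.attrs["sigma_z"] = layout.sigma_z
        f.attrs["seed"] = layout.seed


def load_layout(path) -> FiberBundleLayout:
    with h5py.File(path, "r") as f:
        return FiberBundleLayout(positions=f["positions"][...],
                                 sigma_xy=float(f.attrs["sigma_xy"]),
                                 sigma_z=float(f.attrs["sigma_z"]),
                                 seed=int(f.attrs["seed"]))


def save_population(path, pop: NeuronPopulation) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=pop.positions)
        f.attrs["density"] = pop.density
        f.attrs["box"] = np.asarray(pop.box)
        f.attrs["seed"] = pop.seed


def load_population(path) -> NeuronPopulation:
    with h5py.File(path, "r") as f:
        box = tuple(tuple(float(x) for x in b) for b in f.attrs["box"])
        return NeuronPopulation(positions=f["positions"][...],
                                density=float(f.attrs["density"]),
                                box=box, seed=int(f.attrs["seed"]))


def save_mixing(path, mix: MixingMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("M", data=mix.M, compression="gzip")
        f.create_dataset("excitation_sums", data=mix.excitation_sums)
        if mix.h is not None:
            f.create_dataset("h", data=mix.h, compression="gzip")
        if mix.g is not None:
            f.create_dataset("g", data=mix.g, compression="gzip")
        f.attrs["normalization"] = mix.normalization
        f.attrs["meta"] = json.dumps(mix.meta, default=float)


def load_mixing(path) -> MixingMatrix:
    with h5py.File(path, "r") as f:
        return MixingMatrix(
            M=f["M"][...],
            h=f["h"][...] if "h" in f else None,
            g=f["g"][...] if "g" in f else None,
            excitation_sums=f["excitation_sums"][...],
            normalization=float(f.attrs["normalization"]),
            meta=json.loads(f.attrs.get("meta", "{}")))


def save_traces(path, traces: TraceMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=traces.values, compression="gzip")
        f.attrs["frame_rate"] = traces.frame_rate
        f.attrs["role"] = traces.role
        f.attrs["meta"] = json.dumps(traces.meta, default=float)


def load_traces(path) -> TraceMatrix:
    with h5py.File(path, "r") as f:
        return TraceMatrix(values=f["values"][...],
                           frame_rate=float(f.attrs["frame_rate"]),
                           role=str(f.attrs["role"]),
                           meta=json.loads(f.attrs.get("meta", "{}")))


def save_separation(path, res: SeparationResult) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sources", data=res.sources, compression="gzip")
        if res.traces is not None:
            f.create_dataset("traces", data=res.traces, compression="gzip")
        f.create_dataset("unmixing", data=res.unmixing)
        f.create_dataset("rotation", data=res.rotation)
        f.create_dataset("whitening", data=res.whitening)
        f.create_dataset("mean", data=res.mean)
        f.create_dataset("objective", data=res.objective)
        f.attrs["n_iter"] = res.n_iter
        f.attrs["converged"] = res.converged
        f.attrs["seed"] = res.seed
        f.attrs["meta"] = json.dumps(res.meta, default=float)


def load_separation(path) -> SeparationResult:
    with h5py.File(path, "r") as f:
        return SeparationResult(
            sources=f["sources"][...],
            traces=f["traces"][...] if "traces" in f else None,
            unmixing=f["unmixing"][...], rotation=f["rotation"][...],
            whitening=f["whitening"][...], mean=f["mean"][...],
            objective=f["objective"][...], n_iter=int(f.attrs["n_iter"]),
            converged=bool(f.attrs["converged"]), seed=int(f.attrs["seed"]),
            meta=json.loads(f.attrs.get("meta", "{}")))
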