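"""Forward model for the magnitude multi-echo signal of one voxel."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import AcquisitionProtocol, DEFAULT_PROTOCOL
from .spectrum import TriglycerideComposition, modulation_array


@dataclass(frozen=True)
class VoxelSignalParams:
    """Water/fat amplitudes, shared R2* decay and fat composition of a voxel.

    Amplitudes are in arbitrary proton-signal units; ``r2star`` in 1/s.  A
    single R2* is shared by water and fat: ten magnitude echoes cannot
    support separate decays robustly.
    """

    water: float
    fat: float
    r2star: float
    composition: TriglycerideComposition

    def __post_init__(self) -> None:
        if self.water < 0 or self.fat < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.r2star < 0:
            raise ValueError("r2star must be non-negative")


@dataclass(frozen=True)
class EchoSeries:
    """Magnitude signal sampled at the protocol's echo times."""

    values: np.ndarray
    protocol: AcquisitionProtocol = DEFAULT_PROTOCOL

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.protocol.n_echoes,):
            raise ValueError(
                f"expected {self.protocol.n_echoes} echo values, got {vals.shape}"
            )
        if np.any(vals < 0):
            raise ValueError("magnitude signal cannot be negative")
        object.__setattr__(self, "values", vals)


def model_signal(
    water,
    fat,
    ndb,
    r2star,
    protocol: AcquisitionProtocol = DEFAULT_PROTOCOL,
    cl: float | None = None,
) -> np.ndarray:
    """Noiseless magnitude signal at every echo time.

    ``|water + fat * m(te; ndb)| * exp(-r2star * te / 1000)`` with ``m`` the
    chemical-shift dephasing of the nine-peak fat spectrum (te in ms, r2star
    in 1/s).  Broadcasts over array-valued parameters (echo axis first).
    """
    from .spectrum import DEFAULT_CL

    cl = DEFAULT_CL if cl is None else cl
    tes = protocol.tes_array()
    ndb = np.asarray(ndb, dtype=float)
    m = modulation_array(ndb, protocol, tes, cl=cl)  # (n_te,) + ndb.shape
    water = np.asarray(water, dtype=float)[None, ...]
    fat = np.asarray(fat, dtype=float)[None, ...]
    r2 = np.asarray(r2star, dtype=float)[None, ...]
    shape = (len(tes),) + (1,) * (m.ndim - 1)
    decay = np.exp(-r2 * tes.reshape(shape) / 1000.0)
    out = np.abs(water + fat * m) * decay
    return out


def simulate_signal(
    params: VoxelSignalParams,
    protocol: AcquisitionProtocol = DEFAULT_PROTOCOL,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> EchoSeries:
    """Simulate a magnitude echo series, optionally with Rician noise.

    Independent Gaussian noise of standard deviation ``noise_sd`` is added to
    the real and imaginary channels of the complex signal before taking the
    magnitude, which yields Rician-distributed magnitude data.  Deterministic
    given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    tes = protocol.tes_array()
    comp = params.composition
    m = modulation_array(np.asarray(comp.ndb), protocol, tes, cl=comp.cl)
    decay = np.exp(-params.r2star * tes / 1000.0)
    cplx = (params.water + params.fat * m) * decay
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=(2, len(tes)))
        cplx = cplx + noise[0] + 1j * noise[1]
    return EchoSeries(values=np.abs(cplx), protocol=protocol)
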