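"""Acquisition protocol for the multi-echo chemical-shift sequence."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Gyromagnetic ratio of the proton, MHz/T. Converts ppm at a given field
#: strength into Hz of chemical-shift off-resonance.
GYROMAGNETIC_MHZ_PER_T = 42.577

#: Echo times (ms) of the single-slice multiecho abdominal protocol at 1.5 T.
MULTIECHO_TES_MS = (
    2.38, 4.76, 7.15, 9.53, 11.91, 14.29, 16.67, 19.06, 21.44, 23.82,
)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Parameters of the multi-echo gradient-echo acquisition.

    ``repetition_time`` and ``flip_angle`` are carried for provenance only;
    the magnitude signal model used here has no T1 term.
    """

    field_strength: float = 1.5
    echo_times: tuple[float, ...] = MULTIECHO_TES_MS
    repetition_time: float = 27.0
    flip_angle: float = 20.0
    water_ppm: float = 4.7

    def __post_init__(self) -> None:
        tes = np.asarray(self.echo_times, dtype=float)
        if tes.ndim != 1 or tes.size == 0:
            raise ValueError("echo_times must be a non-empty 1-D sequence")
        if np.any(tes <= 0):
            raise ValueError("echo times must be strictly positive")
        if np.any(np.diff(tes) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.field_strength <= 0:
            raise ValueError("field_strength must be positive")
        object.__setattr__(self, "echo_times", tuple(float(t) for t in tes))

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    def tes_array(self) -> np.ndarray:
        return np.asarray(self.echo_times, dtype=float)


#: The default protocol: 1.5 T, the ten multiecho TEs, TR 27 ms, flip 20 deg.
DEFAULT_PROTOCOL = AcquisitionProtocol()
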