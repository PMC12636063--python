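"""Triglyceride proton spectrum as a function of composition.

A triglyceride molecule is summarized by three numbers: NDB, the mean number
of double bonds; NMIDB, the mean number of methylene-interrupted double bonds
(the diallylic pattern characteristic of polyunsaturation); and CL, the mean
fatty-acid chain length in carbons.  The standard nine-peak proton model
assigns to each spectral line a chemical shift (ppm) and a proton count that
is linear in (NDB, NMIDB, CL).  NMIDB is tied to NDB through the empirical
constraint ``NMIDB = 0.093 * NDB**2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import AcquisitionProtocol, GYROMAGNETIC_MHZ_PER_T

#: Empirical coefficient tying methylene-interrupted double bonds to NDB.
NMIDB_COEFF = 0.093

#: Chemical shifts (ppm) of the nine triglyceride proton resonances.
PEAK_SHIFTS_PPM = np.array([5.3, 5.2, 4.2, 2.75, 2.2, 2.0, 1.6, 1.3, 0.9])

PEAK_NAMES = (
    "olefinic",          # -CH=CH-
    "glycerol_methine",  # glycerol backbone CH
    "glycerol_methylene",  # glycerol backbone CH2 x2
    "diallylic",         # =CH-CH2-CH= (methylene-interrupted)
    "alpha_carboxyl",    # -CO-CH2-
    "alpha_olefinic",    # -CH2-CH=CH-CH2-
    "beta_carboxyl",     # -CO-CH2-CH2-
    "methylene",         # bulk -(CH2)n-
    "methyl",            # terminal -CH3
)

# Proton count of peak p is  alpha_p(cl) + beta_p * ndb + gamma_p * nmidb.
_BETA = np.array([2.0, 0.0, 0.0, 0.0, 0.0, 4.0, 0.0, -8.0, 0.0])
_GAMMA = np.array([0.0, 0.0, 0.0, 2.0, 0.0, -4.0, 0.0, 2.0, 0.0])


def _alpha(cl: float) -> np.ndarray:
    return np.array([0.0, 1.0, 4.0, 0.0, 6.0, 0.0, 6.0, 6.0 * (cl - 4.0), 9.0])


#: Default mean fatty-acid chain length (carbons); fixed, not co-estimated.
DEFAULT_CL = 17.4


def nmidb_from_ndb(ndb):
    """Methylene-interrupted double bonds implied by NDB.

    Uses the empirical constraint ``NMIDB = 0.093 * NDB**2``; monotone
    increasing on the admissible range.
    """
    ndb = np.asarray(ndb, dtype=float)
    if np.any(ndb < 0):
        raise ValueError("ndb must be non-negative")
    out = NMIDB_COEFF * ndb**2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TriglycerideComposition:
    """Composition of the triglyceride pool in one voxel.

    ``nmidb=None`` fills in the empirical constraint from ``ndb``.
    """

    ndb: float
    nmidb: float | None = None
    cl: float = DEFAULT_CL

    def __post_init__(self) -> None:
        if self.ndb < 0:
            raise ValueError("ndb must be non-negative")
        if self.nmidb is None:
            object.__setattr__(self, "nmidb", nmidb_from_ndb(self.ndb))
        if not 0 <= self.nmidb <= max(self.ndb, 1e-12) and self.nmidb != 0:
            raise ValueError("nmidb must lie in [0, ndb]")
        if self.cl <= 4:
            raise ValueError("chain length must exceed 4 carbons")


@dataclass(frozen=True)
class SpectralPeak:
    shift_ppm: float
    protons: float


def _amplitudes(ndb, nmidb, cl):
    return _alpha(cl)[:, None] + _BETA[:, None] * ndb + _GAMMA[:, None] * nmidb


def peak_amplitudes(comp: TriglycerideComposition) -> list[SpectralPeak]:
    """Proton count per spectral peak for one composition.

    Raises if the composition drives any proton count negative (possible for
    extreme NDB at short chain length).
    """
    amps = _amplitudes(
        np.atleast_1d(comp.ndb), np.atleast_1d(comp.nmidb), comp.cl
    )[:, 0]
    if np.any(amps < 0):
        bad = [PEAK_NAMES[i] for i in np.nonzero(amps < 0)[0]]
        raise ValueError(f"composition yields negative proton count for: {bad}")
    return [
        SpectralPeak(float(s), float(a)) for s, a in zip(PEAK_SHIFTS_PPM, amps)
    ]


def total_protons(comp: TriglycerideComposition) -> float:
    """Closed-form total proton count, 6*CL - 2*NDB + 2."""
    return 6.0 * comp.cl - 2.0 * comp.ndb + 2.0


def _phase_matrix(protocol: AcquisitionProtocol, te_ms) -> np.ndarray:
    """exp(i * 2*pi * df_p * te) for each (te, peak); te in ms, df in Hz."""
    df_hz = (
        (PEAK_SHIFTS_PPM - protocol.water_ppm)
        * GYROMAGNETIC_MHZ_PER_T
        * protocol.field_strength
    )
    te_s = np.atleast_1d(np.asarray(te_ms, dtype=float))[:, None] * 1e-3
    return np.exp(2j * np.pi * df_hz[None, :] * te_s)


def modulation_array(ndb, protocol: AcquisitionProtocol, te_ms, cl=DEFAULT_CL):
    """Complex fat dephasing factor for arrays of ndb and echo times.

    Returns an array of shape ``(n_te,) + ndb.shape``: the proton-weighted
    mean phasor over the nine peaks, normalized so the value at te=0 is 1.
    """
    ndb = np.asarray(ndb, dtype=float)
    nmidb = NMIDB_COEFF * ndb**2
    ph = _phase_matrix(protocol, te_ms)  # (n_te, 9)
    alpha = _alpha(cl)
    # numerator coefficients: sum_p (alpha + beta*ndb + gamma*nmidb) e^{i phi}
    c0 = ph @ alpha
    c1 = ph @ _BETA
    c2 = ph @ _GAMMA
    shape = (len(c0),) + (1,) * ndb.ndim
    num = (
        c0.reshape(shape)
        + c1.reshape(shape) * ndb[None, ...]
        + c2.reshape(shape) * nmidb[None, ...]
    )
    total = 6.0 * cl - 2.0 * ndb + 2.0
    return num / total[None, ...]


def modulation_and_derivative(ndb, protocol, te_ms, cl=DEFAULT_CL):
    """Modulation and its analytic derivative with respect to ndb.

    d(nmidb)/d(ndb) = 2 * 0.093 * ndb; the total proton count has slope -2.
    """
    ndb = np.asarray(ndb, dtype=float)
    nmidb = NMIDB_COEFF * ndb**2
    dnmidb = 2.0 * NMIDB_COEFF * ndb
    ph = _phase_matrix(protocol, te_ms)
    alpha = _alpha(cl)
    c0, c1, c2 = ph @ alpha, ph @ _BETA, ph @ _GAMMA
    shape = (len(c0),) + (1,) * ndb.ndim
    num = (
        c0.reshape(shape)
        + c1.reshape(shape) * ndb[None, ...]
        + c2.reshape(shape) * nmidb[None, ...]
    )
    dnum = c1.reshape(shape) + c2.reshape(shape) * dnmidb[None, ...]
    total = 6.0 * cl - 2.0 * ndb + 2.0
    m = num / total[None, ...]
    dm = dnum / total[None, ...] + 2.0 * num / (total**2)[None, ...]
    return m, dm


def fat_modulation(
    comp: TriglycerideComposition,
    protocol: AcquisitionProtocol,
    te_ms: float,
) -> complex:
    """Complex chemical-shift dephasing of the fat signal at one echo time.

    Proton-amplitude-weighted sum of the nine peak phasors, normalized by the
    total proton count; exactly 1 at te=0 and of modulus <= 1 always.
    """
    if te_ms < 0:
        raise ValueError("te must be non-negative")
    ph = _phase_matrix(protocol, [te_ms])[0]
    amps = np.array([p.protons for p in peak_amplitudes(comp)])
    return complex(np.sum(amps * ph) / np.sum(amps))
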