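"""Lobe-contribution reassignment of elliptic Fourier harmonics.

Each EFA harmonic ellipse is the sum of two counter-rotating circles
("rotors"). Riding on a counter-clockwise base circle, a CCW rotor of
harmonic n modulates the radius at spatial frequency n-1, while a CW rotor
of harmonic n modulates it at frequency n+1. Regrouping rotors by the
radial frequency they actually draw yields lobe-number modes: mode l
collects the CCW rotor of harmonic l+1 and the CW rotor of harmonic l-1,
and its scalar amplitude L_l measures the strength of l-fold radial
features directly (in units of the equivalent-circle radius after area
normalisation).

Phase conventions: both rotor phases are starting angular positions,
measured counter-clockwise from the +x axis, i.e. the CCW rotor traces
lambda+ * exp(i(n w t + phi+)) and the CW rotor lambda- * exp(i(phi- - n w t)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contours import Contour
from .efa import EFACoefficients

__all__ = [
    "RotorPair",
    "LocoMode",
    "LocoSpectrum",
    "decompose_rotors",
    "rotors_to_harmonics",
    "canonical_phase",
    "assign_modes",
    "compute_L",
    "loco_spectrum",
    "loco_reconstruct",
]


@dataclass
class RotorPair:
    """The two counter-rotating circles of one EFA harmonic."""

    n: int
    lambda_plus: float
    lambda_minus: float
    phi_plus: float
    phi_minus: float


@dataclass
class _RotorTerm:
    """One circle owned by a lobe mode: radius, start angle, harmonic, sense."""

    radius: float
    phase: float
    harmonic: int
    sense: int  # +1 CCW, -1 CW


@dataclass
class LocoMode:
    """One lobe-number mode and the rotors it owns.

    For l >= 2 the mode owns the CCW rotor of harmonic l+1 and the CW
    rotor of harmonic l-1. Mode 1 is the consistent limit of that rule:
    its "cw slot" holds the base circle (the dominant CCW rotor of
    harmonic 1) and its ccw slot the CCW rotor of harmonic 2.
    """

    l: int
    ccw: _RotorTerm | None
    cw: _RotorTerm | None

    @property
    def r_ccw(self) -> float:
        return self.ccw.radius if self.ccw else 0.0

    @property
    def r_cw(self) -> float:
        return self.cw.radius if self.cw else 0.0

    @property
    def phase_ccw(self) -> float:
        return self.ccw.phase if self.ccw else 0.0

    @property
    def phase_cw(self) -> float:
        return self.cw.phase if self.cw else 0.0


@dataclass
class LocoSpectrum:
    """Lobe-mode amplitudes L_l plus the rotors behind them."""

    modes: list[LocoMode]
    L: np.ndarray  # amplitude per mode, index l-1
    zeta: float  # mode-1 reference phase after canonicalisation
    offset: np.ndarray  # EFA DC term, owned by no mode
    perimeter: float
    normalisation: float = 1.0  # area scale applied upstream
    tau: float = 0.0  # starting-point shift (radians of w*t) applied by canonical_phase

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def mode_amplitudes(self, L_max: int) -> np.ndarray:
        """L_1..L_{L_max}, zero-padded past the truncation."""
        out = np.zeros(L_max)
        k = min(L_max, len(self.L))
        out[:k] = self.L[:k]
        return out

    def argmax_lobe(self, l_min: int = 2) -> int:
        """Mode with the largest amplitude among l >= l_min (lowest wins ties)."""
        sub = self.L[l_min - 1:]
        return int(np.argmax(sub)) + l_min

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "l": [m.l for m in self.modes],
                "L": self.L,
                "r_ccw": [m.r_ccw for m in self.modes],
                "r_cw": [m.r_cw for m in self.modes],
                "phase_ccw": [m.phase_ccw for m in self.modes],
                "phase_cw": [m.phase_cw for m in self.modes],
            }
        )

    def to_json(self) -> str:
        """Self-contained per-cell bundle (modes, zeta, normalisation)."""
        import json

        return json.dumps(
            {
                "zeta": self.zeta,
                "tau": self.tau,
                "offset": list(self.offset),
                "perimeter": self.perimeter,
                "normalisation": self.normalisation,
                "modes": self.to_dataframe().to_dict(orient="records"),
            }
        )


def decompose_rotors(coef: EFACoefficients) -> list[RotorPair]:
    """Split every harmonic into its CCW and CW circles (exact round-trip).

    lambda+ e^{i phi+} = ((a+d) + i(c-b)) / 2,
    lambda- e^{i phi-} = ((a-d) + i(c+b)) / 2.
    """
    out = []
    for i, (a, b, c, d) in enumerate(coef.harmonics, start=1):
        zp = complex(a + d, c - b) / 2.0
        zm = complex(a - d, c + b) / 2.0
        out.append(
            RotorPair(
                n=i,
                lambda_plus=abs(zp),
                lambda_minus=abs(zm),
                phi_plus=float(np.arctan2(zp.imag, zp.real)),
                phi_minus=float(np.arctan2(zm.imag, zm.real)),
            )
        )
    return out


def rotors_to_harmonics(rotors: list[RotorPair]) -> np.ndarray:
    """Inverse of :func:`decompose_rotors`: (N, 4) rows (a, b, c, d)."""
    rows = []
    for r in rotors:
        zp = r.lambda_plus * np.exp(1j * r.phi_plus)
        zm = r.lambda_minus * np.exp(1j * r.phi_minus)
        a = zp.real + zm.real
        d = zp.real - zm.real
        c = zp.imag + zm.imag
        b = zm.imag - zp.imag
        rows.append([a, b, c, d])
    return np.asarray(rows)


def canonical_phase(rotors: list[RotorPair]) -> tuple[list[RotorPair], float]:
    """Remove the starting-point ambiguity of the traversal.

    The same outline entered at a different starting vertex differs only by
    a parameter shift t -> t + tau, which advances phi+_n by n*w*tau and
    retards phi-_n by the same amount. Re-parameterising so the dominant
    (CCW) rotor of harmonic 1 starts at angle zero makes the decomposition
    unique. Returns the shifted rotors and zeta, the residual mode-1
    reference phase entering the L_l formula (zero by construction).
    """
    if not rotors or rotors[0].n != 1:
        raise ValueError("rotor list must start at harmonic 1")
    r1 = rotors[0]
    if r1.lambda_plus == 0.0 and r1.lambda_minus == 0.0:
        raise ValueError("degenerate first harmonic")
    if r1.lambda_minus > r1.lambda_plus:
        raise ValueError(
            "clockwise-dominant first harmonic; canonicalise the contour to CCW first"
        )
    tau = -r1.phi_plus  # in units of w*t
    shifted = [
        RotorPair(
            n=r.n,
            lambda_plus=r.lambda_plus,
            lambda_minus=r.lambda_minus,
            phi_plus=_wrap(r.phi_plus + r.n * tau),
            phi_minus=_wrap(r.phi_minus - r.n * tau),
        )
        for r in rotors
    ]
    zeta = shifted[0].phi_plus  # 0 by construction
    return shifted, zeta


def _wrap(phi: float) -> float:
    return float(np.arctan2(np.sin(phi), np.cos(phi)))


def assign_modes(rotors: list[RotorPair]) -> list[LocoMode]:
    """Regroup rotors by the radial frequency they draw.

    With N harmonics available, modes l = 1..N+1 are produced; the last
    two carry only the boundary CW rotors (harmonics N-1, N), so that the
    rotor content of the harmonic series is conserved exactly. Reported
    spectra conventionally use modes 1..N-1.
    """
    by_n = {r.n: r for r in rotors}
    N = max(by_n)
    modes: list[LocoMode] = []
    for l in range(1, N + 2):
        if l == 1:
            base = by_n[1]
            cw = _RotorTerm(base.lambda_plus, base.phi_plus, 1, +1)
            ccw = None
            if 2 in by_n:
                ccw = _RotorTerm(by_n[2].lambda_plus, by_n[2].phi_plus, 2, +1)
        else:
            cw = None
            if (l - 1) in by_n:
                r = by_n[l - 1]
                cw = _RotorTerm(r.lambda_minus, r.phi_minus, l - 1, -1)
            ccw = None
            if (l + 1) in by_n and l + 1 >= 3:
                r = by_n[l + 1]
                ccw = _RotorTerm(r.lambda_plus, r.phi_plus, l + 1, +1)
        modes.append(LocoMode(l=l, ccw=ccw, cw=cw))
    return modes


def compute_L(
    modes: list[LocoMode],
    zeta: float,
    offset: np.ndarray | None = None,
    perimeter: float = 2 * np.pi,
    normalisation: float = 1.0,
    tau: float = 0.0,
) -> LocoSpectrum:
    """Combine each mode's two rotors into a scalar amplitude.

    Seen from the mode-1 starting point, the two rotors of mode l both
    draw an l-fold cosine on the radius; their phase offsets there are
    phi+_{l+1} - zeta and zeta - phi-_{l-1}, so the combined amplitude is
    the law-of-cosines sum

        L_l = sqrt(r_ccw^2 + r_cw^2 + 2 r_ccw r_cw cos(Delta_l)),
        Delta_l = phase_ccw + phase_cw - 2 zeta,

    which reduces to the single rotor radius when the other vanishes and
    is invariant to rigid rotation and to the contour's starting vertex.
    """
    L = np.empty(len(modes))
    for i, m in enumerate(modes):
        delta = m.phase_ccw + m.phase_cw - 2.0 * zeta
        val = (
            m.r_ccw**2
            + m.r_cw**2
            + 2.0 * m.r_ccw * m.r_cw * np.cos(delta)
        )
        L[i] = np.sqrt(max(val, 0.0))
    return LocoSpectrum(
        modes=modes,
        L=L,
        zeta=zeta,
        offset=np.zeros(2) if offset is None else np.asarray(offset, float),
        perimeter=perimeter,
        normalisation=normalisation,
        tau=tau,
    )


def loco_spectrum(coef: EFACoefficients) -> LocoSpectrum:
    """Full chain: rotors -> canonical phase -> mode assignment -> L_l."""
    rotors = decompose_rotors(coef)
    tau = -rotors[0].phi_plus
    rotors, zeta = canonical_phase(rotors)
    modes = assign_modes(rotors)
    return compute_L(
        modes,
        zeta,
        offset=coef.offset,
        perimeter=coef.perimeter,
        normalisation=coef.scale,
        tau=tau,
    )


def loco_reconstruct(
    spectrum: LocoSpectrum, N_use: int, n_samples: int
) -> Contour:
    """Reconstruct the outline from lobe modes 1..N_use (offset included).

    Adding mode l changes only the l-fold radial feature content; using
    every available mode reproduces the full elliptic-harmonic
    reconstruction exactly, because mode assignment conserves rotors.
    """
    if not (1 <= N_use <= spectrum.n_modes):
        raise ValueError(f"N_use must be in 1..{spectrum.n_modes}")
    t = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
    z = np.full(n_samples, spectrum.offset[0] + 1j * spectrum.offset[1], dtype=complex)
    for m in spectrum.modes[:N_use]:
        for term in (m.ccw, m.cw):
            if term is None or term.radius == 0.0:
                continue
            z += term.radius * np.exp(
                1j * (term.sense * term.harmonic * t + term.phase)
            )
    return Contour(np.column_stack([z.real, z.imag]))
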