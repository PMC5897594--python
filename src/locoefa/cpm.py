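"""Cellular Potts model (CPM) with lobe, elongation and roundness forces.

Cells are domains of equal ID on a square lattice evolving by
Metropolis-style boundary copy events. The base Hamiltonian is

    H = J * (# unlike Moore-neighbour pairs)
        + sum_c [ lambda_a (a_c - A)^2 + lambda_p (p_c - P)^2 ],

with a_c the cell area (site count) and p_c the perimeter counted as
unlike second-order (Moore) neighbour pairs per cell. A copy event that
lowers H by at least the yield Y is always accepted; otherwise it is
accepted with Boltzmann probability exp(-(dH + Y)/T).

On top of that, three cell-specific terms bias each copy event to sculpt
the cell towards a specified shape: a lobe term -s*nu*cos(n*theta) that
favours extension along n equally spaced target directions, an elongation
term -s*chi*cos(2*alpha) along a bipolar axis, and a roundness term
+s*mu*sign(r-R)*(r-R)^2 that resists excursions beyond the equivalent
radius R = sqrt(A/pi) (and retraction inside it), keeping cells coherent.
Here s = +1 when the cell under evaluation gains the site and -1 when it
loses it; theta/alpha/r are measured on the copy vector from the cell's
centre of mass to the evaluated site. Target directions are re-anchored
every 100 Monte Carlo steps to the cell's current strongest extensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy import ndimage

from .contours import LabelImage

logger = logging.getLogger(__name__)

__all__ = ["CPMParams", "CPMSimulation", "acceptance_probability", "read_cpm_config"]

UPDATE_INTERVAL = 100  # MCS between target-vector updates

_OFF_R = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_OFF_C = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)


@dataclass
class CPMParams:
    """Simulation parameters (energies per copy event, lengths in pixels)."""

    J: float = 4.0  # coupling energy per unlike neighbour pair
    A: float = 450.0  # target area, grid points
    P: float = 400.0  # target perimeter, unlike Moore pairs
    lambda_a: float = 0.3  # area stiffness
    lambda_p: float = 0.05  # perimeter stiffness
    nu: float = 0.0  # lobe propensity
    n_lobes: int = 6  # specified lobe count
    chi: float = 0.0  # elongation propensity
    mu: float = 0.0  # roundness stiffness
    T: float = 6.0  # simulation temperature
    Y: float = 0.0  # yield

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature T must be positive")
        if self.A <= 0:
            raise ValueError("target area A must be positive")
        if min(self.lambda_a, self.lambda_p, self.mu) < 0:
            raise ValueError("stiffnesses must be non-negative")

    @property
    def R(self) -> float:
        """Preferred radius sqrt(A/pi) given the target area."""
        return float(np.sqrt(self.A / np.pi))


def acceptance_probability(delta_H: float, params: CPMParams) -> float:
    """Probability of accepting a copy event with energy change ``delta_H``.

    Events lowering the energy by at least the yield Y are certain;
    otherwise acceptance is Boltzmann, exp(-(dH + Y)/T).
    """
    if delta_H <= -params.Y:
        return 1.0
    return float(min(1.0, np.exp(-(delta_H + params.Y) / params.T)))


@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _delta_H(lat, r, c, s_id, t_id, area, perim, sx, sy, phase, elong,
             J, A, P, la, lp, nu, nl, chi, mu, R):
    """Energy change of copying state s_id into site (r, c) holding t_id.

    Returns (dH, n_s, n_t) with n_s/n_t the Moore-neighbour counts of the
    gaining/losing cell around the site (needed for perimeter updates).
    """
    n_s = 0
    n_t = 0
    dh = 0.0
    for k in range(8):
        idy = lat[r + _OFF_R[k], c + _OFF_C[k]]
        if idy == s_id:
            n_s += 1
        if idy == t_id:
            n_t += 1
        # J gates on the Kronecker delta: like pairs contribute nothing
        if idy != s_id:
            dh += J
        if idy != t_id:
            dh -= J
    if t_id > 0:
        at = area[t_id]
        dh += la * ((at - 1 - A) ** 2 - (at - A) ** 2)
        pt = perim[t_id]
        dp_t = 2 * n_t - 8
        dh += lp * ((pt + dp_t - P) ** 2 - (pt - P) ** 2)
    if s_id > 0:
        asrc = area[s_id]
        dh += la * ((asrc + 1 - A) ** 2 - (asrc - A) ** 2)
        ps = perim[s_id]
        dp_s = 8 - 2 * n_s
        dh += lp * ((ps + dp_s - P) ** 2 - (ps - P) ** 2)
    # shape terms, evaluated for both cells involved
    for cid, s in ((s_id, 1.0), (t_id, -1.0)):
        if cid <= 0 or area[cid] == 0:
            continue
        vx = c - sx[cid] / area[cid]
        vy = r - sy[cid] / area[cid]
        rr = np.sqrt(vx * vx + vy * vy)
        ang = np.arctan2(vy, vx)
        if nu != 0.0:
            dh -= s * nu * np.cos(nl * (ang - phase[cid]))
        if chi != 0.0:
            dh -= s * chi * np.cos(2.0 * (ang - elong[cid]))
        if mu != 0.0:
            dev = rr - R
            sgn = 1.0 if dev > 0 else (-1.0 if dev < 0 else 0.0)
            dh += mu * s * sgn * dev * dev
    return dh, n_s, n_t


@njit(cache=True)
def _run_mcs(lat, area, perim, sx, sy, phase, elong,
             J, A, P, la, lp, nu, nl, chi, mu, R, T, Y, n_mcs):
    H, W = lat.shape
    n_sites = (H - 2) * (W - 2)
    for _ in range(n_mcs):
        for _ in range(n_sites):
            r = 1 + int(np.random.random() * (H - 2))
            c = 1 + int(np.random.random() * (W - 2))
            k = int(np.random.random() * 8)
            nr = r + _OFF_R[k]
            nc = c + _OFF_C[k]
            s_id = lat[nr, nc]
            t_id = lat[r, c]
            if s_id == t_id:
                continue
            dh, n_s, n_t = _delta_H(
                lat, r, c, s_id, t_id, area, perim, sx, sy, phase, elong,
                J, A, P, la, lp, nu, nl, chi, mu, R,
            )
            if dh <= -Y:
                accept = True
            else:
                accept = np.random.random() < np.exp(-(dh + Y) / T)
            if accept:
                lat[r, c] = s_id
                if t_id > 0:
                    area[t_id] -= 1
                    perim[t_id] += 2 * n_t - 8
                    sx[t_id] -= c
                    sy[t_id] -= r
                if s_id > 0:
                    area[s_id] += 1
                    perim[s_id] += 8 - 2 * n_s
                    sx[s_id] += c
                    sy[s_id] += r


class CPMSimulation:
    """A running CPM lattice with incremental bookkeeping.

    The outermost lattice ring is frozen background: copy attempts only
    target interior sites. One time step (MCS) is one sweep of as many
    elementary copy evaluations as there are interior sites. A single
    seeded generator drives site choice, neighbour choice and acceptance,
    so trajectories are reproducible bit-for-bit for a given seed.
    """

    def __init__(self, lattice: np.ndarray, params: CPMParams, seed: int = 0):
        lat = np.array(lattice, dtype=np.int64)
        if lat.ndim != 2:
            raise ValueError("lattice must be 2D")
        lat[0, :] = 0
        lat[-1, :] = 0
        lat[:, 0] = 0
        lat[:, -1] = 0
        self.lattice = lat
        self.params = params
        self.seed = int(seed)
        self.time = 0  # MCS elapsed
        n = int(lat.max()) + 1
        self.area = np.zeros(n, dtype=np.int64)
        self.perim = np.zeros(n, dtype=np.int64)
        self.sx = np.zeros(n, dtype=np.float64)
        self.sy = np.zeros(n, dtype=np.float64)
        self._recount()
        rng = np.random.default_rng(seed)
        self.phase = rng.uniform(0, 2 * np.pi, n)
        self.elong = rng.uniform(0, np.pi, n)
        _seed_rng(self.seed)

    # ---------------- construction helpers ----------------

    @classmethod
    def single_cell(cls, params: CPMParams, field: int = 64, seed: int = 0):
        """One square cell of the target area centred in the field."""
        side = max(2, int(round(np.sqrt(params.A))))
        lat = np.zeros((field, field), dtype=np.int64)
        lo = (field - side) // 2
        lat[lo : lo + side, lo : lo + side] = 1
        return cls(lat, params, seed)

    @classmethod
    def tissue(cls, params: CPMParams, n_cells: int, field: int, seed: int = 0):
        """A confluent block of n_cells square cells centred in the field."""
        side = int(np.ceil(np.sqrt(n_cells)))
        b = max(2, int(round(np.sqrt(params.A))))
        if side * b > field - 2:
            raise ValueError("field too small for the requested tissue")
        lat = np.zeros((field, field), dtype=np.int64)
        lo = (field - side * b) // 2
        cid = 0
        for gy in range(side):
            for gx in range(side):
                cid += 1
                if cid > n_cells:
                    break
                lat[
                    lo + gy * b : lo + (gy + 1) * b,
                    lo + gx * b : lo + (gx + 1) * b,
                ] = cid
        return cls(lat, params, seed)

    # ---------------- bookkeeping ----------------

    def _recount(self) -> None:
        """Recount areas, perimeters and COM sums from the lattice."""
        lat = self.lattice
        n = len(self.area)
        self.area[:] = np.bincount(lat.ravel(), minlength=n)[:n]
        self.area[0] = 0
        perim = np.zeros(n, dtype=np.int64)
        for k in range(8):
            sh = _shift(lat, _OFF_R[k], _OFF_C[k])
            unlike = lat != sh
            perim += np.bincount(lat[unlike], minlength=n)[:n]
        perim[0] = 0
        self.perim[:] = perim
        yy, xx = np.mgrid[0 : lat.shape[0], 0 : lat.shape[1]]
        self.sx[:] = np.bincount(lat.ravel(), weights=xx.ravel(), minlength=n)[:n]
        self.sy[:] = np.bincount(lat.ravel(), weights=yy.ravel(), minlength=n)[:n]
        self.sx[0] = self.sy[0] = 0.0

    def audit(self) -> float:
        """Max absolute drift between incremental and recounted state."""
        a, p = self.area.copy(), self.perim.copy()
        sx, sy = self.sx.copy(), self.sy.copy()
        self._recount()
        return float(
            max(
                np.abs(a - self.area).max(initial=0),
                np.abs(p - self.perim).max(initial=0),
                np.abs(sx - self.sx).max(initial=0.0),
                np.abs(sy - self.sy).max(initial=0.0),
            )
        )

    def hamiltonian(self) -> float:
        """Full recomputation of the base Hamiltonian (J + area + perimeter)."""
        lat = self.lattice
        p = self.params
        n_unlike = 0
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):  # each pair once
            sh = _shift(lat, dr, dc, fill=-1)
            n_unlike += int(np.sum((lat != sh) & (sh != -1)))
        h = p.J * n_unlike
        live = self.area > 0
        h += p.lambda_a * float(np.sum((self.area[live] - p.A) ** 2))
        h += p.lambda_p * float(np.sum((self.perim[live] - p.P) ** 2))
        return h

    def delta_H(self, site: tuple[int, int], new_id: int) -> float:
        """Energy change of copying ``new_id`` into ``site`` (no flip)."""
        r, c = site
        p = self.params
        dh, _, _ = _delta_H(
            self.lattice, r, c, new_id, self.lattice[r, c],
            self.area, self.perim, self.sx, self.sy, self.phase, self.elong,
            p.J, p.A, p.P, p.lambda_a, p.lambda_p, p.nu, p.n_lobes,
            p.chi, p.mu, p.R,
        )
        return float(dh)

    # ---------------- dynamics ----------------

    def update_target_vectors(self) -> None:
        """Re-anchor lobe target directions and the elongation axis.

        The lobe phase is set to the offset maximising the circular
        cross-correlation between the cell's radial boundary profile and
        cos(n * (theta - offset)); for a radially featureless (circular)
        cell the correlation is flat and the current phase is kept. The
        elongation axis is the principal axis of the second area moments.
        """
        lat = self.lattice
        p = self.params
        interior = np.zeros_like(lat, dtype=bool)
        boundary = np.zeros_like(lat, dtype=bool)
        for k in range(8):
            boundary |= lat != _shift(lat, _OFF_R[k], _OFF_C[k])
        for cid in range(1, len(self.area)):
            if self.area[cid] == 0:
                continue
            rows, cols = np.nonzero(lat == cid)
            comx = self.sx[cid] / self.area[cid]
            comy = self.sy[cid] / self.area[cid]
            # lobe phase from boundary radial profile
            bsel = boundary[rows, cols]
            if bsel.sum() >= p.n_lobes:
                vx = cols[bsel] - comx
                vy = rows[bsel] - comy
                rr = np.hypot(vx, vy)
                th = np.arctan2(vy, vx)
                w = rr - rr.mean()
                cs = np.sum(w * np.cos(p.n_lobes * th))
                sn = np.sum(w * np.sin(p.n_lobes * th))
                if np.hypot(cs, sn) > 1e-9:
                    self.phase[cid] = np.arctan2(sn, cs) / p.n_lobes
            # elongation axis from second central moments
            ux = cols - comx
            uy = rows - comy
            m20 = np.mean(ux * ux)
            m02 = np.mean(uy * uy)
            m11 = np.mean(ux * uy)
            if abs(m20 - m02) > 1e-9 or abs(m11) > 1e-9:
                self.elong[cid] = 0.5 * np.arctan2(2 * m11, m20 - m02)

    def check_connectivity(self) -> list[int]:
        """IDs of fragmented cells (more than one 4-connected piece)."""
        frag = []
        for cid in range(1, len(self.area)):
            if self.area[cid] == 0:
                continue
            _, n = ndimage.label(self.lattice == cid)
            if n > 1:
                frag.append(cid)
        return frag

    def step(self, n_mcs: int) -> None:
        """Advance the lattice by ``n_mcs`` Monte Carlo steps."""
        p = self.params
        _run_mcs(
            self.lattice, self.area, self.perim, self.sx, self.sy,
            self.phase, self.elong,
            p.J, p.A, p.P, p.lambda_a, p.lambda_p, p.nu, float(p.n_lobes),
            p.chi, p.mu, p.R, p.T, p.Y, n_mcs,
        )
        self.time += n_mcs

    def run(self, steps: int, snapshot_every: int = 0) -> list[LabelImage]:
        """Run with target-vector updates every 100 MCS; return snapshots."""
        if steps < 1:
            raise ValueError("steps must be >= 1")
        snaps: list[LabelImage] = []
        done = 0
        while done < steps:
            block = min(UPDATE_INTERVAL, steps - done)
            self.step(block)
            done += block
            self.update_target_vectors()
            frag = self.check_connectivity()
            if frag:
                logger.warning(
                    "t=%d: cells %s lost coherence (fragmented)", self.time, frag
                )
            if snapshot_every and (done % snapshot_every == 0 or done >= steps):
                snaps.append(self.snapshot())
        if not snapshot_every:
            snaps.append(self.snapshot())
        return snaps

    def snapshot(self) -> LabelImage:
        return LabelImage(self.lattice.astype(np.int32).copy())


def _shift(lat: np.ndarray, dr: int, dc: int, fill: int = -1) -> np.ndarray:
    """Shifted copy of the lattice, out-of-field sites set to ``fill``."""
    out = np.full_like(lat, fill)
    h, w = lat.shape
    rs = slice(max(dr, 0), h + min(dr, 0))
    rd = slice(max(-dr, 0), h + min(-dr, 0))
    cs = slice(max(dc, 0), w + min(dc, 0))
    cd = slice(max(-dc, 0), w + min(-dc, 0))
    out[rd, cd] = lat[rs, cs]
    return out


def read_cpm_config(path) -> tuple[CPMParams, dict]:
    """Parse a key=value config file into params plus run options.

    Recognised parameter keys: J, A, P, lambda_a, lambda_p, nu, n, chi,
    mu, T, Y. Run options: steps, seed, n_cells, field, snapshot_every.
    Lines starting with '#' are ignored.
    """
    values: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = float(val)
    run_keys = {"steps": 10000, "seed": 0, "n_cells": 1, "field": 64,
                "snapshot_every": 0}
    run = {k: int(values.pop(k, d)) for k, d in run_keys.items()}
    pmap = {"J": "J", "A": "A", "P": "P", "lambda_a": "lambda_a",
            "lambda_p": "lambda_p", "nu": "nu", "n": "n_lobes", "chi": "chi",
            "mu": "mu", "T": "T", "Y": "Y"}
    kwargs = {}
    for key, val in values.items():
        if key not in pmap:
            raise ValueError(f"unknown CPM parameter {key!r}")
        kwargs[pmap[key]] = int(val) if pmap[key] == "n_lobes" else val
    return CPMParams(**kwargs), run
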