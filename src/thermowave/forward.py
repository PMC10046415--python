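"""2D TM electromagnetic scattering: state/data equations, MoM solver, noise.

The phantom slice is probed with time-harmonic line sources under the
e^{jwt} convention.  In TM polarization the problem is scalar in the
longitudinal electric field and is governed by the volume integral (state)
equation

    Etot(r, rv) = Einc(r, rv) + kb^2 Int_Omega g(r, r') chi(r') Etot(r', rv) dr'

and the data equation

    ES(rm, rv) = kb^2 Int_Omega g(rm, r') chi(r') Etot(r', rv) dr',

with g the 2D scalar Green's function of the homogeneous lossy background,
g(r, r') = (-j/4) H0^(2)(kb |r - r'|), and chi the contrast function.

Discretization is pulse-basis / point-matching on the raster (Richmond
cells): each square cell is replaced by the equal-area disc of radius
a = h / sqrt(pi), over which the Green's function integrates in closed form
with Bessel functions.  The self term is integrated analytically.  Grids up
to 64^2 use a dense direct factorization; larger grids use an FFT-accelerated
iterative solve exploiting the convolutional structure of the kernel.

An independent analytic series solution for the homogeneous circular
cylinder (line-source incidence) is provided as a validation oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, lgmres
from scipy.special import h2vp, hankel2, jv, jvp

from .dielectric import C0, EPS0, MU0
from .phantom import Phantom, RoiSpec

__all__ = [
    "AntennaLayout",
    "FrequencySet",
    "FieldRecord",
    "background_wavenumber",
    "background_green",
    "incident_field",
    "solve_total_field",
    "analytic_cylinder_reference",
    "add_awgn",
]


class SolverError(RuntimeError):
    """Raised when the forward solve fails to converge or is singular."""


@dataclass(frozen=True)
class AntennaLayout:
    """Positions [m] of the transmit/receive point antennas on the curve Gamma.

    Default: 12 co-located Tx/Rx on a 9 cm-radius circle around the neck.
    Angles are measured from the anterior direction (+y): two groups of
    three flank the anterior hyperthermia-applicator gap at +/-45 deg, and
    six are evenly spaced over the posterior arc [120, 240] deg, leaving
    gaps for the applicator antennas.
    """

    positions: np.ndarray  # (N, 2) float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 1:
            raise ValueError("positions must be a (N, 2) array with N >= 1")
        object.__setattr__(self, "positions", pos)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def default_ring(cls, radius: float = 0.09) -> "AntennaLayout":
        anterior_deg = [-55.0, -45.0, -35.0, 35.0, 45.0, 55.0]
        posterior_deg = [120.0, 144.0, 168.0, 192.0, 216.0, 240.0]
        theta = np.deg2rad(np.array(anterior_deg + posterior_deg))
        # anterior direction is +y; theta grows clockwise towards +x
        xy = np.stack([radius * np.sin(theta), radius * np.cos(theta)], axis=1)
        return cls(positions=xy)


@dataclass(frozen=True)
class FrequencySet:
    """Strictly increasing acquisition frequencies [Hz]."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size < 1:
            raise ValueError("frequencies must be a 1D non-empty array")
        if (f <= 0).any() or (np.diff(f) <= 0).any():
            raise ValueError("frequencies must be positive and strictly increasing")
        object.__setattr__(self, "frequencies", f)

    def __len__(self) -> int:
        return self.frequencies.size

    def __iter__(self):
        return iter(self.frequencies)

    @classmethod
    def evenly_spaced(cls, n: int = 10, band: tuple[float, float] = (0.9e9, 1.8e9)) -> "FrequencySet":
        return cls(frequencies=np.linspace(band[0], band[1], n))


def background_wavenumber(f: float, eps_rb: complex) -> complex:
    """Complex background wavenumber kb = w sqrt(mu0 eps0 eps_rb), Im(kb) <= 0."""
    w = 2.0 * math.pi * f
    kb = w * np.sqrt(MU0 * EPS0 * complex(eps_rb))
    if kb.imag > 0:  # principal sqrt already lands in the 4th quadrant for eps'' > 0
        kb = -kb
    return complex(kb)


def background_green(kb: complex, r: np.ndarray, r_prime: np.ndarray) -> np.ndarray:
    """2D outgoing scalar Green's function g = (-j/4) H0^(2)(kb |r - r'|).

    ``r`` and ``r_prime`` broadcast against each other on their last axis (2).
    Coincident points are not handled here; the singular self term is
    integrated analytically inside the MoM assembly.
    """
    d = np.linalg.norm(np.asarray(r, float) - np.asarray(r_prime, float), axis=-1)
    if np.any(d == 0):
        raise ValueError("coincident points: the self term is handled in the MoM assembly")
    return -0.25j * hankel2(0, kb * d)


def incident_field(layout: AntennaLayout, kb: complex, v: int, points: np.ndarray) -> np.ndarray:
    """Field of the v-th unit line source at ``points`` (shape (..., 2))."""
    if not 0 <= v < layout.n:
        raise IndexError(f"source index {v} out of range for {layout.n} antennas")
    return background_green(kb, np.asarray(points, float), layout.positions[v])


def _richmond_terms(kb: complex, cell_size: float) -> tuple[complex, complex]:
    """(off-diagonal prefactor, self term) of kb^2 Int_cell g over a Richmond cell."""
    a = cell_size / math.sqrt(math.pi)  # equal-area disc radius
    ka = kb * a
    off = -0.5j * math.pi * ka * jv(1, ka)  # multiplies H0^(2)(kb rho)
    self_term = -0.5j * math.pi * ka * hankel2(1, ka) - 1.0
    return complex(off), complex(self_term)


@dataclass
class FieldRecord:
    """Total/incident fields on the contrast support and scattered data.

    Fields are stored on the ``support`` cells (pixels inside the neck
    cross-section, where the contrast can be non-zero), flattened in
    row-major grid order.  ``es`` is the Nm x Nv multistatic data matrix.
    """

    f: float
    kb: complex
    support: np.ndarray  # (n, n) bool
    einc: np.ndarray  # (Nv, ns)
    etot: np.ndarray  # (Nv, ns)
    es: np.ndarray  # (Nm, Nv)
    layout: AntennaLayout
    cell_size: float
    chi: np.ndarray  # (ns,) contrast on the support cells
    _support_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        idx = np.full(self.support.shape, -1, dtype=np.int64)
        idx[self.support] = np.arange(int(self.support.sum()))
        self._support_index = idx

    def _pixel_coords(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        n = self.support.shape[0]
        h = self.cell_size
        half = n * h / 2.0
        return np.stack([(rows + 0.5) * h - half, (cols + 0.5) * h - half], axis=-1)

    def _cell_coords(self) -> np.ndarray:
        rows, cols = np.nonzero(self.support)
        return self._pixel_coords(rows, cols)

    def field_at_pixels(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Total field at arbitrary grid pixels, shape (Nv, npix).

        Support pixels return the stored solution; exterior pixels are
        evaluated by field continuation, Etot = Einc + kb^2 Int g chi Etot.
        """
        sub = self._support_index[rows, cols]
        out = np.empty((self.layout.n, rows.size), dtype=np.complex128)
        on = sub >= 0
        out[:, on] = self.etot[:, sub[on]]
        if (~on).any():
            pts = self._pixel_coords(rows[~on], cols[~on])
            d_src = np.linalg.norm(pts[:, None, :] - self.layout.positions[None, :, :], axis=-1)
            einc_ext = (-0.25j * hankel2(0, self.kb * d_src)).T  # (Nv, next)
            off, _ = _richmond_terms(self.kb, self.cell_size)
            d_cc = np.linalg.norm(pts[:, None, :] - self._cell_coords()[None, :, :], axis=-1)
            g_ext = off * hankel2(0, self.kb * d_cc)  # (next, ns)
            out[:, ~on] = einc_ext + (self.chi[None, :] * self.etot) @ g_ext.T
        return out

    def field_on_roi(self, roi: RoiSpec) -> np.ndarray:
        """Baseline total field on the ROI window pixels, shape (Nv, size^2).

        Pixels are ordered row-major within the window.
        """
        rr, cc = np.meshgrid(
            np.arange(roi.row0, roi.row0 + roi.size),
            np.arange(roi.col0, roi.col0 + roi.size),
            indexing="ij",
        )
        return self.field_at_pixels(rr.ravel(), cc.ravel())


class MomForwardSolver:
    """Method-of-moments solver with geometry precomputed per frequency.

    The Green's matrices depend only on the raster geometry, the antenna
    layout and the background medium, so they are assembled once and reused
    across phantom material states (temperature / randomization changes) —
    the per-state cost is one factorization per frequency.
    """

    def __init__(
        self,
        phantom: Phantom,
        layout: AntennaLayout,
        frequencies: FrequencySet,
        method: str = "auto",
    ) -> None:
        cfg = phantom.config
        self.layout = layout
        self.frequencies = frequencies
        self.method = method
        self.support = phantom.inside_neck.copy()
        self.cell_size = cfg.cell_size
        n = cfg.grid_n
        self._grid_n = n
        x, y = phantom.pixel_centers()
        self._cells = np.stack([x[self.support], y[self.support]], axis=1)  # (ns, 2)
        self._all_cells = np.stack([x.ravel(), y.ravel()], axis=1)

        # antennas must sit strictly outside the neck cross-section
        a, b = cfg.neck_semi_axes
        px, py = layout.positions[:, 0], layout.positions[:, 1]
        if np.any((px / a) ** 2 + (py / b) ** 2 <= 1.0):
            raise ValueError("antenna positions must lie strictly outside the neck")

        self._per_freq: list[dict] = []
        use_dense = method == "direct" or (method == "auto" and n <= 64)
        for f in frequencies:
            eps_rb = cfg.background_eps(f)
            kb = background_wavenumber(f, eps_rb)
            lam = 2.0 * math.pi / kb.real
            if lam / self.cell_size < 10.0:
                warnings.warn(
                    f"{lam / self.cell_size:.1f} cells per background wavelength at "
                    f"{f / 1e9:.2f} GHz (< 10); discretization error may be noticeable",
                    stacklevel=2,
                )
            off, self_term = _richmond_terms(kb, self.cell_size)
            entry: dict = {"f": f, "kb": kb, "eps_rb": eps_rb}
            # receiver-side data kernel kb^2 Int g, (Nm, ns)
            d_rx = np.linalg.norm(layout.positions[:, None, :] - self._cells[None, :, :], axis=-1)
            entry["g_rx"] = off * hankel2(0, kb * d_rx)
            # incident fields at the support cells, (Nv, ns)
            entry["einc"] = -0.25j * hankel2(0, kb * d_rx)  # co-located Tx/Rx
            if use_dense:
                d_cc = np.linalg.norm(self._cells[:, None, :] - self._cells[None, :, :], axis=-1)
                np.fill_diagonal(d_cc, 1.0)
                g_cc = off * hankel2(0, kb * d_cc)
                np.fill_diagonal(g_cc, self_term)
                entry["g_cc"] = g_cc
            else:
                entry["kernel_fft"] = self._convolution_kernel_fft(kb, off, self_term)
            self._per_freq.append(entry)
        self._dense = use_dense

    def _convolution_kernel_fft(self, kb: complex, off: complex, self_term: complex) -> np.ndarray:
        """FFT of the translation-invariant cell-to-cell kernel (2n x 2n)."""
        n, h = self._grid_n, self.cell_size
        ix = np.arange(2 * n)
        ix = np.minimum(ix, 2 * n - ix)  # circulant embedding distances
        dx, dy = np.meshgrid(ix * h, ix * h, indexing="ij")
        d = np.hypot(dx, dy)
        d[0, 0] = 1.0
        ker = off * hankel2(0, kb * d)
        ker[0, 0] = self_term
        return np.fft.fft2(ker)

    def solve(self, phantom: Phantom) -> list[FieldRecord]:
        """Solve the state and data equations for the phantom material state."""
        if phantom.labels.shape != self.support.shape or not np.array_equal(
            phantom.inside_neck, self.support
        ):
            raise ValueError("phantom raster geometry differs from the precomputed solver")
        from .phantom import permittivity_map

        records = []
        for entry in self._per_freq:
            f, kb, eps_rb = entry["f"], entry["kb"], entry["eps_rb"]
            eps = permittivity_map(phantom, f)
            chi = eps[self.support] / eps_rb - 1.0
            einc = entry["einc"]
            if not np.any(chi):
                etot = einc.copy()
                es = np.zeros((self.layout.n, self.layout.n), dtype=np.complex128)
            elif self._dense:
                A = -entry["g_cc"] * chi[None, :]
                A[np.diag_indices_from(A)] += 1.0
                try:
                    etot = np.linalg.solve(A, einc.T).T
                except np.linalg.LinAlgError as exc:
                    raise SolverError(f"singular MoM system at {f / 1e9:.2f} GHz") from exc
                es = entry["g_rx"] @ (chi[:, None] * etot.T)
            else:
                etot = self._solve_cgfft(entry, chi, einc)
                es = entry["g_rx"] @ (chi[:, None] * etot.T)
            records.append(
                FieldRecord(
                    f=f,
                    kb=kb,
                    support=self.support,
                    einc=einc,
                    etot=etot,
                    es=es,
                    layout=self.layout,
                    cell_size=self.cell_size,
                    chi=chi,
                )
            )
        return records

    def _solve_cgfft(self, entry: dict, chi: np.ndarray, einc: np.ndarray) -> np.ndarray:
        """Iterative solve with FFT-accelerated operator application."""
        n = self._grid_n
        ker_fft = entry["kernel_fft"]
        chi_grid = np.zeros((n, n), dtype=np.complex128)
        chi_grid[self.support] = chi

        def matvec(x: np.ndarray) -> np.ndarray:
            xg = x.reshape(n, n)
            src = chi_grid * xg
            pad = np.zeros((2 * n, 2 * n), dtype=np.complex128)
            pad[:n, :n] = src
            conv = np.fft.ifft2(np.fft.fft2(pad) * ker_fft)[:n, :n]
            return (xg - conv).ravel()

        op = LinearOperator((n * n, n * n), matvec=matvec, dtype=np.complex128)
        etot = np.empty_like(einc)
        for v in range(einc.shape[0]):
            rhs = np.zeros((n, n), dtype=np.complex128)
            rhs[self.support] = einc[v]
            sol, info = lgmres(op, rhs.ravel(), rtol=1e-6, atol=0.0, maxiter=2000)
            if info != 0:
                res = np.linalg.norm(matvec(sol) - rhs.ravel()) / np.linalg.norm(rhs)
                raise SolverError(f"CG-FFT solve did not converge (relative residual {res:.2e})")
            etot[v] = sol.reshape(n, n)[self.support]
        return etot


def solve_total_field(
    phantom: Phantom, layout: AntennaLayout, f: float, method: str = "auto"
) -> FieldRecord:
    """One-shot state+data solve at a single frequency (convenience wrapper)."""
    solver = MomForwardSolver(phantom, layout, FrequencySet(np.array([f])), method=method)
    return solver.solve(phantom)[0]


def analytic_cylinder_reference(
    radius: float,
    eps_cyl: complex,
    eps_bg: complex,
    layout: AntennaLayout,
    f: float,
    tol: float = 1e-12,
    max_order: int = 200,
) -> np.ndarray:
    """Series solution for TM scattering by a centred homogeneous cylinder.

    Line-source incidence from each layout position; returns the Nm x Nv
    scattered-field matrix at the (co-located) receiver positions.  The
    cylindrical-harmonic series is summed until an added order contributes
    less than ``tol`` of the running total for every entry.
    """
    kb = background_wavenumber(f, eps_bg)
    kc = background_wavenumber(f, eps_cyl)
    if eps_cyl == eps_bg or radius == 0:
        return np.zeros((layout.n, layout.n), dtype=np.complex128)
    pos = layout.positions
    rho = np.linalg.norm(pos, axis=1)
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    if np.any(rho <= radius):
        raise ValueError("antennas must be outside the cylinder")

    ka, kca = kb * radius, kc * radius
    es = np.zeros((layout.n, layout.n), dtype=np.complex128)

    def order_term(nn: int) -> np.ndarray:
        num = kc * jvp(nn, kca) * jv(nn, ka) - kb * jvp(nn, ka) * jv(nn, kca)
        den = kc * jvp(nn, kca) * hankel2(nn, ka) - kb * h2vp(nn, ka) * jv(nn, kca)
        bn = -(-0.25j) * num / den
        h_m = hankel2(nn, kb * rho)
        # (m, v) outer structure; source factor H_n^(2)(kb rho_v)
        return bn * np.outer(h_m * np.exp(1j * nn * phi), h_m * np.exp(-1j * nn * phi))

    prev_norm = 0.0
    for nn in range(0, max_order + 1):
        term = order_term(nn) if nn == 0 else order_term(nn) + order_term(-nn)
        es += term
        norm = float(np.abs(es).max())
        if nn > 2 and float(np.abs(term).max()) < tol * max(norm, prev_norm):
            return es
        prev_norm = norm
    raise RuntimeError("cylinder series did not converge; increase max_order")


def save_fields_h5(path, records: list[FieldRecord]) -> None:
    """Persist a FieldRecord set (one group per frequency) to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        for i, rec in enumerate(records):
            g = fh.create_group(f"f{i:03d}")
            g.attrs["f"] = rec.f
            g.attrs["kb"] = rec.kb
            g.attrs["cell_size"] = rec.cell_size
            g.create_dataset("support", data=rec.support)
            g.create_dataset("einc", data=rec.einc)
            g.create_dataset("etot", data=rec.etot)
            g.create_dataset("es", data=rec.es)
            g.create_dataset("chi", data=rec.chi)
            g.create_dataset("positions", data=rec.layout.positions)


def load_fields_h5(path) -> list[FieldRecord]:
    """Load a FieldRecord set written by :func:`save_fields_h5`."""
    import h5py

    records = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            g = fh[key]
            records.append(
                FieldRecord(
                    f=float(g.attrs["f"]),
                    kb=complex(g.attrs["kb"]),
                    support=g["support"][()],
                    einc=g["einc"][()],
                    etot=g["etot"][()],
                    es=g["es"][()],
                    layout=AntennaLayout(positions=g["positions"][()]),
                    cell_size=float(g.attrs["cell_size"]),
                    chi=g["chi"][()],
                )
            )
    return records


def add_awgn(
    es: np.ndarray, snr_db: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Add complex circular AWGN to multistatic data at a prescribed SNR.

    ``es`` has shape (Nf, Nm, Nv) (or (Nm, Nv) for one frequency); the noise
    power is set per frequency block so that the ratio of total signal power
    to noise power equals 10^(snr_db/10).  ``snr_db = inf`` returns the data
    unchanged.  Reproducible under a fixed seed.
    """
    if np.isinf(snr_db):
        return es.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.asarray(es, dtype=np.complex128)
    single = arr.ndim == 2
    blocks = arr[None, ...] if single else arr
    out = np.empty_like(blocks)
    for k, block in enumerate(blocks):
        p_sig = float(np.mean(np.abs(block) ** 2))
        p_noise = p_sig * 10.0 ** (-snr_db / 10.0)
        sd = math.sqrt(p_noise / 2.0)
        noise = rng.normal(0.0, sd, block.shape) + 1j * rng.normal(0.0, sd, block.shape)
        out[k] = block + noise
    return out[0] if single else out
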