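"""Differential imaging of the ROIs: DWBA linear operators and TSVD inversion.

During treatment the tissue permittivity perturbations are small, so the
scattering equations linearize around the baseline (pre-heating) state —
the distorted-wave Born approximation.  The baseline total field plays the
role of the Green's function, giving for each receiver/transmitter pair and
frequency

    dES(rm, rv; f) = kb(f)^2 Int_ROI Etot0(r', rm; f) Etot0(r', rv; f) dchi(r') dr'.

Restricting the unknown dchi to a small window around each clinically
relevant structure (tumor, spinal cord) yields one compact linear operator
per ROI.  Rows stack all (f, m, v) combinations (frequency-major);
columns are the window pixels in row-major order.  The operator's SVD is
computed once per baseline state (offline); each differential data vector
is then inverted in real time by a truncated SVD expansion,

    dchi = sum_{p <= Pcut} (1/lambda_p) (u_p^H dES) v_p.

``Pcut`` is the regularization parameter (default 1, matching the strongly
ill-posed single-look regime of the monitoring task).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .forward import FieldRecord
from .phantom import RoiSpec

__all__ = [
    "DifferentialData",
    "RoiOperator",
    "RoiImage",
    "differential_data",
    "build_roi_operator",
    "tsvd_invert",
    "solution_norm_curve",
    "TsvdRoiImager",
]


@dataclass(frozen=True)
class DifferentialData:
    """Stacked multi-frequency differential scattered data dES = ES[s] - ES[0].

    ``stacked`` is the (Nf*Nm*Nv,) vector in frequency-major, then
    receiver-major, transmitter-minor order (C order of the (Nf, Nm, Nv)
    block).
    """

    stacked: np.ndarray
    shape: tuple[int, int, int]  # (Nf, Nm, Nv)

    def blocks(self) -> np.ndarray:
        return self.stacked.reshape(self.shape)


def differential_data(es_heated: np.ndarray, es_baseline: np.ndarray) -> DifferentialData:
    """Element-wise dES = ES[s] - ES[0], stacked across frequencies.

    Inputs have shape (Nf, Nm, Nv) (a single-frequency (Nm, Nv) pair is
    promoted).  Shapes must match exactly.
    """
    a = np.asarray(es_heated, dtype=np.complex128)
    b = np.asarray(es_baseline, dtype=np.complex128)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if a.ndim == 2:
        a, b = a[None], b[None]
    if a.ndim != 3:
        raise ValueError("expected (Nf, Nm, Nv) data")
    delta = a - b
    return DifferentialData(stacked=delta.ravel(), shape=delta.shape)


@dataclass(frozen=True)
class RoiOperator:
    """DWBA map from ROI dchi pixels to stacked differential data, with SVD."""

    matrix: np.ndarray  # (Nf*Nm*Nv, npix)
    roi: RoiSpec
    shape: tuple[int, int, int]  # data block shape (Nf, Nm, Nv)
    u: np.ndarray  # (rows, rank)
    s: np.ndarray  # (rank,) non-increasing, >= 0
    vh: np.ndarray  # (rank, npix)

    @property
    def rank(self) -> int:
        return int(self.s.size)


def build_roi_operator(baseline_fields: list[FieldRecord], roi: RoiSpec) -> RoiOperator:
    """Assemble and factorize the DWBA operator for one ROI.

    ``baseline_fields`` holds one :class:`FieldRecord` per frequency for the
    unheated (physiological-temperature) phantom state.  With co-located
    Tx/Rx arrays, the field radiated from receiver position rm equals the
    recorded source-excited field by reciprocity, so the kernel row for
    (f, m, v) is ``kb^2 * Etot0[m, p] * Etot0[v, p] * cell_area`` over the
    window pixels p.
    """
    blocks = []
    nm = nv = baseline_fields[0].layout.n
    for rec in baseline_fields:
        e_roi = rec.field_on_roi(roi)  # (Nv, npix)
        cell_area = rec.cell_size**2
        kern = rec.kb**2 * cell_area * (e_roi[:, None, :] * e_roi[None, :, :])
        blocks.append(kern.reshape(nm * nv, -1))
    matrix = np.concatenate(blocks, axis=0)
    u, s, vh = np.linalg.svd(matrix, full_matrices=False)
    return RoiOperator(
        matrix=matrix,
        roi=roi,
        shape=(len(baseline_fields), nm, nv),
        u=u,
        s=s,
        vh=vh,
    )


@dataclass(frozen=True)
class RoiImage:
    """Complex differential-contrast estimate on one ROI window."""

    dchi: np.ndarray  # (size, size) complex
    roi: RoiSpec
    p_cut: int

    def channels(self) -> np.ndarray:
        """Real 2-channel view (size, size, 2): Re and Im of dchi."""
        return np.stack([self.dchi.real, self.dchi.imag], axis=-1)


def tsvd_invert(op: RoiOperator, data: DifferentialData, p_cut: int) -> RoiImage:
    """Truncated-SVD inversion of dES on the ROI window.

    Keeps the first ``p_cut`` singular triplets; triplets with singular value
    below 1e-12 of the largest are numerically null and excluded (with a
    warning).  Cost is O(p_cut * Nf*Nm*Nv) per call — the SVD is reused.
    """
    if data.shape != op.shape:
        raise ValueError(f"data block shape {data.shape} != operator {op.shape}")
    if not 1 <= p_cut <= op.rank:
        raise ValueError(f"p_cut must be in [1, {op.rank}], got {p_cut}")
    keep = op.s[:p_cut] > 1e-12 * op.s[0]
    if not keep.all():
        warnings.warn("excluded numerically null singular triplets from the TSVD sum", stacklevel=2)
    idx = np.nonzero(keep)[0]
    coef = (op.u[:, idx].conj().T @ data.stacked) / op.s[idx]
    dchi = op.vh[idx].conj().T @ coef
    size = op.roi.size
    return RoiImage(dchi=dchi.reshape(size, size), roi=op.roi, p_cut=p_cut)


def solution_norm_curve(op: RoiOperator, data: DifferentialData) -> np.ndarray:
    """||dchi(Pcut)|| for Pcut = 1..rank; non-decreasing by construction."""
    coef = np.abs(op.u.conj().T @ data.stacked) / op.s
    return np.sqrt(np.cumsum(coef**2))


class TsvdRoiImager:
    """Estimator-style wrapper: fit on baseline fields, transform dES to images.

    Follows the scikit-learn fit/transform idiom so the imaging stage can be
    composed with the downstream classifier.

    Parameters
    ----------
    roi : RoiSpec
        Window to reconstruct.
    p_cut : int
        TSVD truncation index (default 1).
    """

    def __init__(self, roi: RoiSpec | None = None, p_cut: int = 1):
        self.roi = roi
        self.p_cut = p_cut

    def get_params(self, deep: bool = True) -> dict:
        return {"roi": self.roi, "p_cut": self.p_cut}

    def set_params(self, **params) -> "TsvdRoiImager":
        for k, v in params.items():
            if k not in ("roi", "p_cut"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, baseline_fields: list[FieldRecord], y=None) -> "TsvdRoiImager":
        """Build and factorize the DWBA operator from the unheated state."""
        if self.roi is None:
            raise ValueError("roi must be set before fitting")
        self.operator_ = build_roi_operator(baseline_fields, self.roi)
        return self

    def transform(self, data: DifferentialData | list[DifferentialData]) -> np.ndarray:
        """Invert one or more dES vectors; returns (N, size, size, 2) real arrays."""
        if not hasattr(self, "operator_"):
            raise RuntimeError("imager is not fitted")
        items = data if isinstance(data, (list, tuple)) else [data]
        out = np.stack(
            [tsvd_invert(self.operator_, d, self.p_cut).channels() for d in items]
        )
        return out
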