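"""Water--fat separation and R2* mapping from multi-echo complex data.

Per-voxel signal model (the forward model the phantom module simulates):

    s(TE_n) = (W + F * c_n) * exp(i 2 pi psi TE_n) * exp(-R2* TE_n)

with fat modulation c_n = sum_p alpha_p exp(i 2 pi f_p TE_n) from the
multi-peak fat spectrum, field map psi (Hz) and a single shared R2* per
voxel.  Estimation is decoupled:

1. field map by discrete candidate search over psi with R2* fixed at 0,
   regularised by a mu-weighted quadratic neighbour penalty optimised with
   iterated conditional modes (ICM) on a coarse-to-fine dyadic pyramid;
2. per-voxel 1D discrete search over R2* at the estimated psi;
3. optional continuous Gauss-Newton polish of (psi, R2*) jointly;
4. final linear least-squares for complex W and F, reported as magnitudes.

For fixed (psi, R2*) the amplitudes enter linearly, so a candidate's fit
residual is computed projection-style: ||s||^2 minus the energy of s in
the span of the (demodulated, decayed) basis {1, c_n}.  This makes the
candidate searches single matrix products over all voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np

from .protocol import FatSpectrum


class DegenerateBasisError(ValueError):
    """Raised when the water/fat basis is rank deficient (all c_n == 1)."""


def fat_modulation(spectrum: FatSpectrum, echo_times: Sequence[float]) -> np.ndarray:
    """Complex fat modulation coefficient c_n per echo.

    c_n = sum_p alpha_p exp(i 2 pi f_p TE_n); |c_n| <= 1 because the
    relative amplitudes are positive and sum to one.
    """
    te = np.asarray(echo_times, dtype=float)
    if te.size == 0:
        raise ValueError("echo_times must be non-empty")
    f = spectrum.frequencies_hz
    a = spectrum.amplitudes
    return (a[None, :] * np.exp(2j * np.pi * f[None, :] * te[:, None])).sum(axis=1)


@dataclass(frozen=True)
class ReconOptions:
    """Options for map reconstruction.

    mu is the unitless field-map regularisation weight (default 10).  The
    field-map search defaults to one aliasing period +-1/(2*dTE) in 2 Hz
    steps; R2* is searched on [0, 150] s^-1 in 0.5 s^-1 steps, wide enough
    for adipose/muscle values (~20-40 s^-1) with fine resolution.
    """

    mu: float = 10.0
    fieldmap_range_hz: Optional[Tuple[float, float]] = None  # default +-1/(2 dTE)
    fieldmap_step_hz: float = 2.0
    r2s_max: float = 150.0
    r2s_step: float = 0.5
    n_scales: int = 3
    magnitude_discrimination: bool = True
    refine: bool = True
    icm_sweeps: int = 6

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.fieldmap_step_hz <= 0 or self.r2s_step <= 0:
            raise ValueError("search steps must be positive")
        if self.r2s_max <= 0:
            raise ValueError("r2s search range must be non-empty")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.fieldmap_range_hz is not None:
            lo, hi = self.fieldmap_range_hz
            if hi <= lo:
                raise ValueError("fieldmap search range must be non-empty")

    def psi_candidates(self, delta_te: float) -> np.ndarray:
        """Field-map candidates ordered by the tie-break rule.

        Candidates are sorted by ascending |psi| (positive before negative
        at equal magnitude) so that a first-occurrence argmin over
        residuals implements 'ties broken toward smaller |psi|'.
        """
        if self.fieldmap_range_hz is None:
            half = 1.0 / (2.0 * delta_te)
            lo, hi = -half, half
        else:
            lo, hi = self.fieldmap_range_hz
        n = int(np.floor((hi - lo) / self.fieldmap_step_hz)) + 1
        cand = lo + self.fieldmap_step_hz * np.arange(n)
        order = np.lexsort((cand < 0, np.abs(cand)))
        return cand[order]

    def r2s_candidates(self) -> np.ndarray:
        n = int(np.floor(self.r2s_max / self.r2s_step)) + 1
        return self.r2s_step * np.arange(n)


@dataclass
class QuantitativeMaps:
    """Co-registered water, fat, FF, R2* and field maps on one grid.

    ``ff`` is the fat fraction |F|/(|F|+|W|) stored as a fraction in
    [0, 1]; ``r2s`` in s^-1; ``fieldmap`` in Hz; ``residual`` is the
    final per-voxel fit residual norm.  ``degenerate`` flags voxels where
    F+W fell below the machine-noise floor and FF was set to 0.
    """

    water: np.ndarray
    fat: np.ndarray
    ff: np.ndarray
    r2s: np.ndarray
    fieldmap: np.ndarray
    residual: np.ndarray
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 2.0)
    degenerate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shape = self.water.shape
        for name in ("fat", "ff", "r2s", "fieldmap", "residual"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != water shape {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.ff < 0) or np.any(self.ff > 1):
            raise ValueError("ff must lie in [0, 1]")
        if np.any(self.r2s < 0):
            raise ValueError("r2s must be >= 0")
        if self.degenerate is None:
            self.degenerate = np.zeros(shape, dtype=bool)


# ---------------------------------------------------------------------------
# linear subproblem


def _basis(echo_times: np.ndarray, c: np.ndarray, psi, r2s) -> np.ndarray:
    """Water/fat basis for given (psi, r2s); shape (..., ne, 2)."""
    te = echo_times
    psi = np.asarray(psi, dtype=float)[..., None]
    r2s = np.asarray(r2s, dtype=float)[..., None]
    e = np.exp((2j * np.pi * psi - r2s) * te)
    return np.stack([e, e * c], axis=-1)


def _solve_linear(signal: np.ndarray, A: np.ndarray):
    """Closed-form 2x2 complex least squares of signal on basis A.

    signal: (..., ne); A: (..., ne, 2).  Returns complex (W, F) and the
    residual norm, all with shape (...).
    """
    a0 = A[..., 0]
    a1 = A[..., 1]
    g00 = (a0.conj() * a0).sum(axis=-1).real
    g11 = (a1.conj() * a1).sum(axis=-1).real
    g01 = (a0.conj() * a1).sum(axis=-1)
    det = g00 * g11 - (g01.conj() * g01).real
    scale = np.maximum(g00, g11)
    if np.any(det <= 1e-12 * scale * scale):
        raise DegenerateBasisError(
            "water/fat basis is rank deficient (all fat modulation "
            "coefficients equal 1); cannot separate water from fat"
        )
    b0 = (a0.conj() * signal).sum(axis=-1)
    b1 = (a1.conj() * signal).sum(axis=-1)
    w = (g11 * b0 - g01 * b1) / det
    f = (g00 * b1 - g01.conj() * b0) / det
    model = a0 * w[..., None] + a1 * f[..., None]
    resid = np.linalg.norm(signal - model, axis=-1)
    return w, f, resid


def solve_wf(
    signal: np.ndarray,
    echo_times: Sequence[float],
    spectrum: FatSpectrum,
    psi,
    r2s,
):
    """Solve the linear water/fat subproblem at fixed (psi, r2s).

    Returns (W, F, residual_norm) with W, F as magnitudes.  ``signal`` may
    have any leading shape with echoes last; psi and r2s broadcast over
    the leading shape.
    """
    te = np.asarray(echo_times, dtype=float)
    s = np.asarray(signal)
    if s.shape[-1] != te.size:
        raise ValueError("signal length must equal the number of echoes")
    c = fat_modulation(spectrum, te)
    A = _basis(te, c, psi, r2s)
    w, f, resid = _solve_linear(s, A)
    return np.abs(w), np.abs(f), resid


# ---------------------------------------------------------------------------
# candidate-search machinery


def _stacked_orthobases(bases: np.ndarray) -> np.ndarray:
    """Orthonormalise each candidate basis (ncand, ne, 2) and stack the Q
    factors into one (ne, 2*ncand) matrix, candidate-major."""
    q, _ = np.linalg.qr(bases)  # (ncand, ne, 2)
    return np.ascontiguousarray(q.transpose(1, 0, 2).reshape(q.shape[1], -1))


@lru_cache(maxsize=32)
def _psi_orthobases(te_key: tuple, peaks_key: tuple, cand_key: tuple) -> np.ndarray:
    te = np.array(te_key)
    c = fat_modulation(FatSpectrum(peaks=peaks_key), te)
    cand = np.array(cand_key)
    return _stacked_orthobases(_basis(te, c, cand, np.zeros_like(cand)))


@lru_cache(maxsize=32)
def _r2s_orthobases(te_key: tuple, peaks_key: tuple, cand_key: tuple) -> np.ndarray:
    te = np.array(te_key)
    c = fat_modulation(FatSpectrum(peaks=peaks_key), te)
    cand = np.array(cand_key)
    return _stacked_orthobases(_basis(te, c, np.zeros_like(cand), cand))


def _candidate_residuals(signal2d: np.ndarray, q_stack: np.ndarray) -> np.ndarray:
    """Squared residuals (nvox, ncand) of the projection fits.

    For each candidate's orthonormal basis Q the projection energy is
    ||Q^H s||^2, so all candidates reduce to thin real matrix products
    against the stacked Q factors (exact double precision, no complex
    GEMM).
    """
    sr = np.ascontiguousarray(signal2d.real)
    si = np.ascontiguousarray(signal2d.imag)
    qr = np.ascontiguousarray(q_stack.real)
    qi = np.ascontiguousarray(q_stack.imag)
    tr = sr @ qr + si @ qi
    ti = si @ qr - sr @ qi
    ncand = q_stack.shape[1] // 2
    energy = (tr * tr + ti * ti).reshape(-1, ncand, 2).sum(axis=2)
    power = (sr * sr + si * si).sum(axis=1)
    return np.maximum(power[:, None] - energy, 0.0)


def _spectrum_key(spectrum: FatSpectrum) -> tuple:
    return tuple(tuple(p) for p in spectrum.peaks)


# ---------------------------------------------------------------------------
# field-map estimation


def _downsample2(vol: np.ndarray) -> np.ndarray:
    """Block-average by 2 along x and y (and z while >= 4 slices)."""
    def block(a, axis):
        n = a.shape[axis]
        m = n // 2
        sl = [slice(None)] * a.ndim
        sl[axis] = slice(0, 2 * m)
        a = a[tuple(sl)]
        shape = list(a.shape)
        shape[axis] = m
        shape.insert(axis + 1, 2)
        return a.reshape(shape).mean(axis=axis + 1)

    out = block(block(vol, 0), 1)
    if vol.shape[2] >= 4:
        out = block(out, 2)
    return out


def _upsample_labels(lab: np.ndarray, target_shape: Tuple[int, int, int]) -> np.ndarray:
    out = lab
    for axis in range(3):
        reps = int(np.ceil(target_shape[axis] / out.shape[axis]))
        out = np.repeat(out, reps, axis=axis)
        sl = [slice(None)] * 3
        sl[axis] = slice(0, target_shape[axis])
        out = out[tuple(sl)]
    return out


def _neighbor_sums(psi: np.ndarray):
    """Sum, sum of squares and count of 6-neighbourhood values, with grid
    borders treated as absent neighbours."""
    s1 = np.zeros_like(psi)
    s2 = np.zeros_like(psi)
    k = np.zeros_like(psi)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(psi, shift, axis=axis)
            valid = np.ones_like(psi, dtype=bool)
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            valid[tuple(sl)] = False
            s1 += np.where(valid, rolled, 0.0)
            s2 += np.where(valid, rolled * rolled, 0.0)
            k += valid
    return s1, s2, k


def _serpentine_order(shape: Tuple[int, int, int]) -> np.ndarray:
    """Flat voxel indices in a serpentine (boustrophedon) scan so that
    consecutive entries are grid neighbours."""
    nx, ny, nz = shape
    order = []
    for k in range(nz):
        for j in range(ny) if k % 2 == 0 else range(ny - 1, -1, -1):
            xs = range(nx) if (j + k) % 2 == 0 else range(nx - 1, -1, -1)
            for i in xs:
                order.append((i * ny + j) * nz + k)
    return np.array(order, dtype=np.int64)


def _viterbi_init(
    rhat: np.ndarray, cand: np.ndarray, mu: float, f_scale: float
) -> np.ndarray:
    """Exact chain optimisation of data + smoothness cost along a
    serpentine path; used to initialise the coarsest-scale labelling so
    that coherent water-fat-swapped regions cannot survive as a locally
    consistent solution."""
    shape = rhat.shape[:3]
    ncand = cand.size
    flat = rhat.reshape(-1, ncand)
    order = _serpentine_order(shape)
    trans = mu * ((cand[:, None] - cand[None, :]) / f_scale) ** 2
    n = order.size
    back = np.empty((n, ncand), dtype=np.int32)
    cost = flat[order[0]].copy()
    for step in range(1, n):
        total = cost[:, None] + trans
        back[step] = np.argmin(total, axis=0)
        cost = total[back[step], np.arange(ncand)] + flat[order[step]]
    labels_path = np.empty(n, dtype=np.int64)
    labels_path[-1] = int(np.argmin(cost))
    for step in range(n - 1, 0, -1):
        labels_path[step - 1] = back[step, labels_path[step]]
    labels = np.empty(flat.shape[0], dtype=np.int64)
    labels[order] = labels_path
    return labels


def _checkerboard(shape: Tuple[int, int, int]) -> np.ndarray:
    idx = np.add.outer(np.add.outer(np.arange(shape[0]), np.arange(shape[1])), np.arange(shape[2]))
    return idx % 2 == 0


def _icm_labels(
    rhat: np.ndarray,
    cand: np.ndarray,
    init_labels: np.ndarray,
    mu: float,
    f_scale: float,
    sweeps: int,
) -> np.ndarray:
    """Iterated conditional modes for the discrete field-map labelling.

    rhat: (nx, ny, nz, ncand) normalised data residuals; cost per voxel is
    rhat + mu * sum_nb ((psi - psi_nb)/f_scale)^2.
    """
    shape = rhat.shape[:3]
    labels = init_labels.copy()
    if mu == 0 or sweeps == 0:
        return labels
    parity = _checkerboard(shape)
    inv_f2 = 1.0 / (f_scale * f_scale)
    c2 = cand * cand
    for _ in range(sweeps):
        for par in (parity, ~parity):
            psi = cand[labels]
            s1, s2, k = _neighbor_sums(psi)
            sel = par
            cost = (
                rhat[sel]
                + mu * inv_f2
                * (k[sel, None] * c2[None, :] - 2.0 * s1[sel, None] * cand[None, :] + s2[sel, None])
            )
            labels[sel] = np.argmin(cost, axis=-1)
    return labels


def _discrete_fieldmap_init(
    signal2d: np.ndarray,
    rhat: np.ndarray,
    cand: np.ndarray,
    echo_times: np.ndarray,
    spectrum: FatSpectrum,
    magnitude_discrimination: bool,
) -> np.ndarray:
    """Per-voxel residual argmin with tie handling.

    Candidates are pre-ordered by |psi|, so argmin's first occurrence
    realises the smaller-|psi| tie-break.  With magnitude discrimination
    on, candidates tying with the minimum (relative 1e-9) are instead
    resolved toward the solution whose dominant species fraction
    max(|W|,|F|)/(|W|+|F|) is largest — the most decisive water-or-fat
    assignment.
    """
    labels = np.argmin(rhat, axis=-1)
    if not magnitude_discrimination:
        return labels
    rmin = rhat[np.arange(rhat.shape[0]), labels]
    tol = 1e-9
    tied = rhat <= (rmin * (1 + tol) + tol * 1e-9)[:, None]
    power = (signal2d.conj() * signal2d).sum(axis=1).real
    multi = (tied.sum(axis=1) > 1) & (power > 0)
    if not np.any(multi):
        return labels
    c = fat_modulation(spectrum, echo_times)
    for v in np.nonzero(multi)[0]:
        cands = np.nonzero(tied[v])[0]
        best, best_score = labels[v], -1.0
        for ci in cands:
            A = _basis(echo_times, c, cand[ci], 0.0)
            w, f, _ = _solve_linear(signal2d[v], A)
            tot = abs(w) + abs(f)
            score = max(abs(w), abs(f)) / tot if tot > 0 else 0.0
            if score > best_score + 1e-15:
                best, best_score = ci, score
        labels[v] = best
    return labels


def estimate_fieldmap_multiscale(image, spectrum: FatSpectrum, opts: ReconOptions) -> np.ndarray:
    """Estimate the B0 field map (Hz) by regularised multi-scale search.

    The ICM stage couples neighbours through a quadratic penalty weighted
    by mu; coarse-scale labellings initialise finer scales, which is what
    suppresses water-fat swapped local minima.  With mu = 0 the result is
    the independent per-voxel residual minimiser (brute-force search).
    """
    protocol = image.protocol
    te = protocol.echo_times
    cand = opts.psi_candidates(protocol.delta_te)
    f_scale = 1.0 / (2.0 * protocol.delta_te)

    if opts.mu == 0:
        # unregularised: the estimate is the independent per-voxel
        # minimiser, identical to exhaustive search (pyramid irrelevant)
        s2d = image.signal.reshape(-1, image.signal.shape[3])
        m_flat = _psi_orthobases(tuple(te), _spectrum_key(spectrum), tuple(cand))
        resid = _candidate_residuals(s2d, m_flat)
        power = (s2d.conj() * s2d).sum(axis=1).real
        rhat = resid / np.maximum(power, 1e-300)[:, None]
        labels = _discrete_fieldmap_init(
            s2d, rhat, cand, te, spectrum, opts.magnitude_discrimination
        )
        return cand[labels].reshape(image.signal.shape[:3])

    pyramid = [image.signal]
    for _ in range(opts.n_scales - 1):
        prev = pyramid[-1]
        if min(prev.shape[0], prev.shape[1]) < 8:
            break
        pyramid.append(_downsample2(prev))

    m_flat = _psi_orthobases(tuple(te), _spectrum_key(spectrum), tuple(cand))

    labels = None
    for vol in reversed(pyramid):
        shape = vol.shape[:3]
        s2d = vol.reshape(-1, vol.shape[3])
        resid = _candidate_residuals(s2d, m_flat)
        power = (s2d.conj() * s2d).sum(axis=1).real
        rhat = resid / np.maximum(power, 1e-300)[:, None]
        rhat3 = rhat.reshape(shape + (cand.size,))
        if labels is None:
            if opts.mu > 0:
                init = _viterbi_init(rhat3, cand, opts.mu, f_scale)
            else:
                init = _discrete_fieldmap_init(
                    s2d, rhat, cand, te, spectrum, opts.magnitude_discrimination
                )
        else:
            init = _upsample_labels(labels.reshape(prev_shape), shape).ravel()
        labels = _icm_labels(
            rhat3, cand, init.reshape(shape), opts.mu, f_scale, opts.icm_sweeps
        ).ravel()
        prev_shape = shape

    return cand[labels].reshape(image.signal.shape[:3])


def estimate_r2s(
    signal: np.ndarray,
    echo_times: Sequence[float],
    spectrum: FatSpectrum,
    psi: np.ndarray,
    opts: Optional[ReconOptions] = None,
) -> np.ndarray:
    """Single (shared) R2* per voxel by 1D discrete search at fixed psi.

    Ties break toward smaller R2* (candidates ascend; first argmin wins).
    """
    opts = opts or ReconOptions()
    te = np.asarray(echo_times, dtype=float)
    s = np.asarray(signal)
    lead = s.shape[:-1]
    s2d = s.reshape(-1, te.size)
    psi_flat = np.asarray(psi, dtype=float).reshape(-1)
    demod = s2d * np.exp(-2j * np.pi * psi_flat[:, None] * te[None, :])
    cand = opts.r2s_candidates()
    m_flat = _r2s_orthobases(tuple(te), _spectrum_key(spectrum), tuple(cand))
    resid = _candidate_residuals(demod, m_flat)
    return cand[np.argmin(resid, axis=1)].reshape(lead)


# ---------------------------------------------------------------------------
# continuous polish and full reconstruction


def _project_out_span(j: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Remove the span(A) component of per-voxel vectors j (..., ne).

    This is the Kaufman form of the variable-projection Jacobian: only
    the part of dA/dtheta * x orthogonal to the basis moves the residual.
    """
    a0 = A[..., 0]
    a1 = A[..., 1]
    g00 = (a0.conj() * a0).sum(axis=-1).real
    g11 = (a1.conj() * a1).sum(axis=-1).real
    g01 = (a0.conj() * a1).sum(axis=-1)
    det = np.maximum(g00 * g11 - (g01.conj() * g01).real, 1e-300)
    b0 = (a0.conj() * j).sum(axis=-1)
    b1 = (a1.conj() * j).sum(axis=-1)
    y0 = (g11 * b0 - g01 * b1) / det
    y1 = (g00 * b1 - g01.conj() * b0) / det
    return j - a0 * y0[..., None] - a1 * y1[..., None]


def _refine_psi_r2s(
    signal2d: np.ndarray,
    echo_times: np.ndarray,
    c: np.ndarray,
    psi: np.ndarray,
    r2s: np.ndarray,
    psi_bounds: Tuple[float, float],
    r2s_max: float,
    iterations: int = 12,
):
    """Vectorised Gauss-Newton polish of (psi, r2s) per voxel.

    Uses the variable-projection residual with the Kaufman approximation
    (amplitude dependence on the nonlinear parameters neglected in the
    Jacobian); exact at the noiseless solution where the residual is zero.
    """
    te = echo_times
    psi = psi.astype(float).copy()
    r2s = r2s.astype(float).copy()
    active = (np.abs(signal2d) ** 2).sum(axis=1) > 0
    for _ in range(iterations):
        A = _basis(te, c, psi, r2s)
        w, f, _ = _solve_linear(signal2d, A)
        model = A[..., 0] * w[..., None] + A[..., 1] * f[..., None]
        rho = signal2d - model
        jpsi = _project_out_span(2j * np.pi * te * model, A)
        jr = _project_out_span(-te * model, A)
        g00 = (jpsi.conj() * jpsi).sum(axis=1).real
        g11 = (jr.conj() * jr).sum(axis=1).real
        g01 = (jpsi.conj() * jr).sum(axis=1).real
        b0 = (jpsi.conj() * rho).sum(axis=1).real
        b1 = (jr.conj() * rho).sum(axis=1).real
        damp = 1e-12 * np.maximum(g00, g11) + 1e-300
        g00 = g00 + damp
        g11 = g11 + damp
        det = np.maximum(g00 * g11 - g01 * g01, 1e-300)
        dpsi = np.where(active, (g11 * b0 - g01 * b1) / det, 0.0)
        dr = np.where(active, (g00 * b1 - g01 * b0) / det, 0.0)
        psi = np.clip(psi + dpsi, psi_bounds[0], psi_bounds[1])
        r2s = np.clip(r2s + dr, 0.0, r2s_max)
        if max(np.abs(dpsi).max(), np.abs(dr).max()) < 1e-10:
            break
    return psi, r2s


def reconstruct_maps(image, spectrum: FatSpectrum, opts: Optional[ReconOptions] = None) -> QuantitativeMaps:
    """Full decoupled reconstruction: field map, then R2*, then W/F.

    FF is |F|/(|F|+|W|), forced to 0 (and flagged) where F+W is below the
    machine-noise floor relative to the strongest voxel.
    """
    opts = opts or ReconOptions()
    protocol = image.protocol
    te = protocol.echo_times
    shape = image.signal.shape[:3]
    s2d = image.signal.reshape(-1, te.size)

    psi = estimate_fieldmap_multiscale(image, spectrum, opts).reshape(-1)
    r2s = estimate_r2s(s2d, te, spectrum, psi, opts).reshape(-1)

    c = fat_modulation(spectrum, te)
    cand = opts.psi_candidates(protocol.delta_te)
    psi_bounds = (float(cand.min()) - opts.fieldmap_step_hz,
                  float(cand.max()) + opts.fieldmap_step_hz)
    if opts.refine:
        psi, r2s = _refine_psi_r2s(s2d, te, c, psi, r2s, psi_bounds, opts.r2s_max)

    A = _basis(te, c, psi, r2s)
    w, f, resid = _solve_linear(s2d, A)
    wmag = np.abs(w)
    fmag = np.abs(f)
    total = wmag + fmag
    floor = 1e-9 * max(float(np.abs(s2d).max()), 1e-300)
    degenerate = total <= floor
    ff = np.where(degenerate, 0.0, fmag / np.maximum(total, 1e-300))

    return QuantitativeMaps(
        water=wmag.reshape(shape),
        fat=fmag.reshape(shape),
        ff=np.clip(ff, 0.0, 1.0).reshape(shape),
        r2s=r2s.reshape(shape),
        fieldmap=psi.reshape(shape),
        residual=resid.reshape(shape),
        voxel_size=tuple(protocol.voxel_size),
        degenerate=degenerate.reshape(shape),
    )
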