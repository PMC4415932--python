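"""Digital neck phantoms and synthetic cooling-reheating cohorts.

The phantom hosts the structures the segmentation stages need: two
cervical-supraclavicular fat blobs (sBAT) in the body interior adjacent
to muscle and a vessel on each side, a posterior subcutaneous fat band
(SAT) along the back surface, a central posterior bone-marrow blob, and
muscle filling the rest of the body.  Geometry and within-tissue
heterogeneity are analytic functions of *anatomical* coordinates, so a
rigid inter-state motion produces exactly transformed truth maps with no
interpolation error; the B0 field map is a smooth low-order polynomial
in *scanner* coordinates (shim fields do not move with the subject).

Axis convention: x = right-left, y = anterior-posterior (posterior =
+y), z = feet-head slices.

The cohort generator emulates the three-scan cooling-reheating study:
per-subject baseline FF/R2* drawn from group distributions, a
lipid-type sBAT-FF change (persists through reheating), a
perfusion-type sBAT-FF change (reverses on reheating), tissue R2*
changes with reversibility flags, and a posture-related SAT-FF drift
applied between the last two scans regardless of temperature.  Defaults
are the study's reported group statistics.  A two-scan procedure-study
mode (no cooling, posture drift only) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .protocol import AcquisitionProtocol, FatSpectrum
from .recon import fat_modulation
from .register import RigidTransform

LABELS = {
    "background": 0,
    "muscle": 1,
    "sbat": 2,
    "sat": 3,
    "vessel": 4,
    "bone_marrow": 5,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass(frozen=True)
class TissueParams:
    """Scalar FF/R2* level of one tissue plus smooth within-tissue spatial
    variation (standard deviations of the spatial fields)."""

    ff: float
    r2s: float
    ff_spatial_sd: float = 0.0
    r2s_spatial_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ff <= 1.0):
            raise ValueError("tissue FF must lie in [0, 1]")
        if self.r2s < 0:
            raise ValueError("tissue R2* must be >= 0")


def default_tissue_params(
    ff_spatial_sd: float = 0.015, r2s_spatial_sd: float = 0.5
) -> Dict[str, TissueParams]:
    """Baseline tissue values: adipose depots at the study's group means,
    muscle lean, vessels pure water (no spatial FF variation so they stay
    exactly fat-free)."""
    return {
        "muscle": TissueParams(0.10, 30.0, ff_spatial_sd, r2s_spatial_sd),
        "sbat": TissueParams(0.828, 21.0, ff_spatial_sd, r2s_spatial_sd),
        "sat": TissueParams(0.852, 19.6, ff_spatial_sd, r2s_spatial_sd),
        "vessel": TissueParams(0.0, 25.0, 0.0, r2s_spatial_sd),
        # trabecular bone drives marrow R2* well above adipose values
        "bone_marrow": TissueParams(0.60, 60.0, ff_spatial_sd, r2s_spatial_sd),
    }


@dataclass
class TruthMaps:
    """Ground-truth water/fat densities, R2*, field map and tissue labels."""

    water: np.ndarray
    fat: np.ndarray
    r2s: np.ndarray
    fieldmap: np.ndarray
    label: np.ndarray
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 2.0)

    def __post_init__(self) -> None:
        shape = self.water.shape
        for name in ("fat", "r2s", "fieldmap", "label"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} does not share the grid shape {shape}")
        if np.any(self.water < 0) or np.any(self.fat < 0):
            raise ValueError("water and fat densities must be >= 0")
        if np.any(self.r2s < 0):
            raise ValueError("r2s must be >= 0 everywhere")

    @property
    def ff(self) -> np.ndarray:
        """True fat fraction F/(F+W), zero where F+W = 0."""
        total = self.water + self.fat
        return np.where(total > 0, self.fat / np.maximum(total, 1e-300), 0.0)

    def mask(self, tissue: str) -> np.ndarray:
        return self.label == LABELS[tissue]


@dataclass
class MultiEchoImage:
    """4D complex multi-echo signal tied to its acquisition protocol."""

    signal: np.ndarray
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, echo)")
        if self.signal.shape[3] != self.protocol.n_echoes:
            raise ValueError("echo axis length must equal protocol.n_echoes")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")


# ---------------------------------------------------------------------------
# smooth random fields (analytic, so they move exactly with the anatomy)


class _CosineField:
    """Unit-variance smooth random field: a sum of low-frequency cosines
    with random orientations and phases, evaluated analytically."""

    def __init__(self, rng: np.random.Generator, n_components: int = 8):
        self.k = rng.uniform(-2.5, 2.5, size=(n_components, 3))
        self.phase = rng.uniform(0, 2 * np.pi, size=n_components)
        self.amp = rng.normal(size=n_components)
        # each cosine has variance amp^2/2 over phase
        self.norm = np.sqrt((self.amp**2).sum() / 2.0)

    def __call__(self, xr, yr, zr) -> np.ndarray:
        out = np.zeros(np.broadcast(xr, yr, zr).shape)
        for (kx, ky, kz), ph, a in zip(self.k, self.phase, self.amp):
            out += a * np.cos(2 * np.pi * (kx * xr + ky * yr + kz * zr) + ph)
        return out / self.norm


# ---------------------------------------------------------------------------
# geometry


def _geometry_masks(grid_shape, xb, yb, zb) -> Dict[str, np.ndarray]:
    """Tissue masks from analytic geometry at base-frame voxel coords."""
    nx, ny, nz = grid_shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry = 0.40 * nx, 0.38 * ny

    rho = np.sqrt(((xb - cx) / rx) ** 2 + ((yb - cy) / ry) ** 2)
    body = rho <= 1.0

    sat_thickness = max(4.0, 0.10 * ny)
    sat = body & (rho >= 1.0 - sat_thickness / ry) & (yb > cy)

    sbat = np.zeros_like(body)
    for side in (-1.0, 1.0):
        bx, by, bz = cx + side * 0.19 * nx, cy - 0.15 * ny, cz
        brx, bry, brz = 0.11 * nx, 0.11 * ny, 0.38 * nz
        sbat |= (
            ((xb - bx) / brx) ** 2 + ((yb - by) / bry) ** 2 + ((zb - bz) / brz) ** 2
        ) <= 1.0

    vessel = np.zeros_like(body)
    for side in (-1.0, 1.0):
        vx, vy = cx + side * 0.30 * nx, cy - 0.15 * ny
        vessel |= ((xb - vx) ** 2 + (yb - vy) ** 2) <= (0.045 * nx) ** 2

    # vertebral marrow: central, well separated from the posterior band
    mx, my = cx, cy + 0.06 * ny
    marrow = (
        ((xb - mx) / (0.07 * nx)) ** 2
        + ((yb - my) / (0.07 * ny)) ** 2
        + ((zb - cz) / (0.45 * nz)) ** 2
    ) <= 1.0

    # priority: vessel > sbat > sat > bone_marrow > muscle
    masks = {}
    taken = np.zeros_like(body)
    for name, m in (
        ("vessel", vessel & body),
        ("sbat", sbat & body),
        ("sat", sat),
        ("bone_marrow", marrow & body),
    ):
        masks[name] = m & ~taken
        taken |= m
    masks["muscle"] = body & ~taken
    return masks


def build_neck_phantom(
    grid_shape: Tuple[int, int, int],
    tissue_params: Optional[Dict[str, TissueParams]] = None,
    seed: int = 0,
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 2.0),
    motion: Optional[RigidTransform] = None,
    fieldmap_amplitude_hz: float = 25.0,
) -> TruthMaps:
    """Generate ground-truth maps for a digital neck phantom.

    ``motion`` (optional) rigidly displaces the anatomy relative to the
    scanner grid; geometry and heterogeneity are re-evaluated at the
    back-transformed coordinates so the truth is exact.  The field map is
    a smooth random low-order polynomial (scanner frame) with typical
    amplitude ``fieldmap_amplitude_hz``.
    """
    nx, ny, nz = (int(v) for v in grid_shape)
    if min(nx, ny, nz) < 1:
        raise ValueError("grid_shape must be positive")
    tissue_params = tissue_params or default_tissue_params()
    missing_params = set(LABELS) - {"background"} - set(tissue_params)
    if missing_params:
        raise ValueError(f"tissue_params missing labels: {sorted(missing_params)}")

    rng = np.random.default_rng(seed)
    # draw all random structure up front, in fixed order, so the same seed
    # yields the same anatomy regardless of tissue parameter values
    het_fields = {
        name: (_CosineField(rng), _CosineField(rng))
        for name in ("muscle", "sbat", "sat", "vessel", "bone_marrow")
    }
    poly = rng.uniform(-1.0, 1.0, size=7)

    x, y, z = np.meshgrid(
        np.arange(nx, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nz, dtype=float),
        indexing="ij",
    )
    vs = np.array(voxel_size, dtype=float)
    if motion is not None and not motion.is_identity:
        pts = np.stack([x, y, z], axis=-1) * vs
        base = motion.inverse().apply_points(pts) / vs
        xb, yb, zb = base[..., 0], base[..., 1], base[..., 2]
    else:
        xb, yb, zb = x, y, z

    masks = _geometry_masks((nx, ny, nz), xb, yb, zb)
    for name, m in masks.items():
        if not m.any():
            raise ValueError(
                f"grid {grid_shape} too small to host tissue label '{name}'"
            )

    label = np.zeros((nx, ny, nz), dtype=np.int16)
    ff = np.zeros((nx, ny, nz))
    r2s = np.zeros((nx, ny, nz))
    xr, yr, zr = xb / nx, yb / ny, zb / max(nz, 1)
    for name, m in masks.items():
        p = tissue_params[name]
        label[m] = LABELS[name]
        ff_field, r2s_field = het_fields[name]
        tile_ff = p.ff + (p.ff_spatial_sd * ff_field(xr, yr, zr)[m] if p.ff_spatial_sd else 0.0)
        tile_r2s = p.r2s + (
            p.r2s_spatial_sd * r2s_field(xr, yr, zr)[m] if p.r2s_spatial_sd else 0.0
        )
        ff[m] = np.clip(tile_ff, 0.0, 0.995)
        r2s[m] = np.clip(tile_r2s, 0.0, None)

    body = label > 0
    water = np.where(body, 1.0 - ff, 0.0)
    fat = np.where(body, ff, 0.0)

    xs, ys, zs = (x - (nx - 1) / 2) / nx, (y - (ny - 1) / 2) / ny, (z - (nz - 1) / 2) / max(nz, 1)
    fieldmap = fieldmap_amplitude_hz * (
        poly[0]
        + poly[1] * xs
        + poly[2] * ys
        + poly[3] * zs
        + poly[4] * xs * ys
        + poly[5] * xs**2
        + poly[6] * ys**2
    )

    return TruthMaps(
        water=water,
        fat=fat,
        r2s=r2s,
        fieldmap=fieldmap,
        label=label,
        voxel_size=tuple(voxel_size),
    )


def simulate_multiecho(
    truth: TruthMaps,
    protocol: AcquisitionProtocol,
    spectrum: FatSpectrum,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MultiEchoImage:
    """Simulate the multi-echo complex signal from ground-truth maps.

    Per voxel: s(TE_n) = (W + F c_n) exp(i 2 pi psi TE_n) exp(-R2* TE_n),
    plus independent complex Gaussian noise of standard deviation
    ``noise_sd`` on the real and imaginary parts of every voxel/echo.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if truth.water.shape != tuple(protocol.grid_shape):
        raise ValueError(
            f"truth grid {truth.water.shape} incompatible with protocol grid "
            f"{tuple(protocol.grid_shape)}"
        )
    te = protocol.echo_times
    c = fat_modulation(spectrum, te)
    w = truth.water[..., None]
    f = truth.fat[..., None]
    decay = np.exp(
        (2j * np.pi * truth.fieldmap[..., None] - truth.r2s[..., None]) * te
    )
    signal = (w + f * c) * decay
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + noise_sd * (
            rng.standard_normal(signal.shape) + 1j * rng.standard_normal(signal.shape)
        )
    return MultiEchoImage(signal=signal, protocol=protocol)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class EffectSpec:
    """A per-subject normally distributed effect (mean, SD)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("effect SD must be >= 0")

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.normal(self.mean, self.sd)) if self.sd > 0 else self.mean


@dataclass(frozen=True)
class R2sChange(EffectSpec):
    reversible: bool = True


COOLING_STATES = ("Baseline", "Cold", "Reheated")
PROCEDURE_STATES = ("Scan1", "Scan2")


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    FF levels are fractions; FF effects are in percentage points (pp);
    R2* in s^-1.  Defaults reproduce the cooling-reheating study's group
    statistics: baseline sBAT-FF 82.8 +- 5.0 %, SAT-FF 85.2 +- 5.1 %,
    sBAT-R2* 21.0 +- 1.8, SAT-R2* 19.6 +- 2.8 s^-1; lipid-type sBAT-FF
    change -1.94 +- 1.83 pp (persists through reheating), no perfusion
    component, posture-related SAT-FF drift -0.79 +- 0.27 pp between the
    Cold and Reheated scans, sBAT-R2* +0.65 +- 0.88 s^-1 (reversible) and
    SAT-R2* +0.40 +- 0.46 s^-1 (persistent) on cooling.
    """

    n_subjects: int = 9
    mode: str = "cooling_reheating"
    grid_shape: Tuple[int, int, int] = (32, 32, 8)
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 2.0)
    sbat_ff_baseline: EffectSpec = EffectSpec(0.828, 0.050)
    sat_ff_baseline: EffectSpec = EffectSpec(0.852, 0.051)
    sbat_r2s_baseline: EffectSpec = EffectSpec(21.0, 1.8)
    sat_r2s_baseline: EffectSpec = EffectSpec(19.6, 2.8)
    sbat_lipid_ff_change: EffectSpec = EffectSpec(-1.94, 1.83)
    sbat_perfusion_ff_change: EffectSpec = EffectSpec(0.0, 0.0)
    sat_posture_ff_drift: EffectSpec = EffectSpec(-0.79, 0.27)
    r2s_changes: Dict[str, R2sChange] = field(
        default_factory=lambda: {
            "sbat": R2sChange(0.65, 0.88, reversible=True),
            "sat": R2sChange(0.40, 0.46, reversible=False),
        }
    )
    noise_sd: float = 0.02  # SNR ~50 against unit in-body proton density
    ff_spatial_sd: float = 0.015
    r2s_spatial_sd: float = 0.5
    motion_translation_mm: float = 3.0
    motion_rotation_deg: float = 3.0
    crude_dilation: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.mode not in ("cooling_reheating", "procedure_study"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("sbat_ff_baseline", "sat_ff_baseline"):
            if not (0.0 < getattr(self, name).mean < 1.0):
                raise ValueError(f"{name} mean must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def states(self) -> Tuple[str, ...]:
        return COOLING_STATES if self.mode == "cooling_reheating" else PROCEDURE_STATES

    @property
    def protocol(self) -> AcquisitionProtocol:
        return AcquisitionProtocol(
            grid_shape=tuple(self.grid_shape), voxel_size=tuple(self.voxel_size)
        )

    @classmethod
    def procedure_study(cls, **kwargs) -> "CohortSpec":
        """Two-scan no-cooling variant (n = 8): posture drift only."""
        defaults = dict(
            n_subjects=8,
            mode="procedure_study",
            sbat_lipid_ff_change=EffectSpec(0.0, 0.0),
            sbat_perfusion_ff_change=EffectSpec(0.0, 0.0),
            sat_posture_ff_drift=EffectSpec(-0.75, 0.64),
            r2s_changes={},
        )
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass
class SubjectDraw:
    """Per-subject tissue levels and effects, per state (truth scalars)."""

    subject: int
    state_values: Dict[str, Dict[str, float]]  # state -> {sbat_ff, sat_ff, ...}
    effects: Dict[str, float]


def _draw_subject(spec: CohortSpec, subject: int, rng: np.random.Generator) -> SubjectDraw:
    sbat_ff = float(np.clip(spec.sbat_ff_baseline.draw(rng), 0.05, 0.98))
    sat_ff = float(np.clip(spec.sat_ff_baseline.draw(rng), 0.05, 0.98))
    sbat_r2s = float(np.clip(spec.sbat_r2s_baseline.draw(rng), 5.0, None))
    sat_r2s = float(np.clip(spec.sat_r2s_baseline.draw(rng), 5.0, None))
    lipid = spec.sbat_lipid_ff_change.draw(rng)
    perfusion = spec.sbat_perfusion_ff_change.draw(rng)
    drift = spec.sat_posture_ff_drift.draw(rng)
    d_r2s = {t: ch.draw(rng) for t, ch in spec.r2s_changes.items()}

    def vals(sbat_dff_pp, sat_dff_pp, sbat_dr2s, sat_dr2s):
        return {
            "sbat_ff": float(np.clip(sbat_ff + sbat_dff_pp / 100.0, 0.01, 0.995)),
            "sat_ff": float(np.clip(sat_ff + sat_dff_pp / 100.0, 0.01, 0.995)),
            "sbat_r2s": max(sbat_r2s + sbat_dr2s, 0.0),
            "sat_r2s": max(sat_r2s + sat_dr2s, 0.0),
        }

    sbat_dr = d_r2s.get("sbat")
    sat_dr = d_r2s.get("sat")
    sbat_cold = sbat_dr if sbat_dr is not None else 0.0
    sat_cold = sat_dr if sat_dr is not None else 0.0
    sbat_spec = spec.r2s_changes.get("sbat")
    sat_spec = spec.r2s_changes.get("sat")
    sbat_reheat = 0.0 if (sbat_spec is None or sbat_spec.reversible) else sbat_cold
    sat_reheat = 0.0 if (sat_spec is None or sat_spec.reversible) else sat_cold

    if spec.mode == "cooling_reheating":
        state_values = {
            "Baseline": vals(0.0, 0.0, 0.0, 0.0),
            "Cold": vals(lipid + perfusion, 0.0, sbat_cold, sat_cold),
            "Reheated": vals(lipid, drift, sbat_reheat, sat_reheat),
        }
    else:
        state_values = {
            "Scan1": vals(0.0, 0.0, 0.0, 0.0),
            "Scan2": vals(0.0, drift, 0.0, 0.0),
        }
    return SubjectDraw(
        subject=subject,
        state_values=state_values,
        effects={
            "lipid_pp": lipid,
            "perfusion_pp": perfusion,
            "sat_drift_pp": drift,
            **{f"d_r2s_{t}": v for t, v in d_r2s.items()},
        },
    )


def _random_motion(spec: CohortSpec, rng: np.random.Generator) -> RigidTransform:
    t_xy = rng.uniform(-spec.motion_translation_mm, spec.motion_translation_mm, size=2)
    t_z = rng.uniform(-spec.voxel_size[2], spec.voxel_size[2])
    rot = rng.uniform(-spec.motion_rotation_deg, spec.motion_rotation_deg, size=3)
    center = tuple(
        (n - 1) / 2.0 * v for n, v in zip(spec.grid_shape, spec.voxel_size)
    )
    return RigidTransform(
        rotation_deg=tuple(rot),
        translation_mm=(float(t_xy[0]), float(t_xy[1]), float(t_z)),
        center_mm=center,
    )


@dataclass
class StateScan:
    image: MultiEchoImage
    truth: TruthMaps
    motion: RigidTransform


@dataclass
class SubjectScans:
    subject: int
    states: Dict[str, StateScan]
    crude_sbat: np.ndarray
    draw: SubjectDraw


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: List[SubjectScans]
    ledger: pd.DataFrame


def simulate_cohort_draws(spec: CohortSpec) -> List[SubjectDraw]:
    """Draw only the per-subject truth scalars (no image simulation).

    This is the generator's statistical core; the full simulator realises
    these values as phantom scans.  Useful for fast Monte-Carlo studies
    of the downstream statistics.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    return [
        _draw_subject(spec, i + 1, np.random.default_rng(s))
        for i, s in enumerate(streams)
    ]


def draws_to_ledger(spec: CohortSpec, draws: List[SubjectDraw]) -> pd.DataFrame:
    rows = []
    for d in draws:
        for state in spec.states:
            v = d.state_values[state]
            for voi in ("sbat", "sat"):
                rows.append(
                    {
                        "subject": d.subject,
                        "state": state,
                        "voi": voi,
                        "true_mean_ff_pct": 100.0 * v[f"{voi}_ff"],
                        "true_mean_r2s": v[f"{voi}_r2s"],
                    }
                )
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: CohortSpec, spectrum: Optional[FatSpectrum] = None
) -> Cohort:
    """Simulate a full synthetic cohort of multi-echo scans.

    Returns per-subject scans for each state (multi-echo image, exact
    truth maps, the applied rigid motion), a crude over-segmented sBAT
    mask on the first-state grid, and a truth ledger of per-subject true
    VOI means (spatial means over the true tissue masks, in % and s^-1).
    """
    from scipy.ndimage import binary_dilation

    spectrum = spectrum or FatSpectrum.nine_peak(1.5)
    protocol = spec.protocol
    draws = simulate_cohort_draws(spec)
    root = np.random.SeedSequence((spec.seed, 1))
    streams = root.spawn(spec.n_subjects)

    subjects = []
    rows = []
    for draw, stream in zip(draws, streams):
        rng = np.random.default_rng(stream)
        phantom_seed = int(rng.integers(0, 2**31 - 1))
        states: Dict[str, StateScan] = {}
        for k, state in enumerate(spec.states):
            v = draw.state_values[state]
            params = default_tissue_params(spec.ff_spatial_sd, spec.r2s_spatial_sd)
            params["sbat"] = replace(params["sbat"], ff=v["sbat_ff"], r2s=v["sbat_r2s"])
            params["sat"] = replace(params["sat"], ff=v["sat_ff"], r2s=v["sat_r2s"])
            motion = RigidTransform() if k == 0 else _random_motion(spec, rng)
            truth = build_neck_phantom(
                spec.grid_shape,
                params,
                seed=phantom_seed,
                voxel_size=spec.voxel_size,
                motion=motion,
            )
            noise_seed = int(rng.integers(0, 2**31 - 1))
            image = simulate_multiecho(
                truth, protocol, spectrum, noise_sd=spec.noise_sd, seed=noise_seed
            )
            states[state] = StateScan(image=image, truth=truth, motion=motion)
            ff = truth.ff
            for voi in ("sbat", "sat"):
                m = truth.mask(voi)
                rows.append(
                    {
                        "subject": draw.subject,
                        "state": state,
                        "voi": voi,
                        "true_mean_ff_pct": 100.0 * float(ff[m].mean()),
                        "true_mean_r2s": float(truth.r2s[m].mean()),
                    }
                )

        first = states[spec.states[0]].truth
        crude = binary_dilation(
            first.mask("sbat"), structure=np.ones((3, 3, 3), bool), iterations=spec.crude_dilation
        )
        subjects.append(
            SubjectScans(subject=draw.subject, states=states, crude_sbat=crude, draw=draw)
        )

    return Cohort(spec=spec, subjects=subjects, ledger=pd.DataFrame(rows))
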