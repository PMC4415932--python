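"""Acquisition protocol and fat-spectrum definitions.

The default :class:`AcquisitionProtocol` reproduces a clinical 1.5 T
multi-echo 3D spoiled gradient-echo water--fat protocol of the neck:
six unipolar echoes, TE1 = 1.68 ms, echo spacing 2.87 ms, TR = 32.7 ms,
flip angle 6 deg (small, so T1 weighting is negligible and is not
modelled), 1.0 x 1.0 x 2.0 mm voxels, axial slices.

The default :class:`FatSpectrum` is a nine-resonance triglyceride proton
spectrum derived from the standard chain-length / double-bond
parameterisation (number of carbons ``cl``, double bonds ``ndb``,
methylene-interrupted double bonds ``nmidb``).  Frequencies are stored in
Hz relative to water at the protocol field strength; the dominant
methylene peak at 1.30 ppm sits near -217 Hz at 1.5 T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

GYROMAGNETIC_RATIO_MHZ_PER_T = 42.5774785  # proton, MHz/T
WATER_PPM = 4.7

# Triglyceride resonances: (ppm, proton-count expression).  Proton counts
# follow the standard model: methyl 9H, methylene 6(cl-4)-8ndb+2nmidb,
# beta-carboxyl 6H, allylic 4(ndb-nmidb), alpha-carboxyl 6H, diallylic
# 2nmidb, glycerol 4H + 1H, olefinic 2ndb.
_TG_PPM = (0.90, 1.30, 1.60, 2.02, 2.24, 2.75, 4.20, 5.19, 5.29)


def _triglyceride_proton_counts(cl: float, ndb: float, nmidb: float) -> np.ndarray:
    return np.array(
        [
            9.0,
            6.0 * (cl - 4.0) - 8.0 * ndb + 2.0 * nmidb,
            6.0,
            4.0 * (ndb - nmidb),
            6.0,
            2.0 * nmidb,
            4.0,
            1.0,
            2.0 * ndb,
        ]
    )


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Echo timing, field strength and geometry of a multi-echo scan.

    Parameters use SI units (seconds, tesla) except ``voxel_size`` which is
    in millimetres following NIfTI convention.  ``grid_shape`` is ordered
    (x = right-left, y = anterior-posterior, z = feet-head slices).
    """

    field_strength: float = 1.5
    n_echoes: int = 6
    te_first: float = 1.68e-3
    delta_te: float = 2.87e-3
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 2.0)
    grid_shape: Tuple[int, int, int] = (480, 200, 25)
    flip_angle: float = 6.0
    tr: float = 32.7e-3

    def __post_init__(self) -> None:
        if self.n_echoes < 3:
            raise ValueError("n_echoes must be >= 3 for water/fat/R2* estimation")
        if self.te_first <= 0:
            raise ValueError("te_first must be positive")
        if self.delta_te <= 0:
            raise ValueError("delta_te must be positive (echo times strictly increasing)")
        if any(v <= 0 for v in self.voxel_size) or len(self.voxel_size) != 3:
            raise ValueError("voxel_size must be three positive lengths (mm)")
        if any(int(n) <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive counts")
        if self.field_strength <= 0:
            raise ValueError("field_strength must be positive")

    @property
    def echo_times(self) -> np.ndarray:
        """Echo times TE_n = TE1 + (n-1)*dTE, in seconds."""
        return self.te_first + self.delta_te * np.arange(self.n_echoes)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def replace(self, **kwargs) -> "AcquisitionProtocol":
        from dataclasses import replace

        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "field_strength": self.field_strength,
            "n_echoes": self.n_echoes,
            "te_first": self.te_first,
            "delta_te": self.delta_te,
            "voxel_size": list(self.voxel_size),
            "grid_shape": list(self.grid_shape),
            "flip_angle": self.flip_angle,
            "tr": self.tr,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        d = dict(d)
        d["voxel_size"] = tuple(d["voxel_size"])
        d["grid_shape"] = tuple(int(v) for v in d["grid_shape"])
        return cls(**d)


@dataclass(frozen=True)
class FatSpectrum:
    """Multi-peak fat resonance model.

    ``peaks`` holds (frequency offset in Hz relative to water at
    ``reference_field``, relative amplitude) pairs; amplitudes are positive
    and sum to one.
    """

    peaks: Tuple[Tuple[float, float], ...]
    reference_field: float = 1.5

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError("spectrum must contain at least one peak")
        amps = np.array([a for _, a in self.peaks], dtype=float)
        if np.any(amps <= 0):
            raise ValueError("relative amplitudes must be positive")
        if abs(amps.sum() - 1.0) > 1e-9:
            raise ValueError(f"relative amplitudes must sum to 1 (got {amps.sum()!r})")
        if self.reference_field <= 0:
            raise ValueError("reference_field must be positive")

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.array([f for f, _ in self.peaks], dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for _, a in self.peaks], dtype=float)

    def at_field(self, field_strength: float) -> "FatSpectrum":
        """Rescale peak frequencies to another field strength (chemical
        shifts in ppm are field-independent; Hz offsets scale linearly)."""
        scale = field_strength / self.reference_field
        return FatSpectrum(
            peaks=tuple((f * scale, a) for f, a in self.peaks),
            reference_field=field_strength,
        )

    @classmethod
    def nine_peak(
        cls,
        field_strength: float = 1.5,
        cl: float = 17.4,
        ndb: float = 2.8,
        nmidb: float = 0.7,
    ) -> "FatSpectrum":
        """Nine-peak triglyceride spectrum from the proton-count model.

        Defaults (cl=17.4, ndb=2.8, nmidb=0.7) are typical in-vivo
        triglyceride composition values.
        """
        counts = _triglyceride_proton_counts(cl, ndb, nmidb)
        amps = counts / counts.sum()
        hz_per_ppm = GYROMAGNETIC_RATIO_MHZ_PER_T * field_strength
        freqs = (np.array(_TG_PPM) - WATER_PPM) * hz_per_ppm
        return cls(
            peaks=tuple((float(f), float(a)) for f, a in zip(freqs, amps)),
            reference_field=field_strength,
        )

    @classmethod
    def single_peak(cls, frequency_hz: float = -217.0, field_strength: float = 1.5) -> "FatSpectrum":
        """Degenerate single-resonance spectrum (useful for closed-form tests)."""
        return cls(peaks=((frequency_hz, 1.0),), reference_field=field_strength)

    def to_dict(self) -> dict:
        return {"peaks": [list(p) for p in self.peaks], "reference_field": self.reference_field}

    @classmethod
    def from_dict(cls, d: dict) -> "FatSpectrum":
        return cls(peaks=tuple(tuple(p) for p in d["peaks"]), reference_field=d["reference_field"])
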