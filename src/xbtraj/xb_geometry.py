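"""Per-frame halogen-bond geometry and region classification.

Two numbers describe a halogen bond in each frame: the X···A distance *d*
(halogen to acceptor, Å) and the σ-hole angle *θ* (the C–X···A angle with
vertex at the halogen, degrees; 180° is the ideal collinear geometry,
because the σ-hole sits on the halogen directly opposite the C–X bond).

The (d, θ) plane is partitioned into four regions:

* ``primary``          — d < d_cut and θ > theta_cut: a geometrically
  correct halogen bond (defaults 4.0 Å, 140°);
* ``secondary_short``  — d < d_cut but θ ≤ theta_cut (close but
  misaligned — a weak halogen bond);
* ``secondary_long``   — d ≥ d_cut but θ > theta_cut (aligned but
  stretched — a weak halogen bond);
* ``none``             — neither condition holds.

Boundary convention: the favourable inequalities are strict, so a frame
sitting exactly at d = d_cut or θ = theta_cut falls in the less favourable
region.  This is a measure-zero choice with no effect on occupancy
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateGeometryError
from .io_structures import Frame, Trajectory
from .perception import XBContact

REGIONS = ("primary", "secondary_short", "secondary_long", "none")


@dataclass(frozen=True)
class RegionThresholds:
    """Cutoffs splitting the distance–angle plane into the four regions."""

    d_cut: float = 4.0
    theta_cut: float = 140.0

    def __post_init__(self) -> None:
        if self.d_cut <= 0:
            raise ValueError("d_cut must be positive")
        if not 0 < self.theta_cut < 180:
            raise ValueError("theta_cut must lie in (0, 180)")


DEFAULT_THRESHOLDS = RegionThresholds()


def xb_distance(frame: Frame, contact: XBContact) -> float:
    """Euclidean X···A distance (Å) for one frame."""
    x = frame.coordinates[contact.donor.halogen.coords_index]
    a = frame.coordinates[contact.acceptor.atom.coords_index]
    return float(np.linalg.norm(a - x))


def sigma_hole_angle(frame: Frame, contact: XBContact) -> float:
    """σ-hole angle C–X···A (degrees), vertex at the halogen.

    Raises :class:`DegenerateGeometryError` when either the C–X or X–A
    vector has zero length.
    """
    c = frame.coordinates[contact.donor.carbon.coords_index]
    x = frame.coordinates[contact.donor.halogen.coords_index]
    a = frame.coordinates[contact.acceptor.atom.coords_index]
    v1 = c - x
    v2 = a - x
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError(
            "zero-length C-X or X-A vector; sigma-hole angle undefined"
        )
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def classify_region(
    d: float, theta: float, thresholds: RegionThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Assign one (d, θ) point to exactly one region of the plane."""
    short = d < thresholds.d_cut
    aligned = theta > thresholds.theta_cut
    if short and aligned:
        return "primary"
    if short:
        return "secondary_short"
    if aligned:
        return "secondary_long"
    return "none"


def classify_regions(
    d: np.ndarray,
    theta: np.ndarray,
    thresholds: RegionThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Vectorised :func:`classify_region`."""
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    short = d < thresholds.d_cut
    aligned = theta > thresholds.theta_cut
    out = np.full(d.shape, "none", dtype=object)
    out[short & aligned] = "primary"
    out[short & ~aligned] = "secondary_short"
    out[~short & aligned] = "secondary_long"
    return out


@dataclass
class GeometrySeries:
    """Per-frame (time, d, θ, region) records for one tracked contact."""

    contact: XBContact | None
    data: pd.DataFrame  # columns: time_ns, distance_A, sigma_hole_deg, region
    thresholds: RegionThresholds = field(default_factory=RegionThresholds)

    REQUIRED_COLUMNS = ("time_ns", "distance_A", "sigma_hole_deg", "region")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"GeometrySeries data missing columns {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def label(self) -> str:
        return self.contact.label if self.contact is not None else "contact"

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_arrays(
        cls,
        time_ns,
        distance_A,
        sigma_hole_deg,
        contact: XBContact | None = None,
        thresholds: RegionThresholds = DEFAULT_THRESHOLDS,
    ) -> "GeometrySeries":
        d = np.asarray(distance_A, dtype=float)
        th = np.asarray(sigma_hole_deg, dtype=float)
        df = pd.DataFrame(
            {
                "time_ns": np.asarray(time_ns, dtype=float),
                "distance_A": d,
                "sigma_hole_deg": th,
                "region": classify_regions(d, th, thresholds),
            }
        )
        return cls(contact=contact, data=df, thresholds=thresholds)


def contact_series(
    traj: Trajectory,
    contact: XBContact,
    thresholds: RegionThresholds = DEFAULT_THRESHOLDS,
) -> GeometrySeries:
    """Measure d and θ for every frame and classify each into a region."""
    ci = contact.donor.carbon.coords_index
    xi = contact.donor.halogen.coords_index
    ai = contact.acceptor.atom.coords_index
    coords = np.stack([fr.coordinates for fr in traj.frames])
    c, x, a = coords[:, ci], coords[:, xi], coords[:, ai]
    v1 = c - x
    v2 = a - x
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0.0) or np.any(n2 == 0.0):
        raise DegenerateGeometryError(
            "zero-length C-X or X-A vector in at least one frame"
        )
    d = n2
    theta = np.degrees(
        np.arccos(np.clip(np.sum(v1 * v2, axis=1) / (n1 * n2), -1.0, 1.0))
    )
    return GeometrySeries.from_arrays(
        traj.times_ns, d, theta, contact=contact, thresholds=thresholds
    )
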