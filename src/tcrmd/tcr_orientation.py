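"""Relative orientation of the TCR variable domains.

Each domain is reduced to its first and second principal axes, computed
from the C-alpha atoms of a conserved residue core, plus an anchor point
(the core centroid).  Six quantities describe the inter-domain geometry:

* ``BA``  - signed torsion between the two first axes about the
  inter-anchor vector C (degrees, (-180, 180]).
* ``AC1``/``BC1`` - tilt: angle between a domain's first axis and C
  (resp. -C) (degrees).
* ``AC2``/``BC2`` - twist: angle between a domain's second axis and C
  (resp. -C) (degrees).
* ``DC``  - anchor separation (nm).

Axis signs are fixed against a reference orientation so smoothly varying
coordinates never produce 180-degree sign flips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateFrameError
from .trajectory_io import Ensemble, ComplexAnnotation

ANGLE_LABELS = ("BA", "BC1", "BC2", "AC1", "AC2", "DC")


@dataclass
class DomainFrame:
    """Principal axes (orthonormal, sign-fixed) and anchor of one domain."""

    axis1: np.ndarray
    axis2: np.ndarray
    anchor: np.ndarray


@dataclass
class OrientationAngles:
    BA: float
    AC1: float
    BC1: float
    AC2: float
    BC2: float
    DC: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ANGLE_LABELS}


@dataclass
class OrientationReference:
    """Shared sign-fixing reference: one DomainFrame per domain."""

    alpha: DomainFrame
    beta: DomainFrame


def domain_frame(
    core_coords: np.ndarray,
    reference: DomainFrame | None = None,
) -> DomainFrame:
    """Principal-axis frame of a conserved-core C-alpha point set.

    Axes are the first two right singular vectors of the centred
    coordinates.  With a reference, each axis's sign is chosen to maximise
    its dot product with the reference axis; otherwise signs follow a
    structure-internal convention (positive projection onto the vector from
    the last to the first core residue), which is rotation-equivariant and
    stable from frame to frame for rigid-ish cores.
    """
    pts = np.asarray(core_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegenerateFrameError(f"core coordinates must be (k, 3), got {pts.shape}")
    if pts.shape[0] < 4:
        raise DegenerateFrameError("need >= 4 core residues")
    anchor = pts.mean(axis=0)
    centered = pts - anchor
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateFrameError("core C-alpha set is (nearly) collinear")
    a1, a2 = vt[0].copy(), vt[1].copy()
    if reference is not None:
        if np.dot(a1, reference.axis1) < 0:
            a1 = -a1
        if np.dot(a2, reference.axis2) < 0:
            a2 = -a2
    else:
        internal = pts[0] - pts[-1]
        scale = np.linalg.norm(internal)
        for a in (a1, a2):
            proj = np.dot(a, internal)
            if abs(proj) > 1e-6 * scale:
                if proj < 0:
                    a *= -1.0
            elif a[np.argmax(np.abs(a))] < 0:  # fallback: core ordering orthogonal to axis
                a *= -1.0
    return DomainFrame(axis1=a1, axis2=a2, anchor=anchor)


def _signed_torsion(v_a: np.ndarray, axis: np.ndarray, v_b: np.ndarray) -> float:
    """Signed dihedral (deg) between v_a and v_b about ``axis`` (right-hand rule)."""
    u = axis / np.linalg.norm(axis)
    pa = v_a - np.dot(v_a, u) * u
    pb = v_b - np.dot(v_b, u) * u
    na, nb = np.linalg.norm(pa), np.linalg.norm(pb)
    if na < 1e-12 or nb < 1e-12:
        raise DegenerateFrameError("torsion undefined: axis parallel to a principal axis")
    x = np.dot(pa, pb)
    y = np.dot(np.cross(pa, pb), u)
    return float(np.degrees(np.arctan2(y, x)))


def _angle(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def orientation_from_frames(alpha: DomainFrame, beta: DomainFrame) -> OrientationAngles:
    """The five angles and distance from two domain frames."""
    c = beta.anchor - alpha.anchor
    dc = float(np.linalg.norm(c))
    if dc < 1e-9:
        raise DegenerateFrameError("coincident domain anchors")
    cu = c / dc
    return OrientationAngles(
        BA=_signed_torsion(alpha.axis1, cu, beta.axis1),
        AC1=_angle(alpha.axis1, cu),
        BC1=_angle(beta.axis1, -cu),
        AC2=_angle(alpha.axis2, cu),
        BC2=_angle(beta.axis2, -cu),
        DC=dc,
    )


def reference_from_coords(
    coords: np.ndarray,
    ensemble: Ensemble,
    annotation: ComplexAnnotation,
) -> OrientationReference:
    """Build a sign-fixing reference from one set of coordinates."""
    ia = annotation.core_calpha_indices(ensemble, "alpha")
    ib = annotation.core_calpha_indices(ensemble, "beta")
    return OrientationReference(
        alpha=domain_frame(coords[ia]),
        beta=domain_frame(coords[ib]),
    )


def orientation_angles(
    coords: np.ndarray,
    ensemble: Ensemble,
    annotation: ComplexAnnotation,
    reference: OrientationReference | None = None,
) -> OrientationAngles:
    """Orientation measurement for one frame."""
    ia = annotation.core_calpha_indices(ensemble, "alpha")
    ib = annotation.core_calpha_indices(ensemble, "beta")
    fa = domain_frame(coords[ia], reference.alpha if reference else None)
    fb = domain_frame(coords[ib], reference.beta if reference else None)
    return orientation_from_frames(fa, fb)


def orientation_series(
    ensembles: Sequence[Ensemble],
    annotation: ComplexAnnotation,
    reference: OrientationReference | None = None,
) -> dict[str, "SampleDistribution"]:
    """Per-frame orientation over all ensembles; one distribution per label.

    With no explicit reference, a shared reference is built from frame 0 of
    the first ensemble so sign conventions are comparable across
    simulations (the default for group comparisons).
    """
    from .group_statistics import SampleDistribution

    if not ensembles:
        raise ValueError("no ensembles")
    if reference is None:
        first = ensembles[0]
        reference = reference_from_coords(first.frames[0], first, annotation)

    values: dict[str, list[float]] = {k: [] for k in ANGLE_LABELS}
    sim_ids: list[str] = []
    for ens in ensembles:
        ia = annotation.core_calpha_indices(ens, "alpha")
        ib = annotation.core_calpha_indices(ens, "beta")
        for frame in ens.frames:
            fa = domain_frame(frame[ia], reference.alpha)
            fb = domain_frame(frame[ib], reference.beta)
            ang = orientation_from_frames(fa, fb)
            for k in ANGLE_LABELS:
                values[k].append(getattr(ang, k))
        sim_ids.extend([ens.sim_id] * ens.n_frames)
    ids = np.array(sim_ids, dtype=object)
    return {
        k: SampleDistribution(np.array(v), ids.copy()) for k, v in values.items()
    }
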