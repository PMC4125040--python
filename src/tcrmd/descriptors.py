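"""Per-frame and per-residue structural descriptors.

Hydrogen-bond footprints use a normalized frequency score: 0 if a residue
mediates no bond in any frame, 1 for one bond persistent in every frame,
above 1 when a residue mediates several bonds at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AnnotationError, UndefinedFluctuationError
from .trajectory_io import Ensemble, ComplexAnnotation, superpose, stride_frames

#: default geometric hydrogen-bond criterion (donor-acceptor distance,
#: hydrogen-donor-acceptor angle) matching common MD analysis defaults
HBOND_DIST_CUTOFF_NM = 0.35
HBOND_ANGLE_CUTOFF_DEG = 30.0
#: a hydrogen within this distance of an N/O is treated as covalently bound
HBOND_COVALENT_H_NM = 0.12

#: van der Waals radii (nm) used for SASA, by element
VDW_RADII_NM: Mapping[str, float] = {
    "H": 0.110,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
}
SASA_PROBE_RADIUS_NM = 0.14
SASA_N_SPHERE_POINTS = 960

_DONOR_ACCEPTOR_ELEMENTS = ("N", "O")
BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond (indices into the ensemble's atom list)."""

    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    donor_acceptor_distance: float
    hda_angle: float


@dataclass
class FootprintProfile:
    """Residue-keyed normalized hydrogen-bond frequency scores.

    Keys are ``(chain_id, residue_index)``; values are nonnegative and may
    exceed 1 for residues mediating several simultaneous bonds.
    """

    scores: dict[tuple[str, int], float]
    selection_pair: tuple[str, str]

    def score(self, chain: str, resid: int) -> float:
        return self.scores.get((chain, resid), 0.0)


def _donor_hydrogen_pairs(
    coords: np.ndarray,
    elements: np.ndarray,
    donor_candidates: np.ndarray,
    h_bond_max: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(donor, hydrogen) index pairs: N/O donors with a covalently close H."""
    heavy = donor_candidates[np.isin(elements[donor_candidates], _DONOR_ACCEPTOR_ELEMENTS)]
    hydrogens = np.nonzero(elements == "H")[0]
    if heavy.size == 0 or hydrogens.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = cdist(coords[heavy], coords[hydrogens])
    di, hi = np.nonzero(d <= h_bond_max)
    return heavy[di], hydrogens[hi]


def detect_hbonds(
    coords: np.ndarray,
    elements: np.ndarray,
    donors_selection: Sequence[int],
    acceptors_selection: Sequence[int],
    dist_cutoff_nm: float = HBOND_DIST_CUTOFF_NM,
    angle_cutoff_deg: float = HBOND_ANGLE_CUTOFF_DEG,
    h_bond_max_nm: float = HBOND_COVALENT_H_NM,
) -> list[HBond]:
    """Detect donor-H...acceptor bonds in one frame.

    A bond requires donor-acceptor distance <= ``dist_cutoff_nm`` and
    hydrogen-donor-acceptor angle <= ``angle_cutoff_deg``.  Donors are N/O
    atoms of ``donors_selection`` carrying a hydrogen within
    ``h_bond_max_nm``; acceptors are N/O atoms of ``acceptors_selection``.
    """
    if dist_cutoff_nm <= 0 or angle_cutoff_deg <= 0:
        raise ValueError("cutoffs must be positive")
    donors_selection = np.asarray(donors_selection, dtype=int)
    acceptors_selection = np.asarray(acceptors_selection, dtype=int)
    elements = np.asarray(elements, dtype=object)

    dons, hyds = _donor_hydrogen_pairs(coords, elements, donors_selection, h_bond_max_nm)
    accs = acceptors_selection[
        np.isin(elements[acceptors_selection], _DONOR_ACCEPTOR_ELEMENTS)
    ]
    if dons.size == 0 or accs.size == 0:
        return []

    da = cdist(coords[dons], coords[accs])  # (n_pairs, n_acc)
    dh = coords[hyds] - coords[dons]  # (n_pairs, 3)
    dav = coords[accs][None, :, :] - coords[dons][:, None, :]  # (n_pairs, n_acc, 3)
    dh_norm = np.linalg.norm(dh, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("pj,paj->pa", dh, dav) / (dh_norm[:, None] * da)
    cosang = np.clip(cosang, -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))

    ok = (da <= dist_cutoff_nm) & (angles <= angle_cutoff_deg) & (da > 1e-12)
    bonds = []
    seen = set()
    for p, a in zip(*np.nonzero(ok)):
        key = (int(dons[p]), int(hyds[p]), int(accs[a]))
        if key[0] == key[2] or key in seen:
            continue
        seen.add(key)
        bonds.append(HBond(*key, float(da[p, a]), float(angles[p, a])))
    return bonds


def hbond_footprint(
    ensembles: Sequence[Ensemble],
    selection_A: Sequence[int] | str,
    selection_B: Sequence[int] | str,
    annotation: ComplexAnnotation | None = None,
    dist_cutoff_nm: float = HBOND_DIST_CUTOFF_NM,
    angle_cutoff_deg: float = HBOND_ANGLE_CUTOFF_DEG,
) -> FootprintProfile:
    """Normalized per-residue frequency of A<->B hydrogen bonds.

    ``score(r)`` = total count over all frames of all ensembles of A<->B
    bonds involving residue ``r``, divided by the total frame count.  Bonds
    are searched in both directions (donor in A/acceptor in B and vice
    versa); both end residues of a bond are incremented.
    """
    if not ensembles:
        raise ValueError("no ensembles")
    labels = (
        selection_A if isinstance(selection_A, str) else "A",
        selection_B if isinstance(selection_B, str) else "B",
    )
    counts: dict[tuple[str, int], float] = {}
    total_frames = 0
    for ens in ensembles:
        sel_a = (annotation.region_atoms(ens, selection_A)
                 if isinstance(selection_A, str) else np.asarray(selection_A, dtype=int))
        sel_b = (annotation.region_atoms(ens, selection_B)
                 if isinstance(selection_B, str) else np.asarray(selection_B, dtype=int))
        if sel_a.size == 0 or sel_b.size == 0:
            raise AnnotationError("empty H-bond selection")
        chains, resids = ens.atom_chains, ens.atom_resids
        total_frames += ens.n_frames
        for frame in ens.frames:
            bonds = detect_hbonds(frame, ens.atom_elements, sel_a, sel_b,
                                  dist_cutoff_nm, angle_cutoff_deg)
            bonds += detect_hbonds(frame, ens.atom_elements, sel_b, sel_a,
                                   dist_cutoff_nm, angle_cutoff_deg)
            for b in bonds:
                for atom in (b.donor_atom, b.acceptor_atom):
                    key = (str(chains[atom]), int(resids[atom]))
                    counts[key] = counts.get(key, 0.0) + 1.0
    scores = {k: v / total_frames for k, v in counts.items()}
    return FootprintProfile(scores=scores, selection_pair=labels)


# ---------------------------------------------------------------------------
# SASA (deterministic Shrake-Rupley point sphere)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _radii_for(elements: np.ndarray, radii: Mapping[str, float]) -> np.ndarray:
    out = np.empty(len(elements))
    for i, e in enumerate(elements):
        try:
            out[i] = radii[e]
        except KeyError:
            raise AnnotationError(f"no SASA radius configured for element {e!r}") from None
    return out


def sasa_frame(
    coords: np.ndarray,
    elements: np.ndarray,
    selection: Sequence[int],
    chains: np.ndarray | None = None,
    resids: np.ndarray | None = None,
    probe_radius_nm: float = SASA_PROBE_RADIUS_NM,
    n_sphere_points: int = SASA_N_SPHERE_POINTS,
    radii: Mapping[str, float] = VDW_RADII_NM,
) -> tuple[dict[tuple[str, int], float], float]:
    """Solvent-accessible surface area of the selected body in one frame.

    Returns ``(per_residue, total)`` in nm^2.  Only selected atoms form the
    body (others neither contribute area nor occlude).  Per-residue areas
    sum to the total exactly.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise AnnotationError("empty SASA selection")
    elements = np.asarray(elements, dtype=object)
    xyz = np.asarray(coords, dtype=float)[sel]
    r = _radii_for(elements[sel], radii) + probe_radius_nm
    pts = sphere_points(n_sphere_points)

    n = sel.size
    areas = np.empty(n)
    # neighbour culling via pairwise distances
    d2 = cdist(xyz, xyz, "sqeuclidean")
    for i in range(n):
        reach = (r[i] + r) ** 2
        nbr = np.nonzero((d2[i] < reach) & (np.arange(n) != i))[0]
        surf = xyz[i] + r[i] * pts
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in nbr:
            exposed &= np.sum((surf - xyz[j]) ** 2, axis=1) > r[j] ** 2
            if not exposed.any():
                break
        areas[i] = 4.0 * np.pi * r[i] ** 2 * exposed.mean()

    per_residue: dict[tuple[str, int], float] = {}
    if chains is None or resids is None:
        keys = [("", 0)] * n
    else:
        chains = np.asarray(chains, dtype=object)
        resids = np.asarray(resids)
        keys = [(str(chains[a]), int(resids[a])) for a in sel]
    for key, area in zip(keys, areas):
        per_residue[key] = per_residue.get(key, 0.0) + float(area)
    return per_residue, float(areas.sum())


def sasa_series(
    ensemble: Ensemble,
    selection: Sequence[int],
    probe_radius_nm: float = SASA_PROBE_RADIUS_NM,
    n_sphere_points: int = SASA_N_SPHERE_POINTS,
    radii: Mapping[str, float] = VDW_RADII_NM,
    stride: int = 1,
) -> np.ndarray:
    """Per-frame total SASA (nm^2) of the selection; carries the frame stride."""
    ens = stride_frames(ensemble, stride)
    totals = np.empty(ens.n_frames)
    for i, frame in enumerate(ens.frames):
        _, totals[i] = sasa_frame(
            frame, ens.atom_elements, selection,
            probe_radius_nm=probe_radius_nm,
            n_sphere_points=n_sphere_points, radii=radii,
        )
    return totals


# ---------------------------------------------------------------------------
# RMSF


def rmsf(
    ensemble: Ensemble,
    target_selection: Sequence[int],
    fit_selection: Sequence[int] | None = None,
) -> dict[tuple[str, int], float]:
    """Per-residue backbone RMSF (nm) about the time-average position.

    If ``fit_selection`` is given the ensemble is superposed internally
    (two-pass mean reference) before fluctuations are measured.  Per-atom
    RMSF values are averaged, unweighted, over each residue's backbone
    atoms (N, CA, C, O).
    """
    if ensemble.n_frames < 2:
        raise UndefinedFluctuationError("RMSF needs at least 2 frames")
    if fit_selection is not None:
        ensemble = superpose(ensemble, fit_selection)
    target = np.asarray(target_selection, dtype=int)
    if target.size == 0:
        raise AnnotationError("empty RMSF selection")
    names = ensemble.atom_names[target]
    target = target[np.isin(names, list(BACKBONE_NAMES))]
    if target.size == 0:
        raise AnnotationError("no backbone atoms (N, CA, C, O) in RMSF selection")

    coords = ensemble.frames[:, target, :]
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))

    chains, resids = ensemble.atom_chains[target], ensemble.atom_resids[target]
    sums: dict[tuple[str, int], list[float]] = {}
    for c, r, v in zip(chains, resids, per_atom):
        sums.setdefault((str(c), int(r)), []).append(float(v))
    return {k: float(np.mean(v)) for k, v in sums.items()}
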