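"""Reading, writing and preprocessing of coordinate ensembles.

Coordinates are stored in nanometres internally; PDB files (Angstrom) are
converted on read and write.  One :class:`Ensemble` holds the full
multi-frame Cartesian history of a single simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    AnnotationError,
    DegenerateFitError,
    EmptyEnsembleError,
    FormatError,
)

ANGSTROM_PER_NM = 10.0

#: residue names dropped on load (solvent / ions)
SOLVENT_RESNAMES = frozenset(
    {"HOH", "SOL", "WAT", "TIP3", "TIP4", "SPC", "NA", "CL", "NA+", "CL-", "K", "K+", "MG", "ION"}
)

_BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Atom:
    """A single atom of the topology."""

    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str


@dataclass
class Ensemble:
    """Atoms plus their coordinates over time for one simulation.

    Attributes
    ----------
    atoms : list of Atom
    frames : (T, N, 3) float array, nm
    times : (T,) float array, ns, strictly increasing
    sim_id : opaque simulation identifier
    """

    atoms: list[Atom]
    frames: np.ndarray
    times: np.ndarray
    sim_id: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise FormatError(f"frames must be (T, N, 3), got {self.frames.shape}")
        if self.frames.shape[1] != len(self.atoms):
            raise FormatError(
                f"frame atom count {self.frames.shape[1]} != topology atom count {len(self.atoms)}"
            )
        if self.frames.shape[0] != self.times.shape[0]:
            raise FormatError("times length must equal frame count")
        if not np.all(np.isfinite(self.frames)):
            raise FormatError("non-finite coordinates")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def _array(self, key, fn, dtype):
        if key not in self._cache:
            self._cache[key] = np.array([fn(a) for a in self.atoms], dtype=dtype)
        return self._cache[key]

    @property
    def atom_names(self) -> np.ndarray:
        return self._array("names", lambda a: a.name, object)

    @property
    def atom_elements(self) -> np.ndarray:
        return self._array("elements", lambda a: a.element, object)

    @property
    def atom_resids(self) -> np.ndarray:
        return self._array("resids", lambda a: a.residue_index, int)

    @property
    def atom_resnames(self) -> np.ndarray:
        return self._array("resnames", lambda a: a.residue_name, object)

    @property
    def atom_chains(self) -> np.ndarray:
        return self._array("chains", lambda a: a.chain_id, object)

    def select(self, chain: str | None = None, resid_range: tuple[int, int] | None = None,
               names: Iterable[str] | None = None) -> np.ndarray:
        """Atom indices matching chain / inclusive residue range / atom names."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.atom_chains == chain
        if resid_range is not None:
            lo, hi = resid_range
            mask &= (self.atom_resids >= lo) & (self.atom_resids <= hi)
        if names is not None:
            mask &= np.isin(self.atom_names, list(names))
        return np.nonzero(mask)[0]


def guess_element(name: str) -> str:
    """Element symbol from a (protein) atom name: first alphabetic character."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def load_ensemble(
    topology_source: str,
    coordinate_sources: Sequence[str] = (),
    sim_id: str = "",
    dt_ns: float = 1.0,
    t0_ns: float = 0.0,
    times_ns: Sequence[float] | None = None,
    drop_solvent: bool = True,
) -> Ensemble:
    """Read a topology plus coordinate files into an :class:`Ensemble`.

    ``coordinate_sources`` are concatenated in order; if empty the topology
    file itself provides the frames (multi-model PDB).  Frame times default
    to ``t0_ns + dt_ns * (i + 1)`` unless ``times_ns`` is given.
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if coordinate_sources:
                u = mda.Universe(topology_source, *coordinate_sources)
            else:
                u = mda.Universe(topology_source)
    except (ValueError, IndexError) as exc:
        raise FormatError(f"inconsistent topology/trajectory: {exc}") from exc
    except OSError:
        raise

    try:
        chains = u.atoms.chainIDs
    except (AttributeError, mda.exceptions.NoDataError):
        chains = u.atoms.segids
    try:
        elements = [e if e else guess_element(n) for e, n in zip(u.atoms.elements, u.atoms.names)]
    except (AttributeError, mda.exceptions.NoDataError):
        elements = [guess_element(n) for n in u.atoms.names]

    atoms = [
        Atom(name=str(n), element=str(e), residue_index=int(r), residue_name=str(rn),
             chain_id=str(c))
        for n, e, r, rn, c in zip(u.atoms.names, elements, u.atoms.resids,
                                  u.atoms.resnames, chains)
    ]

    keep = np.arange(len(atoms))
    if drop_solvent:
        keep = np.array(
            [i for i, a in enumerate(atoms) if a.residue_name.upper() not in SOLVENT_RESNAMES],
            dtype=int,
        )
        atoms = [atoms[i] for i in keep]

    coords = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            for ts in u.trajectory:
                coords.append(ts.positions[keep] / ANGSTROM_PER_NM)
        except (ValueError, IndexError) as exc:
            raise FormatError(f"trajectory/topology atom mismatch: {exc}") from exc
    frames = np.array(coords, dtype=float)

    if times_ns is not None:
        times = np.asarray(times_ns, dtype=float)
    else:
        times = t0_ns + dt_ns * (np.arange(frames.shape[0]) + 1)
    return Ensemble(atoms=atoms, frames=frames, times=times, sim_id=sim_id)


def write_pdb(ensemble: Ensemble, path: str) -> None:
    """Write all frames as a multi-model PDB (coordinates nm -> Angstrom)."""
    with open(path, "w") as fh:
        for m, frame in enumerate(ensemble.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (atom, xyz) in enumerate(zip(ensemble.atoms, frame), start=1):
                x, y, z = xyz * ANGSTROM_PER_NM
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {i:5d} {name:4s} {atom.residue_name:>3s} "
                    f"{atom.chain_id[:1]:1s}{atom.residue_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def discard_equilibration(ensemble: Ensemble, cutoff_ns: float) -> Ensemble:
    """Drop every frame with time <= cutoff_ns (initial relaxation)."""
    if cutoff_ns < 0:
        raise ValueError("cutoff_ns must be >= 0")
    keep = ensemble.times > cutoff_ns
    if not np.any(keep):
        raise EmptyEnsembleError(
            f"cutoff {cutoff_ns} ns removes all {ensemble.n_frames} frames of {ensemble.sim_id!r}"
        )
    return Ensemble(
        atoms=ensemble.atoms,
        frames=ensemble.frames[keep],
        times=ensemble.times[keep],
        sim_id=ensemble.sim_id,
    )


def stride_frames(ensemble: Ensemble, stride: int) -> Ensemble:
    """Keep every ``stride``-th frame (stride >= 1)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride == 1:
        return ensemble
    return Ensemble(
        atoms=ensemble.atoms,
        frames=ensemble.frames[::stride],
        times=ensemble.times[::stride],
        sim_id=ensemble.sim_id,
    )


def _check_fit_atoms(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateFitError("need at least 3 fit atoms")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise DegenerateFitError("fit atoms are collinear")


def kabsch_transform(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with ``mobile @ R.T + t ~= target``."""
    pc = mobile.mean(axis=0)
    qc = target.mean(axis=0)
    h = (mobile - pc).T @ (target - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, qc - rot @ pc


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(
    ensemble: Ensemble,
    fit_selection: Sequence[int],
    reference_coords: np.ndarray | None = None,
) -> Ensemble:
    """Rigid-body fit every frame onto a reference using the fit atoms only.

    The transform minimising the RMSD of ``fit_selection`` to the reference
    is applied to *all* atoms of the frame.  With no explicit reference a
    two-pass procedure is used: frames are first aligned to frame 0, their
    mean fit-atom structure is computed, and the original frames are then
    aligned to that mean.
    """
    fit = np.asarray(fit_selection, dtype=int)
    if fit.size == 0:
        raise AnnotationError("empty fit selection")
    _check_fit_atoms(ensemble.frames[0, fit])

    if reference_coords is None:
        ref0 = ensemble.frames[0, fit]
        aligned = np.empty((ensemble.n_frames, fit.size, 3))
        for i, frame in enumerate(ensemble.frames):
            rot, t = kabsch_transform(frame[fit], ref0)
            aligned[i] = frame[fit] @ rot.T + t
        reference_coords = aligned.mean(axis=0)
    else:
        reference_coords = np.asarray(reference_coords, dtype=float)
        if reference_coords.shape != (fit.size, 3):
            raise AnnotationError(
                f"reference shape {reference_coords.shape} != ({fit.size}, 3)"
            )

    out = np.empty_like(ensemble.frames)
    for i, frame in enumerate(ensemble.frames):
        rot, t = kabsch_transform(frame[fit], reference_coords)
        out[i] = frame @ rot.T + t
    return Ensemble(atoms=ensemble.atoms, frames=out, times=ensemble.times.copy(),
                    sim_id=ensemble.sim_id)


# ---------------------------------------------------------------------------
# Region annotation


CDR_LABELS = ("cdr1a", "cdr2a", "cdr3a", "cdr1b", "cdr2b", "cdr3b")
HELIX_LABELS = ("helix1", "helix2")
ROLES = ("peptide", "mhc", "tcr_alpha", "tcr_beta", "beta2m")


@dataclass
class ComplexAnnotation:
    """Maps chains and residue ranges to their structural roles.

    Ranges are ``(chain_id, first_resid, last_resid)`` inclusive, 1-based,
    in the numbering of the input files.  ``core_alpha``/``core_beta`` list
    the conserved-core residue numbers on the TCR alpha/beta chains whose
    C-alpha atoms define the domain principal axes.
    """

    role_of_chain: Mapping[str, str]
    cdr_ranges: Mapping[str, tuple[str, int, int]]
    helix_ranges: Mapping[str, tuple[str, int, int]]
    kink_residues: Mapping[str, tuple[str, int]]
    core_alpha: Sequence[int]
    core_beta: Sequence[int]
    peptide_length: int

    def validate(self) -> None:
        for chain, role in self.role_of_chain.items():
            if role not in ROLES:
                raise AnnotationError(f"unknown role {role!r} for chain {chain!r}")
        for label in CDR_LABELS:
            if label not in self.cdr_ranges:
                raise AnnotationError(f"missing CDR range {label!r}")
        for label in HELIX_LABELS:
            if label not in self.helix_ranges:
                raise AnnotationError(f"missing helix range {label!r}")
            if label not in self.kink_residues:
                raise AnnotationError(f"missing kink residue for {label!r}")
            hchain, lo, hi = self.helix_ranges[label]
            kchain, kres = self.kink_residues[label]
            if kchain != hchain or not (lo <= kres <= hi):
                raise AnnotationError(f"kink residue of {label!r} outside its helix range")
        if len(self.core_alpha) < 4 or len(self.core_beta) < 4:
            raise AnnotationError("conserved cores need >= 4 residues each")
        if self.peptide_length < 1:
            raise AnnotationError("peptide_length must be >= 1")

    def chain_of_role(self, role: str) -> str:
        for chain, r in self.role_of_chain.items():
            if r == role:
                return chain
        raise AnnotationError(f"no chain annotated with role {role!r}")

    # -- selection helpers --------------------------------------------------

    def role_atoms(self, ensemble: Ensemble, role: str) -> np.ndarray:
        chains = [c for c, r in self.role_of_chain.items() if r == role]
        if not chains:
            raise AnnotationError(f"no chain annotated with role {role!r}")
        mask = np.isin(ensemble.atom_chains, chains)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise AnnotationError(f"role {role!r} selects no atoms")
        return idx

    def range_atoms(self, ensemble: Ensemble, rng: tuple[str, int, int]) -> np.ndarray:
        chain, lo, hi = rng
        idx = ensemble.select(chain=chain, resid_range=(lo, hi))
        if idx.size == 0:
            raise AnnotationError(f"range {rng} selects no atoms")
        return idx

    def region_atoms(self, ensemble: Ensemble, label: str) -> np.ndarray:
        """Atom indices for a named region label.

        Labels: roles (peptide, mhc, tcr_alpha, tcr_beta), "tcr" (both TCR
        chains), CDR labels, helix labels, and "cdr3s" (both CDR3 loops).
        """
        if label in ROLES:
            return self.role_atoms(ensemble, label)
        if label == "tcr":
            return np.sort(np.concatenate([
                self.role_atoms(ensemble, "tcr_alpha"),
                self.role_atoms(ensemble, "tcr_beta"),
            ]))
        if label in self.cdr_ranges:
            return self.range_atoms(ensemble, self.cdr_ranges[label])
        if label in self.helix_ranges:
            return self.range_atoms(ensemble, self.helix_ranges[label])
        if label == "cdr3s":
            return np.sort(np.concatenate([
                self.range_atoms(ensemble, self.cdr_ranges["cdr3a"]),
                self.range_atoms(ensemble, self.cdr_ranges["cdr3b"]),
            ]))
        raise AnnotationError(f"unknown region label {label!r}")

    def calpha_index(self, ensemble: Ensemble, chain: str, resid: int) -> int:
        idx = ensemble.select(chain=chain, resid_range=(resid, resid), names=["CA"])
        if idx.size != 1:
            raise AnnotationError(f"expected one CA for {chain}:{resid}, found {idx.size}")
        return int(idx[0])

    def core_calpha_indices(self, ensemble: Ensemble, domain: str) -> np.ndarray:
        if domain == "alpha":
            chain, resids = self.chain_of_role("tcr_alpha"), self.core_alpha
        elif domain == "beta":
            chain, resids = self.chain_of_role("tcr_beta"), self.core_beta
        else:
            raise AnnotationError(f"unknown domain {domain!r}")
        return np.array([self.calpha_index(ensemble, chain, r) for r in resids], dtype=int)

    def backbone_atoms(self, ensemble: Ensemble, label: str) -> np.ndarray:
        idx = self.region_atoms(ensemble, label)
        names = ensemble.atom_names[idx]
        return idx[np.isin(names, list(_BACKBONE_NAMES))]


def _as_range(value) -> tuple[str, int, int]:
    chain, lo, hi = value
    return str(chain), int(lo), int(hi)


def load_annotation(path: str) -> ComplexAnnotation:
    """Read a ComplexAnnotation from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return annotation_from_dict(raw)


def annotation_from_dict(raw: Mapping) -> ComplexAnnotation:
    try:
        ann = ComplexAnnotation(
            role_of_chain={str(k): str(v) for k, v in raw["role_of_chain"].items()},
            cdr_ranges={str(k): _as_range(v) for k, v in raw["cdr_ranges"].items()},
            helix_ranges={str(k): _as_range(v) for k, v in raw["helix_ranges"].items()},
            kink_residues={str(k): (str(v[0]), int(v[1]))
                           for k, v in raw["kink_residues"].items()},
            core_alpha=[int(r) for r in raw["core_alpha"]],
            core_beta=[int(r) for r in raw["core_beta"]],
            peptide_length=int(raw["peptide_length"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise AnnotationError(f"malformed annotation: {exc}") from exc
    ann.validate()
    return ann


def annotation_to_dict(ann: ComplexAnnotation) -> dict:
    return {
        "role_of_chain": dict(ann.role_of_chain),
        "cdr_ranges": {k: list(v) for k, v in ann.cdr_ranges.items()},
        "helix_ranges": {k: list(v) for k, v in ann.helix_ranges.items()},
        "kink_residues": {k: list(v) for k, v in ann.kink_residues.items()},
        "core_alpha": list(ann.core_alpha),
        "core_beta": list(ann.core_beta),
        "peptide_length": ann.peptide_length,
    }


def write_annotation(ann: ComplexAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(annotation_to_dict(ann), fh, sort_keys=True)
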