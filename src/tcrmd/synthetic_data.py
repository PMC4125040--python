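"""Synthetic inputs: APL enumeration, toy complexes, seeded ensembles.

The toy complex is deliberately *not* a physical protein model.  It is the
minimal five-region geometry (peptide strand between two helical rods, two
variable-domain cores above) carrying backbone atoms (N, H, CA, C, O) so
that every descriptor operation — H-bond detection, SASA, RMSF, interface
distances and domain orientation — runs on it, with controllable planted
group effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import InputError
from .trajectory_io import Atom, ComplexAnnotation, Ensemble

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_BACKBONE_OFFSETS = {
    # local offsets (nm) of a residue's atoms from its base point
    "N": (0.0, 0.0, 0.0),
    "H": (0.0, -0.100, 0.0),
    "CA": (0.146, 0.050, 0.030),
    "C": (0.250, -0.040, 0.010),
    "O": (0.251, -0.160, 0.040),
}
_ELEMENT_OF = {"N": "N", "H": "H", "CA": "C", "C": "C", "O": "O"}

#: planted H-bond geometry: donor N sits this far from the acceptor O,
#: with its hydrogen on the N->O axis (well inside the 0.35 nm / 30 deg cut)
_BOND_NO_DIST = 0.29
_BOND_NH_DIST = 0.10


def enumerate_apls(wildtype_sequence: str) -> list[str]:
    """Wild-type plus every single-position substitution, position-major.

    A 9-mer yields 1 + 9*19 = 172 unique sequences.
    """
    wt = wildtype_sequence.upper()
    if not wt:
        raise InputError("empty sequence")
    bad = set(wt) - set(AMINO_ACIDS)
    if bad:
        raise InputError(f"non-standard amino acid letters: {sorted(bad)}")
    out = [wt]
    for pos in range(len(wt)):
        for aa in AMINO_ACIDS:
            if aa != wt[pos]:
                out.append(wt[:pos] + aa + wt[pos + 1:])
    return out


@dataclass
class ToyComplexSpec:
    """Parameters of the synthetic five-region complex and its ensembles."""

    peptide_length: int = 9
    helix_length: int = 11
    residue_spacing_nm: float = 0.35
    helix_offset_nm: float = 0.8            # helix rods at y = +/- this
    domain_separation_nm: float = 1.6       # Valpha/Vbeta anchor distance
    domain_height_nm: float = 1.8           # z of the domain cores
    core_half_lengths_nm: tuple = (0.10, 0.40, 0.20)  # (x, y, z): axis1=y, axis2=z
    beta_twist_deg: float = -35.0           # built-in Vbeta twist about the C axis
    sigma_nm: float | Mapping[str, float] = 0.02  # per-coordinate jitter by role
    n_frames: int = 50
    dc_sim_sigma_nm: float = 0.0            # per-simulation DC baseline spread
    ba_sim_sigma_deg: float = 0.0           # per-simulation BA baseline spread
    t0_ns: float = 10.0
    t_end_ns: float = 100.0

    def validate(self) -> None:
        if self.peptide_length < 1 or self.helix_length < 3:
            raise InputError("degenerate region lengths")
        if self.n_frames < 2:
            raise InputError("n_frames must be >= 2")
        sigmas = (self.sigma_nm.values() if isinstance(self.sigma_nm, Mapping)
                  else [self.sigma_nm])
        if any(s < 0 for s in sigmas):
            raise InputError("negative fluctuation sigma")
        if self.dc_sim_sigma_nm < 0 or self.ba_sim_sigma_deg < 0:
            raise InputError("negative simulation-level sigma")

    def sigma_for(self, role: str) -> float:
        if isinstance(self.sigma_nm, Mapping):
            return float(self.sigma_nm.get(role, 0.0))
        return float(self.sigma_nm)


@dataclass
class ToyComplex:
    """Reference structure, annotation and planted-effect bookkeeping."""

    atoms: list[Atom]
    coords: np.ndarray
    annotation: ComplexAnnotation
    spec: ToyComplexSpec
    beta_atom_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    c_unit: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    beta_anchor: np.ndarray = field(default_factory=lambda: np.zeros(3))
    donor_n_index: int = -1
    donor_h_index: int = -1
    acceptor_o_index: int = -1
    bonded_n_coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bonded_h_coords: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def _add_residue(atoms, coords, chain, resid, base, resname="GLY"):
    for name, off in _BACKBONE_OFFSETS.items():
        atoms.append(Atom(name=name, element=_ELEMENT_OF[name],
                          residue_index=resid, residue_name=resname, chain_id=chain))
        coords.append(np.asarray(base, dtype=float) + off)


def build_toy_complex(spec: ToyComplexSpec | None = None) -> ToyComplex:
    """Construct the reference toy structure and its full annotation."""
    spec = spec or ToyComplexSpec()
    spec.validate()
    sp = spec.residue_spacing_nm
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []

    # peptide (chain P) along x at the origin
    for i in range(spec.peptide_length):
        _add_residue(atoms, coords, "P", i + 1, (i * sp, 0.0, 0.0))
    x_center = (spec.peptide_length - 1) * sp / 2.0

    # MHC (chain M): helix1 at +y, helix2 at -y, centred over the peptide
    hl = spec.helix_length
    x0 = x_center - (hl - 1) * sp / 2.0
    for i in range(hl):
        _add_residue(atoms, coords, "M", i + 1, (x0 + i * sp, spec.helix_offset_nm, 0.0))
    for i in range(hl):
        _add_residue(atoms, coords, "M", hl + i + 1, (x0 + i * sp, -spec.helix_offset_nm, 0.0))

    # TCR variable domains (chains A, B): 8 core residues at cuboid corners
    # (distinct principal axes: 1st along y, 2nd along z), then 6 CDR
    # stand-in residues below the core
    hx, hy, hz = spec.core_half_lengths_nm
    corners = np.array([(sx * hx, sy * hy, sz * hz)
                        for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    ca_off = np.array(_BACKBONE_OFFSETS["CA"])
    centers = {
        "A": np.array([x_center - spec.domain_separation_nm / 2.0, 0.0,
                       spec.domain_height_nm]) - ca_off,
        "B": np.array([x_center + spec.domain_separation_nm / 2.0, 0.0,
                       spec.domain_height_nm]) - ca_off,
    }
    for chain in ("A", "B"):
        for i, corner in enumerate(corners):
            _add_residue(atoms, coords, chain, i + 1, centers[chain] + corner)
        for j in range(6):  # residues 9..14: cdr1 (9,10), cdr2 (11,12), cdr3 (13,14)
            base = centers[chain] + np.array([(j - 2.5) * 0.3, 0.35, -0.9])
            _add_residue(atoms, coords, chain, 9 + j, base)

    coords = np.array(coords)
    atom_chain = np.array([a.chain_id for a in atoms], dtype=object)
    atom_resid = np.array([a.residue_index for a in atoms])
    atom_name = np.array([a.name for a in atoms], dtype=object)

    # built-in Vbeta twist about the inter-anchor (x) axis
    beta_idx = np.nonzero(atom_chain == "B")[0]
    beta_core_ca = np.nonzero((atom_chain == "B") & (atom_resid <= 8) & (atom_name == "CA"))[0]
    anchor_b = coords[beta_core_ca].mean(axis=0)
    rot = Rotation.from_rotvec(np.radians(spec.beta_twist_deg) * np.array([1.0, 0.0, 0.0]))
    coords[beta_idx] = (coords[beta_idx] - anchor_b) @ rot.as_matrix().T + anchor_b
    anchor_b = coords[beta_core_ca].mean(axis=0)

    kink1 = (spec.helix_length + 1) // 2
    kink2 = spec.helix_length + kink1
    annotation = ComplexAnnotation(
        role_of_chain={"P": "peptide", "M": "mhc", "A": "tcr_alpha", "B": "tcr_beta"},
        cdr_ranges={
            "cdr1a": ("A", 9, 10), "cdr2a": ("A", 11, 12), "cdr3a": ("A", 13, 14),
            "cdr1b": ("B", 9, 10), "cdr2b": ("B", 11, 12), "cdr3b": ("B", 13, 14),
        },
        helix_ranges={"helix1": ("M", 1, hl), "helix2": ("M", hl + 1, 2 * hl)},
        kink_residues={"helix1": ("M", kink1), "helix2": ("M", kink2)},
        core_alpha=list(range(1, 9)),
        core_beta=list(range(1, 9)),
        peptide_length=spec.peptide_length,
    )
    annotation.validate()

    # planted H-bond: peptide middle residue N-H donor -> helix1 kink O acceptor
    pep_mid = (spec.peptide_length + 1) // 2
    donor_n = int(np.nonzero((atom_chain == "P") & (atom_resid == pep_mid)
                             & (atom_name == "N"))[0][0])
    donor_h = int(np.nonzero((atom_chain == "P") & (atom_resid == pep_mid)
                             & (atom_name == "H"))[0][0])
    acceptor_o = int(np.nonzero((atom_chain == "M") & (atom_resid == kink1)
                                & (atom_name == "O"))[0][0])
    o_pos = coords[acceptor_o]
    bonded_n = o_pos + np.array([0.0, -_BOND_NO_DIST, 0.0])
    bonded_h = o_pos + np.array([0.0, -(_BOND_NO_DIST - _BOND_NH_DIST), 0.0])

    return ToyComplex(
        atoms=atoms,
        coords=coords,
        annotation=annotation,
        spec=spec,
        beta_atom_indices=beta_idx,
        c_unit=np.array([1.0, 0.0, 0.0]),
        beta_anchor=anchor_b,
        donor_n_index=donor_n,
        donor_h_index=donor_h,
        acceptor_o_index=acceptor_o,
        bonded_n_coords=bonded_n,
        bonded_h_coords=bonded_h,
    )


def generate_ensemble(
    toy: ToyComplex,
    seed: int,
    sim_id: str = "sim",
    dc_offset_nm: float = 0.0,
    ba_offset_deg: float = 0.0,
    hbond_occupancy: float | None = None,
    n_frames: int | None = None,
) -> Ensemble:
    """Seeded multi-frame ensemble with planted group effects.

    * ``dc_offset_nm`` translates the whole beta chain along the
      inter-anchor axis (shifts DC by exactly that amount on noiseless
      frames).
    * ``ba_offset_deg`` rotates the beta chain about the inter-anchor axis
      through its anchor (shifts BA by exactly that angle).
    * ``hbond_occupancy`` plants the peptide-MHC hydrogen bond in that
      fraction of frames (donor atoms pinned to exact bonded/unbonded
      geometry).
    * Per-simulation baseline offsets (``dc_sim_sigma_nm``,
      ``ba_sim_sigma_deg`` of the spec) are drawn once per ensemble.
    """
    spec = toy.spec
    if seed is None:
        raise InputError("seed is required")
    if hbond_occupancy is not None and not (0.0 <= hbond_occupancy <= 1.0):
        raise InputError("hbond_occupancy must be in [0, 1]")
    rng = np.random.default_rng(seed)
    T = n_frames if n_frames is not None else spec.n_frames
    if T < 2:
        raise InputError("n_frames must be >= 2")

    dc_total = dc_offset_nm + (rng.normal(0.0, spec.dc_sim_sigma_nm)
                               if spec.dc_sim_sigma_nm > 0 else 0.0)
    ba_total = ba_offset_deg + (rng.normal(0.0, spec.ba_sim_sigma_deg)
                                if spec.ba_sim_sigma_deg > 0 else 0.0)

    base = toy.coords.copy()
    bidx = toy.beta_atom_indices
    if ba_total:
        rot = Rotation.from_rotvec(np.radians(ba_total) * toy.c_unit).as_matrix()
        base[bidx] = (base[bidx] - toy.beta_anchor) @ rot.T + toy.beta_anchor
    if dc_total:
        base[bidx] = base[bidx] + dc_total * toy.c_unit

    role_of_chain = dict(toy.annotation.role_of_chain)
    sigma_per_atom = np.array(
        [spec.sigma_for(role_of_chain.get(a.chain_id, "")) for a in toy.atoms]
    )[:, None]

    frames = np.empty((T, toy.n_atoms, 3))
    bond_state = (rng.random(T) < hbond_occupancy) if hbond_occupancy is not None else None
    for t in range(T):
        frame = base + rng.normal(0.0, 1.0, size=base.shape) * sigma_per_atom
        if bond_state is not None:
            if bond_state[t]:
                frame[toy.donor_n_index] = toy.bonded_n_coords
                frame[toy.donor_h_index] = toy.bonded_h_coords
            else:
                frame[toy.donor_n_index] = toy.coords[toy.donor_n_index]
                frame[toy.donor_h_index] = toy.coords[toy.donor_h_index]
        frames[t] = frame

    dt = (spec.t_end_ns - spec.t0_ns) / T
    times = spec.t0_ns + dt * (np.arange(T) + 1)
    return Ensemble(atoms=toy.atoms, frames=frames, times=times, sim_id=sim_id)


def generate_immunogenicity_table(
    n_peptides: int,
    fractions: tuple[float, float, float] = (0.3, 0.3, 0.4),
    seed: int = 0,
    wildtype: str = "FLRGRAYGL",
) -> pd.DataFrame:
    """Synthetic peptide table: (never, strong, intermediate) fractions.

    'strong' entries get -log10 lysis-50 concentrations >= 6.94 (groupM
    territory), 'intermediate' entries fall between the criteria, 'never'
    entries never induce 50% lysis.  Deterministic given the seed.
    """
    f_never, f_strong, f_mid = fractions
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise InputError("fractions must be nonnegative and sum to 1")
    peptides = enumerate_apls(wildtype)
    if n_peptides > len(peptides):
        raise InputError(
            f"at most {len(peptides)} peptides available from wild-type {wildtype!r}"
        )
    peptides = peptides[:n_peptides]

    n_never = int(round(f_never * n_peptides))
    n_strong = int(round(f_strong * n_peptides))
    n_never = min(n_never, n_peptides)
    n_strong = min(n_strong, n_peptides - n_never)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_peptides)
    values: list = [None] * n_peptides
    for i in order[:n_never]:
        values[i] = "never"
    for i in order[n_never:n_never + n_strong]:
        values[i] = round(float(rng.uniform(6.94, 9.0)), 3)
    for i in order[n_never + n_strong:]:
        values[i] = round(float(rng.uniform(4.0, 6.5)), 3)
    return pd.DataFrame(
        {"peptide_sequence": peptides, "lysis50_neg_log10_molar": values}
    )


def generate_group_ensembles(
    toy: ToyComplex,
    n_per_group: int,
    seed: int,
    effects_M: Mapping[str, float] | None = None,
    effects_L: Mapping[str, float] | None = None,
    n_frames: int | None = None,
) -> tuple[list[Ensemble], list[Ensemble]]:
    """Two seeded groups of ensembles with optional planted effect maps.

    Effect maps accept the keyword arguments of :func:`generate_ensemble`
    (``dc_offset_nm``, ``ba_offset_deg``, ``hbond_occupancy``).
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * n_per_group)
    group_m = [
        generate_ensemble(toy, seed=int(seeds[i]), sim_id=f"M{i:03d}",
                          n_frames=n_frames, **(effects_M or {}))
        for i in range(n_per_group)
    ]
    group_l = [
        generate_ensemble(toy, seed=int(seeds[n_per_group + i]), sim_id=f"L{i:03d}",
                          n_frames=n_frames, **(effects_L or {}))
        for i in range(n_per_group)
    ]
    return group_m, group_l
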