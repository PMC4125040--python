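"""The 16 named TCR/peptide/MHC interface distances.

Single-residue endpoints (helix kinks, peptide first/middle/last residue)
use the residue's C-alpha; multi-residue endpoints (CDR loops, "peptide
mean", "mean of both CDR3s") use the unweighted centroid of the region's
non-hydrogen atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnnotationError
from .trajectory_io import Ensemble, ComplexAnnotation


@dataclass(frozen=True)
class Endpoint:
    """One end of an interface distance.

    kind "calpha": ``target`` is (chain, resid).
    kind "centroid": ``target`` is a region label resolved by the annotation.
    """

    kind: str
    target: tuple

    def resolve(self, ensemble: Ensemble, annotation: ComplexAnnotation):
        if self.kind == "calpha":
            chain, resid = self.target
            return ("calpha", np.array([annotation.calpha_index(ensemble, chain, resid)]))
        if self.kind == "centroid":
            (label,) = self.target
            return ("centroid", annotation.region_atoms(ensemble, label))
        raise AnnotationError(f"unknown endpoint kind {self.kind!r}")


@dataclass(frozen=True)
class DistanceSpec:
    label: str
    endpoint_A: Endpoint
    endpoint_B: Endpoint


def region_point(
    coords: np.ndarray,
    atom_indices: Sequence[int],
    mode: str,
    atom_names: np.ndarray | None = None,
    atom_elements: np.ndarray | None = None,
) -> np.ndarray:
    """Reference point of a region: its C-alpha or its heavy-atom centroid."""
    idx = np.asarray(atom_indices, dtype=int)
    if idx.size == 0:
        raise AnnotationError("empty region")
    if mode == "calpha":
        if atom_names is not None:
            idx = idx[np.asarray(atom_names, dtype=object)[idx] == "CA"]
        if idx.size != 1:
            raise AnnotationError(f"expected exactly one C-alpha, found {idx.size}")
        return np.asarray(coords, dtype=float)[idx[0]]
    if mode == "centroid":
        if atom_elements is not None:
            heavy = idx[np.asarray(atom_elements, dtype=object)[idx] != "H"]
            idx = heavy if heavy.size else idx
        return np.asarray(coords, dtype=float)[idx].mean(axis=0)
    raise AnnotationError(f"unknown region point mode {mode!r}")


def default_distance_specs(annotation: ComplexAnnotation) -> list[DistanceSpec]:
    """The 16 default interface distance definitions, order-stable.

    A-C: helix-1 kink C-alpha to the three beta-chain CDR centroids.
    D-F: helix-2 kink C-alpha to the three alpha-chain CDR centroids.
    G-I: groove begin/middle/end (helix1-helix2 C-alpha pairs at the first,
         kink and last annotated helix residues).
    J-K: peptide middle residue to the two CDR3 centroids.
    L-M: peptide first residue to the two CDR3 centroids.
    N-O: peptide last residue to the two CDR3 centroids.
    P:   peptide heavy-atom centroid to the joint centroid of both CDR3s.
    """
    pchain = annotation.chain_of_role("peptide")
    plen = annotation.peptide_length
    pfirst, pmid, plast = 1, (plen + 1) // 2, plen
    k1 = annotation.kink_residues["helix1"]
    k2 = annotation.kink_residues["helix2"]
    h1 = annotation.helix_ranges["helix1"]
    h2 = annotation.helix_ranges["helix2"]

    ca = lambda chain, resid: Endpoint("calpha", (chain, resid))
    cen = lambda label: Endpoint("centroid", (label,))

    return [
        DistanceSpec("helix1_kink-cdr1b", ca(*k1), cen("cdr1b")),
        DistanceSpec("helix1_kink-cdr2b", ca(*k1), cen("cdr2b")),
        DistanceSpec("helix1_kink-cdr3b", ca(*k1), cen("cdr3b")),
        DistanceSpec("helix2_kink-cdr1a", ca(*k2), cen("cdr1a")),
        DistanceSpec("helix2_kink-cdr2a", ca(*k2), cen("cdr2a")),
        DistanceSpec("helix2_kink-cdr3a", ca(*k2), cen("cdr3a")),
        DistanceSpec("groove_begin", ca(h1[0], h1[1]), ca(h2[0], h2[1])),
        DistanceSpec("groove_middle", ca(*k1), ca(*k2)),
        DistanceSpec("groove_end", ca(h1[0], h1[2]), ca(h2[0], h2[2])),
        DistanceSpec("pep_middle-cdr3a", ca(pchain, pmid), cen("cdr3a")),
        DistanceSpec("pep_middle-cdr3b", ca(pchain, pmid), cen("cdr3b")),
        DistanceSpec("pep_first-cdr3a", ca(pchain, pfirst), cen("cdr3a")),
        DistanceSpec("pep_first-cdr3b", ca(pchain, pfirst), cen("cdr3b")),
        DistanceSpec("pep_last-cdr3a", ca(pchain, plast), cen("cdr3a")),
        DistanceSpec("pep_last-cdr3b", ca(pchain, plast), cen("cdr3b")),
        DistanceSpec("pep_mean-cdr3s_mean", cen("peptide"), cen("cdr3s")),
    ]


def _endpoint_point(coords, ensemble, annotation, endpoint: Endpoint) -> np.ndarray:
    mode, idx = endpoint.resolve(ensemble, annotation)
    return region_point(coords, idx, mode,
                        atom_names=ensemble.atom_names,
                        atom_elements=ensemble.atom_elements)


def interface_distances(
    coords: np.ndarray,
    ensemble: Ensemble,
    annotation: ComplexAnnotation,
    specs: Sequence[DistanceSpec] | None = None,
) -> dict[str, float]:
    """Labelled Euclidean distances (nm) for one frame, order-stable."""
    if specs is None:
        specs = default_distance_specs(annotation)
    out: dict[str, float] = {}
    for spec in specs:
        pa = _endpoint_point(coords, ensemble, annotation, spec.endpoint_A)
        pb = _endpoint_point(coords, ensemble, annotation, spec.endpoint_B)
        out[spec.label] = float(np.linalg.norm(pa - pb))
    return out


def distance_series(
    ensembles: Sequence[Ensemble],
    annotation: ComplexAnnotation,
    specs: Sequence[DistanceSpec] | None = None,
) -> dict[str, "SampleDistribution"]:
    """Per-frame evaluation over all ensembles; one distribution per label."""
    from .group_statistics import SampleDistribution

    if specs is None:
        specs = default_distance_specs(annotation)
    values: dict[str, list[float]] = {s.label: [] for s in specs}
    sim_ids: list[str] = []
    for ens in ensembles:
        # resolve endpoints once per ensemble, evaluate per frame
        resolved = [
            (s.label,
             s.endpoint_A.resolve(ens, annotation),
             s.endpoint_B.resolve(ens, annotation))
            for s in specs
        ]
        for frame in ens.frames:
            for label, (ma, ia), (mb, ib) in resolved:
                pa = region_point(frame, ia, ma, ens.atom_names, ens.atom_elements)
                pb = region_point(frame, ib, mb, ens.atom_names, ens.atom_elements)
                values[label].append(float(np.linalg.norm(pa - pb)))
        sim_ids.extend([ens.sim_id] * ens.n_frames)
    ids = np.array(sim_ids, dtype=object)
    return {
        label: SampleDistribution(np.array(vals), ids.copy())
        for label, vals in values.items()
    }
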