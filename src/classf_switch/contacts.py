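"""Residue-residue contact detection, typing, and ensemble fingerprints.

The molecular-switch analysis asks which contacts residue 6.32 makes with
the lower ends of TM7 and TM2 across an ensemble of inactive-state receptor
structures.  A residue pair is in contact when any two heavy (non-hydrogen)
atoms lie within a cutoff (default 4.5 A); contacts between residues 4 or
fewer positions apart in the same chain are disregarded, and when a segment
map is available contacts within one helix are dropped so only interhelical
pairs remain.  Detected contacts can be typed as hydrogen bonds
(donor/acceptor N/O heavy atoms within 3.5 A; crystal structures carry no
hydrogens, so the criterion is distance-only) and pi-cation interactions
(Arg guanidinium centroid or Lys NZ within 6.0 A of an aromatic ring
centroid).

A fingerprint is the presence/absence matrix of generic-label contact pairs
(rows) across structures (columns).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .generic_numbering import GenericLabel, SegmentMap

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ResidueRef",
    "ContactPair",
    "detect_contacts",
    "classify_contact",
    "fingerprint",
    "superpose",
]

HEAVY_CUTOFF = 4.5  # A, any heavy-atom pair
MIN_SEPARATION = 4  # same-chain pairs <= this far apart in sequence are dropped
HBOND_CUTOFF = 3.5  # A, donor-acceptor N/O heavy atoms
PI_CATION_CUTOFF = 6.0  # A, cation center to aromatic ring centroid

# aromatic ring atoms; TRP uses the six-membered ring by default
_RING_ATOMS = {
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_TRP_FIVE_RING = ("CG", "CD1", "NE1", "CE2", "CD2")
_CATION_ATOMS = {"ARG": ("CZ", "NH1", "NH2"), "LYS": ("NZ",)}


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    res_index: int
    res_name: str
    atom_name: str
    element: str
    coords: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class StructureModel:
    """One structure: a flat atom list plus an optional segment map."""

    structure_id: str
    atoms: list[AtomRecord]
    segment_map: SegmentMap | None = None

    def __post_init__(self) -> None:
        keys = [(a.chain, a.res_index, a.atom_name) for a in self.atoms]
        if len(keys) != len(set(keys)):
            raise ValueError(
                f"duplicate (chain, res_index, atom_name) in {self.structure_id}"
            )

    def residues(self) -> dict[tuple[str, int], list[AtomRecord]]:
        """Atoms grouped by (chain, res_index), in input order."""
        out: dict[tuple[str, int], list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault((a.chain, a.res_index), []).append(a)
        return out

    def label_of(self, res_index: int) -> GenericLabel | None:
        if self.segment_map is None or not self.segment_map.is_mapped(res_index):
            return None
        return self.segment_map.assign_label(res_index)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with coordinates x -> R x + t (rigid transform)."""
        atoms = [
            replace(a, coords=tuple(rotation @ np.asarray(a.coords) + translation))
            for a in self.atoms
        ]
        return StructureModel(self.structure_id, atoms, self.segment_map)


@dataclass(frozen=True, order=True)
class ResidueRef:
    chain: str
    res_index: int
    label: GenericLabel | None = field(compare=False, default=None)


@dataclass(frozen=True)
class ContactPair:
    """An unordered residue pair in contact; res_a < res_b by (chain, index)."""

    res_a: ResidueRef
    res_b: ResidueRef
    contact_types: frozenset[str]
    min_distance: float

    def __post_init__(self) -> None:
        if (self.res_a.chain, self.res_a.res_index) >= (
            self.res_b.chain,
            self.res_b.res_index,
        ):
            raise ValueError("ContactPair must be canonicalized with res_a < res_b")

    @property
    def label_pair(self) -> tuple[str, str] | None:
        if self.res_a.label is None or self.res_b.label is None:
            return None
        return (str(self.res_a.label), str(self.res_b.label))


def _heavy_coords(model: StructureModel):
    heavy = [a for a in model.atoms if a.is_heavy]
    if not heavy:
        raise ValueError(f"structure {model.structure_id} has no heavy atoms")
    coords = np.array([a.coords for a in heavy], dtype=float)
    return heavy, coords


def _same_helix(model: StructureModel, ra: ResidueRef, rb: ResidueRef) -> bool:
    return (
        ra.label is not None
        and rb.label is not None
        and ra.label.helix == rb.label.helix
    )


def detect_contacts(
    model: StructureModel,
    heavy_cutoff: float = HEAVY_CUTOFF,
    min_separation: int = MIN_SEPARATION,
    interhelical_only: bool | None = None,
) -> list[ContactPair]:
    """All residue pairs with any heavy-atom pair within ``heavy_cutoff``.

    Same-chain pairs with sequence separation <= ``min_separation`` are
    disregarded.  When the model carries a segment map, pairs within one
    helix are also dropped unless ``interhelical_only=False`` is passed
    (without a map the separation filter alone applies).

    Pairs are canonicalized (res_a < res_b) and carry the minimum heavy-atom
    distance; the neighbor search uses a k-d tree, which the tests check
    against an independent all-pairs scan.
    """
    if heavy_cutoff <= 0:
        raise ValueError(f"heavy_cutoff must be > 0, got {heavy_cutoff}")
    heavy, coords = _heavy_coords(model)
    if interhelical_only is None:
        interhelical_only = model.segment_map is not None

    tree = cKDTree(coords)
    best: dict[tuple[tuple[str, int], tuple[str, int]], float] = {}
    for i, j in tree.query_pairs(heavy_cutoff):
        key_i = (heavy[i].chain, heavy[i].res_index)
        key_j = (heavy[j].chain, heavy[j].res_index)
        if key_i == key_j:
            continue
        a, b = sorted((key_i, key_j))
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d <= heavy_cutoff and d < best.get((a, b), np.inf):
            best[(a, b)] = d

    out: list[ContactPair] = []
    for (ka, kb), d in sorted(best.items()):
        if ka[0] == kb[0] and abs(ka[1] - kb[1]) <= min_separation:
            continue
        ra = ResidueRef(ka[0], ka[1], model.label_of(ka[1]))
        rb = ResidueRef(kb[0], kb[1], model.label_of(kb[1]))
        if interhelical_only and _same_helix(model, ra, rb):
            continue
        out.append(ContactPair(ra, rb, frozenset({"heavy_atom"}), d))
    return out


def _atom_map(atoms: list[AtomRecord]) -> dict[str, np.ndarray]:
    return {a.atom_name: np.asarray(a.coords, dtype=float) for a in atoms if a.is_heavy}


def _ring_centroids(res_name: str, atom_map, include_trp_five: bool) -> list[np.ndarray]:
    rings = []
    names = _RING_ATOMS.get(res_name)
    if names and all(n in atom_map for n in names):
        rings.append(np.mean([atom_map[n] for n in names], axis=0))
    if res_name == "TRP" and include_trp_five:
        if all(n in atom_map for n in _TRP_FIVE_RING):
            rings.append(np.mean([atom_map[n] for n in _TRP_FIVE_RING], axis=0))
    return rings


def _cation_centers(res_name: str, atom_map) -> list[np.ndarray]:
    names = _CATION_ATOMS.get(res_name)
    if not names:
        return []
    if all(n in atom_map for n in names):
        return [np.mean([atom_map[n] for n in names], axis=0)]
    return []


def classify_contact(
    model: StructureModel,
    pair: ContactPair,
    hbond_cutoff: float = HBOND_CUTOFF,
    pi_cation_cutoff: float = PI_CATION_CUTOFF,
    trp_five_ring: bool = False,
) -> frozenset[str]:
    """Contact types for a detected pair: heavy_atom plus optional
    hydrogen_bond and/or pi_cation.

    hydrogen_bond: any N/O heavy atom of one residue within
    ``hbond_cutoff`` of any N/O heavy atom of the other (distance-only; no
    angle term since hydrogens are absent from crystal structures).

    pi_cation: a cation center (Arg guanidinium centroid of CZ/NH1/NH2, Lys
    NZ) within ``pi_cation_cutoff`` of an aromatic ring centroid
    (Trp six-ring by default, Tyr/Phe/His), in either direction.

    Residues lacking the atoms a criterion needs simply evaluate absent.
    """
    residues = model.residues()
    atoms_a = residues[(pair.res_a.chain, pair.res_a.res_index)]
    atoms_b = residues[(pair.res_b.chain, pair.res_b.res_index)]
    types = set(pair.contact_types)

    no_a = [np.asarray(a.coords) for a in atoms_a if a.is_heavy and a.element.upper() in "NO"]
    no_b = [np.asarray(a.coords) for a in atoms_b if a.is_heavy and a.element.upper() in "NO"]
    if no_a and no_b:
        d = np.linalg.norm(
            np.asarray(no_a)[:, None, :] - np.asarray(no_b)[None, :, :], axis=-1
        )
        if d.min() <= hbond_cutoff:
            types.add("hydrogen_bond")

    map_a, map_b = _atom_map(atoms_a), _atom_map(atoms_b)
    name_a, name_b = atoms_a[0].res_name, atoms_b[0].res_name
    for (cat_name, cat_map), (ring_name, ring_map) in (
        ((name_a, map_a), (name_b, map_b)),
        ((name_b, map_b), (name_a, map_a)),
    ):
        for cation in _cation_centers(cat_name, cat_map):
            for centroid in _ring_centroids(ring_name, ring_map, trp_five_ring):
                if np.linalg.norm(cation - centroid) <= pi_cation_cutoff:
                    types.add("pi_cation")
    return frozenset(types)


def fingerprint(
    models: list[StructureModel],
    focus: GenericLabel | str | None = None,
    partner_filter: set[int] | None = None,
    **detect_kwargs,
) -> pd.DataFrame:
    """Presence/absence matrix of generic-label contact pairs across models.

    Rows are label pairs ("a-b"), columns structure ids, cells 0/1.  With a
    ``focus`` label (e.g. 6.32) only pairs involving it are kept, optionally
    restricted to partner helices (e.g. {7, 2} for TM7/TM2).  Pairs whose
    residues lack labels are ignored: the fingerprint compares structures in
    generic coordinates.
    """
    if not models:
        raise ValueError("need at least one model")
    if isinstance(focus, str) and focus not in (None, "all"):
        focus = GenericLabel.parse(focus)
    if focus == "all":
        focus = None
    if focus is not None:
        if all(
            m.segment_map is None
            or not any(str(l) == str(focus) for l in m.segment_map.labels())
            for m in models
        ):
            raise ValueError(f"focus label {focus} is unmapped in every model")

    per_model: dict[str, set[tuple[str, str]]] = {}
    for m in models:
        pairs = set()
        for cp in detect_contacts(m, **detect_kwargs):
            lp = cp.label_pair
            if lp is None:
                continue
            la, lb = sorted(lp)
            if focus is not None:
                f = str(focus)
                if f not in (la, lb):
                    continue
                partner = GenericLabel.parse(lb if la == f else la)
                if partner_filter is not None and partner.helix not in partner_filter:
                    continue
            pairs.add((la, lb))
        per_model[m.structure_id] = pairs

    rows = sorted(set().union(*per_model.values()))
    data = {
        sid: [int(r in pairs) for r in rows] for sid, pairs in per_model.items()
    }
    fp = pd.DataFrame(data, index=pd.Index([f"{a}-{b}" for a, b in rows], name="pair"))
    return fp[[m.structure_id for m in models]]


def superpose(
    reference: StructureModel,
    mobile: StructureModel,
    selection=None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares (Kabsch) rigid superposition of mobile onto reference.

    Atoms are paired by (chain, res_index, atom_name) shared between the two
    models after applying ``selection`` (a predicate on AtomRecord; default
    keeps Calpha atoms).  Returns (rotation, translation, rmsd) with the
    transform x -> R x + t minimizing RMSD over the paired atoms.
    """
    if selection is None:
        selection = lambda a: a.atom_name == "CA"

    ref_map = {
        (a.chain, a.res_index, a.atom_name): np.asarray(a.coords)
        for a in reference.atoms
        if selection(a)
    }
    mob_map = {
        (a.chain, a.res_index, a.atom_name): np.asarray(a.coords)
        for a in mobile.atoms
        if selection(a)
    }
    shared = sorted(set(ref_map) & set(mob_map))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared atoms under selection, got {len(shared)}")
    P = np.array([mob_map[k] for k in shared])  # mobile
    Q = np.array([ref_map[k] for k in shared])  # reference

    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    if np.linalg.matrix_rank(H) < 2:
        raise ValueError("degenerate (collinear) selection: superposition underdetermined")
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return R, t, rmsd
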