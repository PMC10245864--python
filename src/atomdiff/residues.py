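"""Canonical residue atom tables and the sidechain-superposition algebra.

Two dense coordinate layouts are used throughout the package:

* **atom37** — one slot per distinct heavy-atom name occurring in protein
  chains.  The vocabulary follows the AlphaFold ordering and has 37 names;
  36 of them occur within the 20 canonical residue types, and the final
  ``OXT`` slot is reserved for the C-terminal carboxyl oxygen, which this
  package never models (it is dropped on input and always masked).

* **atom73** — the superposition layout: 5 slots shared by every residue
  type (N, CA, C, CB, O) followed by one *exclusive* block per residue
  type holding its sidechain atoms beyond CB.  The exclusive blocks are
  disjoint, so the coordinates of all twenty possible sidechains at a
  position can be stored simultaneously and denoised independently.

``collapse`` selects, per residue, the slots matching a given sequence to
produce a concrete (masked atom37) structure; ``update`` writes newly
predicted coordinates for a sequence back into the superposition, touching
only the addressed slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "AA_ORDER",
    "AA1_TO_AA3",
    "AA3_TO_AA1",
    "ATOM37_NAMES",
    "ATOM37_INDEX",
    "BACKBONE_ATOMS",
    "SHARED_ATOM73",
    "N_ATOM73",
    "RESIDUE_ATOMS",
    "Atom73Layout",
    "ATOM73",
    "CollapsedStructure",
    "Superposition",
    "atoms_for",
    "shared_atoms",
    "build_atom73_layout",
    "canonical_mask",
    "sequence_mask",
    "collapse",
    "update",
    "obscure_atom_mask",
    "export_atom_table",
]

# --------------------------------------------------------------------------
# Amino-acid codes
# --------------------------------------------------------------------------

#: Three-letter codes of the 20 canonical amino acids, alphabetical.
AA_ORDER: Tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA3_TO_AA1: Dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3: Dict[str, str] = {v: k for k, v in AA3_TO_AA1.items()}

#: One-letter alphabet in the same (alphabetical three-letter) order.
AA1_ORDER: str = "".join(AA3_TO_AA1[aa] for aa in AA_ORDER)


def _canon3(code: str) -> str:
    """Normalise a one- or three-letter amino-acid code to three letters."""
    c = code.upper()
    if len(c) == 1:
        if c not in AA1_TO_AA3:
            raise KeyError(f"unknown amino-acid code: {code!r}")
        return AA1_TO_AA3[c]
    if c not in AA3_TO_AA1:
        raise KeyError(f"unknown amino-acid code: {code!r}")
    return c


# --------------------------------------------------------------------------
# atom37 vocabulary (AlphaFold ordering) and per-residue atom lists
# --------------------------------------------------------------------------

ATOM37_NAMES: Tuple[str, ...] = (
    "N", "CA", "C", "CB", "O", "CG", "CG1", "CG2", "OG", "OG1", "SG", "CD",
    "CD1", "CD2", "ND1", "ND2", "OD1", "OD2", "SD", "CE", "CE1", "CE2",
    "CE3", "NE", "NE1", "NE2", "OE1", "OE2", "CH2", "NH1", "NH2", "OH",
    "CZ", "CZ2", "CZ3", "NZ", "OXT",
)
ATOM37_INDEX: Dict[str, int] = {n: i for i, n in enumerate(ATOM37_NAMES)}

BACKBONE_ATOMS: Tuple[str, ...] = ("N", "CA", "C", "O")

# Sidechain atoms beyond CB, per residue type, ordered by atom37 index.
_SIDECHAIN_BEYOND_CB: Dict[str, Tuple[str, ...]] = {
    "ALA": (),
    "ARG": ("CG", "CD", "NE", "NH1", "NH2", "CZ"),
    "ASN": ("CG", "ND2", "OD1"),
    "ASP": ("CG", "OD1", "OD2"),
    "CYS": ("SG",),
    "GLN": ("CG", "CD", "NE2", "OE1"),
    "GLU": ("CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CG", "CD2", "ND1", "CE1", "NE2"),
    "ILE": ("CG1", "CG2", "CD1"),
    "LEU": ("CG", "CD1", "CD2"),
    "LYS": ("CG", "CD", "CE", "NZ"),
    "MET": ("CG", "SD", "CE"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CG", "CD"),
    "SER": ("OG",),
    "THR": ("CG2", "OG1"),
    "TRP": ("CG", "CD1", "CD2", "CE2", "CE3", "NE1", "CH2", "CZ2", "CZ3"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "OH", "CZ"),
    "VAL": ("CG1", "CG2"),
}

#: Ordered heavy-atom names per residue type: N, CA, C, O, then CB (except
#: glycine), then the remaining sidechain atoms in atom37 order.
RESIDUE_ATOMS: Dict[str, Tuple[str, ...]] = {
    aa: BACKBONE_ATOMS + (() if aa == "GLY" else ("CB",)) + _SIDECHAIN_BEYOND_CB[aa]
    for aa in AA_ORDER
}


def atoms_for(residue_type: str) -> List[str]:
    """Ordered canonical heavy-atom names of one residue type.

    Order: N, CA, C, O, CB (absent for glycine), then remaining sidechain
    atoms by atom37 index.  Accepts one- or three-letter codes.
    """
    return list(RESIDUE_ATOMS[_canon3(residue_type)])


def shared_atoms(a: str, b: str) -> set:
    """Atom names common to residue types ``a`` and ``b``."""
    return set(atoms_for(a)) & set(atoms_for(b))


# --------------------------------------------------------------------------
# atom73 layout
# --------------------------------------------------------------------------

#: Shared atom73 slots, in the order N, CA, C, CB, O.
SHARED_ATOM73: Tuple[str, ...] = ("N", "CA", "C", "CB", "O")


@dataclass(frozen=True)
class Atom73Layout:
    """Slot assignment of the 73-slot superposition layout.

    5 shared slots (N, CA, C, CB, O) followed by disjoint exclusive blocks,
    one per residue type in alphabetical order, holding that type's
    sidechain atoms beyond CB in atom37 order.
    """

    n_slots: int
    shared: Tuple[str, ...]
    blocks: Dict[str, Tuple[int, int]]          # residue type -> [start, stop)
    slot_names: Tuple[str, ...]                  # length n_slots
    _slot_of: Dict[Tuple[str, str], int] = field(repr=False, default_factory=dict)

    def slot_of(self, residue_type: str, atom_name: str) -> int:
        """Slot index of ``atom_name`` within residue type ``residue_type``."""
        key = (_canon3(residue_type), atom_name)
        if key not in self._slot_of:
            raise KeyError(
                f"atom {atom_name!r} is not part of residue type {key[0]!r}"
            )
        return self._slot_of[key]

    def block_size(self, residue_type: str) -> int:
        start, stop = self.blocks[_canon3(residue_type)]
        return stop - start

    def slots_for(self, residue_type: str) -> np.ndarray:
        """atom73 slot indices for a residue type, aligned with atoms_for."""
        aa = _canon3(residue_type)
        return np.array([self._slot_of[(aa, a)] for a in RESIDUE_ATOMS[aa]], dtype=int)

    def atom37_indices_for(self, residue_type: str) -> np.ndarray:
        """atom37 indices for a residue type, aligned with atoms_for."""
        aa = _canon3(residue_type)
        return np.array([ATOM37_INDEX[a] for a in RESIDUE_ATOMS[aa]], dtype=int)


def build_atom73_layout(residue_atoms: Optional[Dict[str, Sequence[str]]] = None) -> Atom73Layout:
    """Construct the atom73 layout from the canonical residue atom table."""
    table = residue_atoms if residue_atoms is not None else RESIDUE_ATOMS
    slot_of: Dict[Tuple[str, str], int] = {}
    slot_names: List[str] = list(SHARED_ATOM73)
    blocks: Dict[str, Tuple[int, int]] = {}
    shared_index = {name: i for i, name in enumerate(SHARED_ATOM73)}
    cursor = len(SHARED_ATOM73)
    for aa in AA_ORDER:
        start = cursor
        for atom in table[aa]:
            if atom in shared_index:
                slot_of[(aa, atom)] = shared_index[atom]
            else:
                slot_of[(aa, atom)] = cursor
                slot_names.append(f"{aa}:{atom}")
                cursor += 1
        blocks[aa] = (start, cursor)
    return Atom73Layout(
        n_slots=cursor,
        shared=SHARED_ATOM73,
        blocks=blocks,
        slot_names=tuple(slot_names),
        _slot_of=slot_of,
    )


#: The package-wide atom73 layout.
ATOM73: Atom73Layout = build_atom73_layout()
N_ATOM73: int = ATOM73.n_slots

# Precomputed per-residue-type index maps (atom37 <-> atom73), used by the
# hot collapse/update paths.
_A37_FOR: Dict[str, np.ndarray] = {aa: ATOM73.atom37_indices_for(aa) for aa in AA_ORDER}
_A73_FOR: Dict[str, np.ndarray] = {aa: ATOM73.slots_for(aa) for aa in AA_ORDER}

# Shared atom73 slot indices of the four backbone atoms (always stepped).
BACKBONE_SLOTS73: np.ndarray = np.array(
    [SHARED_ATOM73.index(a) for a in BACKBONE_ATOMS], dtype=int
)


def canonical_mask(residue_type: str) -> np.ndarray:
    """Boolean atom37 mask of one residue type."""
    m = np.zeros(len(ATOM37_NAMES), dtype=bool)
    m[_A37_FOR[_canon3(residue_type)]] = True
    return m


_CANONICAL_MASK: Dict[str, np.ndarray] = {aa: canonical_mask(aa) for aa in AA_ORDER}


def sequence_mask(sequence: str) -> np.ndarray:
    """L x 37 boolean mask of a one-letter sequence."""
    return np.stack([_CANONICAL_MASK[_canon3(c)] for c in sequence])


# --------------------------------------------------------------------------
# Structure containers
# --------------------------------------------------------------------------


@dataclass
class CollapsedStructure:
    """A concrete ("real") protein: sequence + masked atom37 coordinates.

    Parameters
    ----------
    sequence
        One-letter amino-acid string, length L.
    coords37
        (L, 37, 3) float array of heavy-atom coordinates in Angstrom.
        Entries outside ``atom_mask`` carry no meaning.
    atom_mask
        (L, 37) boolean; normally the canonical atom set of ``sequence``
        (the mask-obscuring operation produces an all-true mask instead).
    atom_sigma
        Optional (L, 37) per-atom noise level in Angstrom.
    """

    sequence: str
    coords37: np.ndarray
    atom_mask: np.ndarray
    atom_sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords37 = np.asarray(self.coords37, dtype=float)
        self.atom_mask = np.asarray(self.atom_mask, dtype=bool)
        L = len(self.sequence)
        if self.coords37.shape != (L, 37, 3):
            raise ValueError(
                f"coords37 shape {self.coords37.shape} does not match "
                f"sequence length {L}"
            )
        if self.atom_mask.shape != (L, 37):
            raise ValueError("atom_mask must have shape (L, 37)")
        if self.atom_sigma is not None:
            self.atom_sigma = np.asarray(self.atom_sigma, dtype=float)
            if self.atom_sigma.shape != (L, 37):
                raise ValueError("atom_sigma must have shape (L, 37)")
        for c in self.sequence:
            _canon3(c)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def copy(self) -> "CollapsedStructure":
        return CollapsedStructure(
            sequence=self.sequence,
            coords37=self.coords37.copy(),
            atom_mask=self.atom_mask.copy(),
            atom_sigma=None if self.atom_sigma is None else self.atom_sigma.copy(),
        )

    def masked_coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinates of the unmasked atoms."""
        return self.coords37[self.atom_mask]

    def has_canonical_mask(self) -> bool:
        return bool(np.array_equal(self.atom_mask, sequence_mask(self.sequence)))


@dataclass
class Superposition:
    """Per-residue 73-slot coordinate state with per-slot noise bookkeeping.

    Holds one coordinate instance (the sampler keeps two Superpositions, one
    for the noisy state X_t and one for the denoised estimate X_0).
    ``slot_sigma`` records, per slot, the noise level (Angstrom) at which
    the slot was last written; it is non-increasing over a sampling
    trajectory.
    """

    coords73: np.ndarray        # (L, 73, 3)
    slot_sigma: np.ndarray      # (L, 73)

    def __post_init__(self) -> None:
        self.coords73 = np.asarray(self.coords73, dtype=float)
        self.slot_sigma = np.asarray(self.slot_sigma, dtype=float)
        if self.coords73.ndim != 3 or self.coords73.shape[1:] != (N_ATOM73, 3):
            raise ValueError(f"coords73 must have shape (L, {N_ATOM73}, 3)")
        if self.slot_sigma.shape != self.coords73.shape[:2]:
            raise ValueError(f"slot_sigma must have shape (L, {N_ATOM73})")

    @property
    def length(self) -> int:
        return self.coords73.shape[0]

    def copy(self) -> "Superposition":
        return Superposition(self.coords73.copy(), self.slot_sigma.copy())

    @classmethod
    def zeros(cls, L: int, sigma: float = 0.0) -> "Superposition":
        return cls(
            np.zeros((L, N_ATOM73, 3)),
            np.full((L, N_ATOM73), float(sigma)),
        )


# --------------------------------------------------------------------------
# Collapse / update algebra
# --------------------------------------------------------------------------


def _index_arrays(sequence: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flattened (residue, atom37, atom73) index triples for a sequence."""
    res_idx, a37, a73 = [], [], []
    for i, c in enumerate(sequence):
        aa = _canon3(c)
        n = len(RESIDUE_ATOMS[aa])
        res_idx.append(np.full(n, i, dtype=int))
        a37.append(_A37_FOR[aa])
        a73.append(_A73_FOR[aa])
    return np.concatenate(res_idx), np.concatenate(a37), np.concatenate(a73)


def collapse(sp: Superposition, sequence: str) -> CollapsedStructure:
    """Select the slots matching ``sequence`` to yield a concrete structure.

    Copies, for each residue i, the atom73 slots of ``sequence[i]`` into the
    corresponding atom37 channels; everything else is masked.  The per-slot
    noise levels are carried along as ``atom_sigma``.
    """
    if len(sequence) != sp.length:
        raise ValueError(
            f"sequence length {len(sequence)} does not match superposition "
            f"length {sp.length}"
        )
    L = sp.length
    coords37 = np.zeros((L, 37, 3))
    sigma37 = np.zeros((L, 37))
    mask = np.zeros((L, 37), dtype=bool)
    res, a37, a73 = _index_arrays(sequence)
    coords37[res, a37] = sp.coords73[res, a73]
    sigma37[res, a37] = sp.slot_sigma[res, a73]
    mask[res, a37] = True
    return CollapsedStructure(sequence, coords37, mask, atom_sigma=sigma37)


def update(
    sp: Superposition,
    sequence: str,
    s: CollapsedStructure,
    slot_sigma=None,
    where: Optional[np.ndarray] = None,
) -> Superposition:
    """Write ``s``'s coordinates back into the slots addressed by ``sequence``.

    Only the (sequence[i], atom) slots are overwritten; all other slots'
    coordinates and noise levels are untouched.  The overwritten slots'
    ``slot_sigma`` is set to ``slot_sigma`` (scalar or (L, 37) array); if
    None, ``s.atom_sigma`` is used.

    Parameters
    ----------
    where
        Optional (L, 37) boolean restricting the write to a subset of the
        addressed atoms (used by the sampler when the denoiser output does
        not carry every atom of a newly predicted sequence).
    """
    if len(sequence) != sp.length or s.length != sp.length:
        raise ValueError("sequence/structure length does not match superposition")
    if where is None and not np.array_equal(s.atom_mask, sequence_mask(sequence)):
        raise ValueError("structure atom_mask is inconsistent with sequence")
    if slot_sigma is None:
        if s.atom_sigma is None:
            raise ValueError("no noise level supplied (slot_sigma or s.atom_sigma)")
        sigma37 = s.atom_sigma
    else:
        sigma37 = np.broadcast_to(np.asarray(slot_sigma, dtype=float), (sp.length, 37))
    out = sp.copy()
    res, a37, a73 = _index_arrays(sequence)
    if where is not None:
        keep = np.asarray(where, dtype=bool)[res, a37]
        res, a37, a73 = res[keep], a37[keep], a73[keep]
    out.coords73[res, a73] = s.coords37[res, a37]
    out.slot_sigma[res, a73] = sigma37[res, a37]
    return out


def obscure_atom_mask(
    s: CollapsedStructure, sigma: float, rng: np.random.Generator
) -> CollapsedStructure:
    """Noise all 37 atom channels so the mask no longer betrays the sequence.

    True atoms are noised in place with i.i.d. Gaussian noise of scale
    ``sigma``; absent atoms are filled with noise of the same scale centred
    on the residue's CA, keeping the filler spatially local.  The returned
    mask is all-true, so sequence identity is not recoverable from the mask
    alone.  The reserved OXT channel is filled like any other absent atom.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    L = s.length
    ca = s.coords37[:, ATOM37_INDEX["CA"], :]          # (L, 3)
    base = np.where(s.atom_mask[..., None], s.coords37, ca[:, None, :])
    coords = base + rng.normal(scale=sigma, size=(L, 37, 3)) if sigma > 0 else base.copy()
    return CollapsedStructure(
        sequence=s.sequence,
        coords37=coords,
        atom_mask=np.ones((L, 37), dtype=bool),
        atom_sigma=np.full((L, 37), float(sigma)),
    )


# --------------------------------------------------------------------------
# Machine-readable export of the slot tables
# --------------------------------------------------------------------------


def export_atom_table() -> List[Tuple[str, str, int, int]]:
    """Rows of (residue code, atom name, atom37 index, atom73 slot)."""
    rows = []
    for aa in AA_ORDER:
        for atom in RESIDUE_ATOMS[aa]:
            rows.append((aa, atom, ATOM37_INDEX[atom], ATOM73.slot_of(aa, atom)))
    return rows


def write_atom_table_csv(path) -> None:
    """Write the slot table as CSV (shipped copy lives in atomdiff/data)."""
    with open(path, "w") as fh:
        fh.write("residue,atom,atom37_index,atom73_slot\n")
        for aa, atom, i37, i73 in export_atom_table():
            fh.write(f"{aa},{atom},{i37},{i73}\n")
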