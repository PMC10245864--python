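"""PDB reading and writing for CollapsedStructure (via biotite).

Conventions: single chain 'A', 1-based residue numbering in files (0-based
internally), occupancy 1.00, and the B-factor column carries the per-atom
noise level in Angstrom (0.00 for finished samples).  Only heavy atoms of
the 20 canonical residue types are modelled: hydrogens, OXT, HETATM
records and non-canonical residues are skipped with a logged warning.
For alternate locations the highest-occupancy conformer is kept (ties go
to altloc 'A').
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .residues import (
    AA3_TO_AA1,
    ATOM37_INDEX,
    ATOM37_NAMES,
    CollapsedStructure,
    RESIDUE_ATOMS,
    sequence_mask,
)

__all__ = ["read_pdb", "write_pdb"]

logger = logging.getLogger(__name__)


def read_pdb(path) -> CollapsedStructure:
    """Read a single-model, single-chain PDB file into a CollapsedStructure.

    The B-factor column is interpreted as a per-atom noise level.  Unknown
    residues and atoms outside a residue type's canonical heavy-atom set
    are skipped with a warning; a write/read round trip preserves sequence,
    mask and coordinates to the format's 3-decimal precision.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(
            model=1, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
        )
    except Exception as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc

    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no ATOM records of canonical residues")
    chains = np.unique(atoms.chain_id)
    if len(chains) > 1:
        logger.warning("%s: %d chains found, keeping chain %r",
                       path, len(chains), chains[0])
        atoms = atoms[atoms.chain_id == chains[0]]

    res_ids = []
    seen = set()
    for rid in atoms.res_id:
        if rid not in seen:
            seen.add(rid)
            res_ids.append(rid)

    sequence = []
    kept_rows = []
    for i, rid in enumerate(res_ids):
        sel = atoms[atoms.res_id == rid]
        res_name = sel.res_name[0]
        if res_name not in AA3_TO_AA1:
            logger.warning("%s: skipping non-canonical residue %s %d",
                           path, res_name, rid)
            continue
        allowed = set(RESIDUE_ATOMS[res_name])
        row = {}
        for j in range(sel.array_length()):
            name = sel.atom_name[j]
            if name not in allowed:
                logger.warning("%s: dropping atom %s from %s %d "
                               "(not in canonical heavy-atom set)",
                               path, name, res_name, rid)
                continue
            row[name] = (sel.coord[j], float(sel.b_factor[j]))
        sequence.append(AA3_TO_AA1[res_name])
        kept_rows.append(row)

    if not sequence:
        raise ValueError(f"{path}: no canonical residues found")
    L = len(sequence)
    coords37 = np.zeros((L, 37, 3))
    sigma37 = np.zeros((L, 37))
    mask = np.zeros((L, 37), dtype=bool)
    for i, row in enumerate(kept_rows):
        for name, (xyz, b) in row.items():
            k = ATOM37_INDEX[name]
            coords37[i, k] = xyz
            sigma37[i, k] = b
            mask[i, k] = True
    return CollapsedStructure("".join(sequence), coords37, mask, atom_sigma=sigma37)


def write_pdb(s: CollapsedStructure, path) -> None:
    """Write a CollapsedStructure as a standard fixed-width PDB file."""
    from .residues import AA1_TO_AA3

    n_atoms = int(s.atom_mask.sum())
    arr = struc.AtomArray(n_atoms)
    arr.add_annotation("b_factor", dtype=float)
    arr.add_annotation("occupancy", dtype=float)
    k = 0
    for i, c in enumerate(s.sequence):
        aa3 = AA1_TO_AA3[c.upper()]
        for name in RESIDUE_ATOMS[aa3]:
            j = ATOM37_INDEX[name]
            if not s.atom_mask[i, j]:
                continue
            arr.coord[k] = s.coords37[i, j]
            arr.chain_id[k] = "A"
            arr.res_id[k] = i + 1
            arr.res_name[k] = aa3
            arr.atom_name[k] = name
            arr.element[k] = name[0]
            arr.hetero[k] = False
            arr.occupancy[k] = 1.0
            arr.b_factor[k] = (
                float(s.atom_sigma[i, j]) if s.atom_sigma is not None else 0.0
            )
            k += 1
    # obscured structures may set mask entries outside the canonical atom
    # set (incl. the reserved OXT channel); those are not writable atoms
    if k < n_atoms:
        arr = arr[:k]
        logger.warning("write_pdb: %d masked channels without canonical atoms "
                       "were not written", n_atoms - k)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
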