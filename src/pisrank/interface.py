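"""Interface-residue detection.

A residue belongs to the interface set I when at least one of its atoms
(heavy atoms by default) lies within a distance cutoff of an atom on a
*different* polymer chain. The default cutoff of 4.5 Å between heavy
atoms is the interface convention of the interface-TM-score lineage
this toolkit implements. I is partitioned per chain into the sets I_p,
whose union is I.

Ligand and ion atoms never create interface residues: the confidence
scores downstream are residue-indexed over polymer chains only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model_io import AtomRecord, ComplexStructure

__all__ = ["InterfaceSet", "find_interface", "interface_by_pair", "interface_to_tsv"]

DEFAULT_CUTOFF = 4.5  # Å, heavy-atom contact


@dataclass
class InterfaceSet:
    """The interfacial residue set I and its per-chain partition {I_p}."""

    residues: tuple[tuple[str, int], ...]
    by_chain: dict[str, tuple[tuple[str, int], ...]]
    cutoff_used: float

    @property
    def size(self) -> int:
        """|I|, the total number of interfacial residues."""
        return len(self.residues)

    def chains(self) -> list[str]:
        return [c for c, members in self.by_chain.items() if members]


def _candidate_atoms(
    structure: ComplexStructure, heavy_only: bool, protein_only: bool
) -> list[AtomRecord]:
    protein_chains: set[str] | None = None
    if protein_only:
        # a chain counts as protein when it contains CA atoms
        protein_chains = {
            a.chain_id for a in structure.atoms if a.is_polymer and a.atom_name == "CA"
        }
    out = []
    for a in structure.atoms:
        if not a.is_polymer:
            continue
        if heavy_only and a.is_hydrogen:
            continue
        if protein_chains is not None and a.chain_id not in protein_chains:
            continue
        out.append(a)
    return out


def _contact_pairs(
    atoms: list[AtomRecord], cutoff: float
) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """All cross-chain residue pairs with an atom-atom distance <= cutoff."""
    if len(atoms) < 2:
        return set()
    coords = np.array([a.xyz for a in atoms])
    tree = cKDTree(coords)
    pairs: set[tuple[tuple[str, int], tuple[str, int]]] = set()
    for i, j in tree.query_pairs(cutoff):
        ai, aj = atoms[i], atoms[j]
        if ai.chain_id == aj.chain_id:
            continue
        ri = (ai.chain_id, ai.residue_index)
        rj = (aj.chain_id, aj.residue_index)
        pairs.add((ri, rj) if ri <= rj else (rj, ri))
    return pairs


def find_interface(
    structure: ComplexStructure,
    cutoff: float = DEFAULT_CUTOFF,
    heavy_only: bool = True,
    protein_only: bool = False,
) -> InterfaceSet:
    """Determine the interfacial residue set I of a complex.

    Parameters
    ----------
    structure
        The complex to analyse.
    cutoff
        Contact distance in Å; an atom pair at exactly the cutoff counts
        as a contact.
    heavy_only
        Ignore hydrogens when measuring contacts (default).
    protein_only
        Restrict I to protein chains, excluding nucleic-acid residues.

    A single-chain structure yields an empty interface (no error).
    Members of I are ordered by (chain_id, residue_index) so downstream
    maxima are reproducible under ties.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    atoms = _candidate_atoms(structure, heavy_only, protein_only)
    members: set[tuple[str, int]] = set()
    for ri, rj in _contact_pairs(atoms, cutoff):
        members.add(ri)
        members.add(rj)
    ordered = tuple(sorted(members))
    by_chain: dict[str, tuple[tuple[str, int], ...]] = {
        c: tuple(r for r in ordered if r[0] == c) for c in structure.chain_ids
    }
    by_chain = {c: v for c, v in by_chain.items() if v}
    return InterfaceSet(residues=ordered, by_chain=by_chain, cutoff_used=cutoff)


def interface_by_pair(
    structure: ComplexStructure,
    cutoff: float = DEFAULT_CUTOFF,
    heavy_only: bool = True,
    protein_only: bool = False,
) -> dict[tuple[str, str], list[tuple[tuple[str, int], tuple[str, int]]]]:
    """Per chain-pair residue contact lists.

    Returns a map from the sorted chain-id pair to the sorted list of
    residue pairs in contact; symmetric under chain-pair swap by
    construction. Chain pairs with no contacts are omitted.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    atoms = _candidate_atoms(structure, heavy_only, protein_only)
    out: dict[tuple[str, str], set] = {}
    for ri, rj in _contact_pairs(atoms, cutoff):
        key = (ri[0], rj[0])
        out.setdefault(key, set()).add((ri, rj))
    return {k: sorted(v) for k, v in sorted(out.items())}


def interface_to_tsv(interface: InterfaceSet, pair_map=None) -> str:
    """BED-like TSV export: chain, residue_index, partner_chains."""
    partners: dict[tuple[str, int], set[str]] = {}
    if pair_map:
        for (c1, c2), pairs in pair_map.items():
            for ri, rj in pairs:
                partners.setdefault(ri, set()).add(rj[0])
                partners.setdefault(rj, set()).add(ri[0])
    lines = ["chain\tresidue_index\tpartner_chains"]
    for res in interface.residues:
        p = ",".join(sorted(partners.get(res, set()))) or "."
        lines.append(f"{res[0]}\t{res[1]}\t{p}")
    return "\n".join(lines) + "\n"
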