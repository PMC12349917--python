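"""Deterministic synthetic complexes, PAE matrices and decoys.

Everything the test surface needs is generated here, with no
downloads: toy multi-chain complexes with exactly controlled
inter-chain geometry, matching confidence bundles with planted error
patterns, rigid-body decoys for evaluation tests, and consistent job
specifications.

Geometry is idealised: each chain is a straight strand of
poly-alanine-like residues (4 heavy atoms each, N/CA/C/O names on a
zig-zag line), chains are stacked along y so that the closest
inter-chain heavy-atom distance equals ``inter_chain_gap`` exactly by
construction. Scoring and evaluation depend only on inter-atomic
distances, not stereochemistry, so no attempt is made at realistic
bond geometry or side chains. Sequences are all-alanine with a
chain-distinct first residue so chain mapping is unambiguous.

Every fixture is a pure function of its recipe: the same seed yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .model_io import (
    AtomRecord,
    ComplexStructure,
    ConfidenceBundle,
    JobSpec,
    LigandEntry,
    IonEntry,
    PaeMatrix,
    PolymerEntry,
    Token,
    write_confidence,
    write_jobspec,
    write_structure,
)

__all__ = [
    "ZeroPae",
    "UniformPae",
    "PlantedPae",
    "FixtureRecipe",
    "make_complex",
    "make_pae",
    "make_decoys",
    "make_random_complex",
    "write_fixture_bundle",
]

# residue pitch along the strand and heavy-atom offsets within a residue
_PITCH = 4.5
_ATOM_OFFSETS = (("N", 0.0, 0.0), ("CA", 1.2, 0.7), ("C", 2.4, 0.0), ("O", 3.3, 0.7))

# chain-distinct first residues (cycled for many chains)
_MARKERS = ("GLY", "SER", "THR", "VAL", "LEU", "ILE", "PHE", "TYR", "TRP", "MET")
_MARKER_LETTERS = dict(
    GLY="G", SER="S", THR="T", VAL="V", LEU="L", ILE="I", PHE="F", TYR="Y", TRP="W", MET="M"
)


@dataclass(frozen=True)
class ZeroPae:
    """Perfect confidence: every expected error is 0 Å."""


@dataclass(frozen=True)
class UniformPae:
    """Errors drawn uniformly from [lo, hi] Å, diagonal zero."""

    lo: float = 0.5
    hi: float = 10.0


@dataclass(frozen=True)
class PlantedPae:
    """Cross-chain token errors around interface_err, same-chain around core_err."""

    interface_err: float = 10.0
    core_err: float = 1.0


PaeMode = Union[ZeroPae, UniformPae, PlantedPae]


@dataclass(frozen=True)
class FixtureRecipe:
    seed: int = 0
    n_chains: int = 2
    residues_per_chain: int = 5
    inter_chain_gap: float = 4.4  # Å, exact closest heavy-atom distance
    pae_noise: PaeMode = ZeroPae()
    decoy_perturbations: tuple[tuple[float, float], ...] = ()  # (rotation°, translation Å)
    with_ligand: bool = False

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.residues_per_chain < 1:
            raise ValueError("need at least one chain and one residue per chain")
        if self.inter_chain_gap <= 0:
            raise ValueError(
                f"impossible geometry: inter_chain_gap must be positive, "
                f"got {self.inter_chain_gap}"
            )


def _chain_id(k: int) -> str:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if k < len(alphabet):
        return alphabet[k]
    return alphabet[k // len(alphabet) - 1] + alphabet[k % len(alphabet)]


def make_complex(recipe: FixtureRecipe) -> tuple[ComplexStructure, JobSpec]:
    """Build a toy complex and a job specification describing it.

    Chain k occupies the plane y = k·gap; atoms of corresponding
    residues in adjacent chains share x and z coordinates, so the
    minimum inter-chain heavy-atom distance is exactly the requested
    gap. The job spec carries placeholder unpaired and paired MSAs (the
    query sequence alone) so the prep transforms have content to act on.
    """
    atoms: list[AtomRecord] = []
    polymers: list[PolymerEntry] = []
    for k in range(recipe.n_chains):
        cid = _chain_id(k)
        marker = _MARKERS[k % len(_MARKERS)]
        seq_letters = []
        for r in range(recipe.residues_per_chain):
            res_name = marker if r == 0 else "ALA"
            seq_letters.append(_MARKER_LETTERS[marker] if r == 0 else "A")
            for name, dx, dz in _ATOM_OFFSETS:
                atoms.append(
                    AtomRecord(
                        chain_id=cid,
                        residue_index=r + 1,
                        residue_name=res_name,
                        atom_name=name,
                        element=name[0],
                        xyz=(r * _PITCH + dx, k * recipe.inter_chain_gap, dz),
                    )
                )
        seq = "".join(seq_letters)
        msa = f">query\n{seq}\n"
        polymers.append(
            PolymerEntry(
                chain_id=cid,
                kind="protein",
                sequence=seq,
                unpaired_msa=msa,
                paired_msa=msa,
            )
        )
    ligands: tuple[LigandEntry, ...] = ()
    ions: tuple[IonEntry, ...] = ()
    if recipe.with_ligand:
        lig_id, ion_id = "L", "Z"
        for i in range(3):  # a small 3-carbon ligand, far from the polymer chains
            atoms.append(
                AtomRecord(
                    chain_id=lig_id,
                    residue_index=1,
                    residue_name="UNL",
                    atom_name=f"C{i + 1}",
                    element="C",
                    xyz=(i * 1.5, -50.0, 0.0),
                    is_polymer=False,
                )
            )
        atoms.append(
            AtomRecord(
                chain_id=ion_id,
                residue_index=1,
                residue_name="MG",
                atom_name="MG",
                element="Mg",
                xyz=(0.0, -60.0, 0.0),
                is_polymer=False,
            )
        )
        ligands = (LigandEntry(chain_ids=(lig_id,), ccd_codes=("UNL",)),)
        ions = (IonEntry(chain_ids=(ion_id,), ccd_codes=("MG",)),)
    structure = ComplexStructure(
        model_id=f"fixture_seed{recipe.seed}", atoms=atoms
    )
    spec = JobSpec(
        job_name=f"fixture_seed{recipe.seed}",
        polymers=tuple(polymers),
        ligands=ligands,
        ions=ions,
        seed=recipe.seed,
    )
    return structure, spec


def make_pae(
    structure: ComplexStructure,
    mode: PaeMode = ZeroPae(),
    seed: int = 0,
    ptm: Optional[float] = None,
    iptm: Optional[float] = None,
) -> ConfidenceBundle:
    """Build a confidence bundle over the structure's polymer residues.

    One token per polymer residue, in structure order. Planted mode
    draws cross-chain entries around ``interface_err`` and same-chain
    entries around ``core_err`` (clipped at zero, zero diagonal),
    emulating a predictor that is confident within chains but uncertain
    about their relative placement.
    """
    tokens = [
        Token(chain_id=c, residue_index=r) for c, r in structure.iter_polymer_residues()
    ]
    n = len(tokens)
    rng = np.random.default_rng(seed)
    if isinstance(mode, ZeroPae):
        values = np.zeros((n, n))
    elif isinstance(mode, UniformPae):
        values = rng.uniform(mode.lo, mode.hi, size=(n, n))
        np.fill_diagonal(values, 0.0)
    elif isinstance(mode, PlantedPae):
        same_chain = np.array(
            [[ti.chain_id == tj.chain_id for tj in tokens] for ti in tokens]
        )
        spread_core = 0.05 * mode.core_err + 0.01
        spread_iface = 0.05 * mode.interface_err + 0.01
        core = rng.normal(mode.core_err, spread_core, size=(n, n))
        iface = rng.normal(mode.interface_err, spread_iface, size=(n, n))
        values = np.where(same_chain, core, iface).clip(min=0.0)
        np.fill_diagonal(values, 0.0)
    else:
        raise TypeError(f"unknown PAE mode: {mode!r}")
    return ConfidenceBundle(
        pae=PaeMatrix(values=values, token_map=tokens), ptm=ptm, iptm=iptm
    )


def _rotate_z(coords: np.ndarray, degrees: float, center: np.ndarray) -> np.ndarray:
    theta = np.deg2rad(degrees)
    rot = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    return (coords - center) @ rot.T + center


def make_decoys(
    reference: ComplexStructure,
    perturbations: Sequence[tuple[float, float]],
) -> list[ComplexStructure]:
    """Rigid-body decoys: each perturbation (rotation°, translation Å)
    rotates the last polymer chain about z through its centroid and then
    translates it along +y, away from the rest of the complex."""
    polymer_chains = reference.polymer_chain_ids
    if len(polymer_chains) < 2:
        raise ValueError("decoys need at least two polymer chains")
    moving = polymer_chains[-1]
    moving_idx = [i for i, a in enumerate(reference.atoms) if a.chain_id == moving]
    coords = reference.coords()
    center = coords[moving_idx].mean(axis=0)
    decoys = []
    for k, (rot_deg, trans) in enumerate(perturbations):
        new_coords = coords.copy()
        moved = _rotate_z(new_coords[moving_idx], rot_deg, center)
        moved[:, 1] += trans
        new_coords[moving_idx] = moved
        atoms = [
            AtomRecord(
                chain_id=a.chain_id,
                residue_index=a.residue_index,
                residue_name=a.residue_name,
                atom_name=a.atom_name,
                element=a.element,
                xyz=tuple(new_coords[i]),
                is_polymer=a.is_polymer,
                is_hydrogen=a.is_hydrogen,
            )
            for i, a in enumerate(reference.atoms)
        ]
        decoys.append(
            ComplexStructure(
                model_id=f"{reference.model_id}_decoy{k}_r{rot_deg:g}_t{trans:g}",
                atoms=atoms,
                chain_ids=list(reference.chain_ids),
            )
        )
    return decoys


def make_random_complex(
    seed: int,
    n_chains: int = 2,
    residues_per_chain: int = 10,
    box_size: float = 25.0,
    atoms_per_residue: int = 3,
) -> ComplexStructure:
    """A complex with uniformly random atom positions in a cubic box.

    No geometric regularity at all — used to exercise distance-based
    operations (interface detection, clash counting) against brute-force
    oracles on arbitrary geometry.
    """
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    names = ("N", "CA", "C", "O", "CB")
    for k in range(n_chains):
        cid = _chain_id(k)
        for r in range(residues_per_chain):
            for a in range(atoms_per_residue):
                xyz = tuple(rng.uniform(0.0, box_size, size=3))
                atoms.append(
                    AtomRecord(
                        chain_id=cid,
                        residue_index=r + 1,
                        residue_name="ALA",
                        atom_name=names[a % len(names)],
                        element=names[a % len(names)][0],
                        xyz=xyz,
                    )
                )
    return ComplexStructure(model_id=f"random_seed{seed}", atoms=atoms)


def write_fixture_bundle(directory: str | Path, recipe: FixtureRecipe) -> dict[str, Path]:
    """Write a complete fixture bundle: model.cif, reference.cif,
    confidence.json and job.json. The model is the reference perturbed
    by the first decoy perturbation (or identical when none given)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    reference, spec = make_complex(recipe)
    if recipe.decoy_perturbations:
        model = make_decoys(reference, recipe.decoy_perturbations[:1])[0]
    else:
        model = reference
    # scalar confidences included so empty-interface models can fall back to pTM
    bundle = make_pae(model, recipe.pae_noise, seed=recipe.seed, ptm=0.8, iptm=0.75)
    paths = {
        "model": directory / "model.cif",
        "reference": directory / "reference.cif",
        "confidence": directory / "confidence.json",
        "job": directory / "job.json",
    }
    write_structure(reference, paths["reference"])
    write_structure(model, paths["model"])
    write_confidence(bundle, paths["confidence"])
    write_jobspec(spec, paths["job"])
    return paths
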