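"""Readers/writers for the three document kinds the pipeline touches.

Structures (mmCIF/PDB via gemmi), confidence bundles (JSON carrying an
N×N predicted-aligned-error matrix plus optional pTM/ipTM scalars) and
job specifications (the JSON dialect consumed by AlphaFold-family
predictors) are loaded into plain domain types that the rest of the
toolkit operates on.

Conventions:

* only the first model/coordinate set of a structure file is read;
* residues are re-indexed 1-based per chain in file order (PDB insertion
  codes are flattened away);
* for alternate locations the highest-occupancy conformer is kept, ties
  broken by altloc identifier order;
* hydrogens are retained but flagged, and excluded from heavy-atom work
  downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional, Sequence

import gemmi
import numpy as np

from .errors import (
    ConfidenceFormatError,
    EmptyStructureError,
    JobSpecError,
    StructureFormatError,
    TokenMappingError,
)

__all__ = [
    "AtomRecord",
    "ComplexStructure",
    "Token",
    "PaeMatrix",
    "ConfidenceBundle",
    "PolymerEntry",
    "LigandEntry",
    "IonEntry",
    "JobSpec",
    "read_structure",
    "write_structure",
    "read_confidence",
    "write_confidence",
    "read_jobspec",
    "write_jobspec",
    "validate_token_coverage",
]

POLYMER_KINDS = ("protein", "dna", "rna")


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a complex, with 1-based per-chain residue indexing."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]
    is_polymer: bool = True
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        if not self.element:
            raise ValueError("element must be non-empty")
        if not all(math.isfinite(c) for c in self.xyz):
            raise ValueError(f"non-finite coordinates: {self.xyz}")


@dataclass
class ComplexStructure:
    """Chains, residues and atom coordinates of one predicted or reference complex."""

    model_id: str
    atoms: list[AtomRecord]
    chain_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chain_ids:
            seen: dict[str, None] = {}
            for a in self.atoms:
                seen.setdefault(a.chain_id, None)
            self.chain_ids = list(seen)
        missing = {a.chain_id for a in self.atoms} - set(self.chain_ids)
        if missing:
            raise ValueError(f"atoms reference chains not in chain_ids: {sorted(missing)}")

    @property
    def chain_count(self) -> int:
        return len(self.chain_ids)

    @property
    def polymer_chain_ids(self) -> list[str]:
        poly = {a.chain_id for a in self.atoms if a.is_polymer}
        return [c for c in self.chain_ids if c in poly]

    def iter_polymer_residues(self) -> Iterator[tuple[str, int]]:
        """Yield (chain_id, residue_index) for polymer residues, in atom order."""
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if not a.is_polymer:
                continue
            key = (a.chain_id, a.residue_index)
            if key not in seen:
                seen.add(key)
                yield key

    def heavy_atoms(self, polymer_only: bool = True) -> list[AtomRecord]:
        return [
            a
            for a in self.atoms
            if not a.is_hydrogen and (a.is_polymer or not polymer_only)
        ]

    def coords(self, atoms: Optional[Sequence[AtomRecord]] = None) -> np.ndarray:
        pool = self.atoms if atoms is None else atoms
        if not pool:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in pool], dtype=float)

    def chain_atoms(self, chain_id: str, heavy_only: bool = True) -> list[AtomRecord]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain_id and not (heavy_only and a.is_hydrogen)
        ]


def _pick_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
        elif (atom.occ, _altloc_rank(prev)) > (prev.occ, _altloc_rank(atom)):
            # strictly higher occupancy wins; on equal occupancy the earlier
            # altloc identifier (e.g. 'A' before 'B') is kept
            if atom.occ > prev.occ:
                best[atom.name] = atom
    return list(best.values())


def _altloc_rank(atom: gemmi.Atom) -> int:
    return ord(atom.altloc) if atom.altloc else 0


def read_structure(
    path: str | Path, format: Literal["mmcif", "pdb", "auto"] = "auto"
) -> ComplexStructure:
    """Read the first model of an mmCIF or PDB file into a ComplexStructure.

    Hydrogens are kept but flagged; residues are renumbered 1-based per
    chain in file order; non-polymer components (ligands, ions, waters
    excluded) are loaded with ``is_polymer=False``.
    """
    path = Path(path)
    fmt = {
        "mmcif": gemmi.CoorFormat.Mmcif,
        "pdb": gemmi.CoorFormat.Pdb,
        "auto": gemmi.CoorFormat.Detect,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no coordinate models found")

    atoms: list[AtomRecord] = []
    chain_ids: list[str] = []
    model = st[0]  # first model only
    for chain in model:
        chain_ids.append(chain.name)
        res_counter = 0
        for residue in chain:
            if residue.is_water():
                continue
            res_counter += 1
            is_poly = residue.entity_type == gemmi.EntityType.Polymer
            for atom in _pick_altlocs(residue):
                pos = atom.pos
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_index=res_counter,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        xyz=(pos.x, pos.y, pos.z),
                        is_polymer=is_poly,
                        is_hydrogen=atom.element.is_hydrogen,
                    )
                )
    chain_ids = [c for c in chain_ids if any(a.chain_id == c for a in atoms)]
    if not any(a.is_polymer for a in atoms):
        raise EmptyStructureError(f"{path}: no polymer chains")
    return ComplexStructure(model_id=path.stem, atoms=atoms, chain_ids=chain_ids)


def write_structure(
    structure: ComplexStructure,
    path: str | Path,
    format: Literal["mmcif", "pdb", "auto"] = "auto",
) -> None:
    """Write a ComplexStructure as mmCIF or PDB (chosen by extension when auto)."""
    path = Path(path)
    if format == "auto":
        format = "pdb" if path.suffix.lower() in {".pdb", ".ent"} else "mmcif"
    st = gemmi.Structure()
    st.name = structure.model_id
    model = gemmi.Model(1)
    for chain_id in structure.chain_ids:
        chain = gemmi.Chain(chain_id)
        # gemmi containers copy on add: assemble each residue fully first
        grouped: dict[int, list[AtomRecord]] = {}
        for a in structure.atoms:
            if a.chain_id == chain_id:
                grouped.setdefault(a.residue_index, []).append(a)
        for res_index in sorted(grouped):
            group = grouped[res_index]
            residue = gemmi.Residue()
            residue.name = group[0].residue_name
            residue.seqid = gemmi.SeqId(res_index, " ")
            if not group[0].is_polymer:
                residue.het_flag = "H"
            for a in group:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.xyz)
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# confidence bundles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Token:
    """One row/column of the PAE matrix, mapped to a residue."""

    chain_id: str
    residue_index: int
    is_polymer: bool = True


@dataclass
class PaeMatrix:
    """N×N expected position errors ⟨e_ij⟩ in Å with a token→residue map.

    Entry (i, j) is the expected error of token j's position when the
    prediction is aligned on token i; the matrix need not be symmetric.
    """

    values: np.ndarray
    token_map: list[Token]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ConfidenceFormatError(
                f"PAE matrix must be square, got shape {self.values.shape}"
            )
        if len(self.token_map) != self.values.shape[0]:
            raise ConfidenceFormatError(
                f"token map length {len(self.token_map)} != matrix dimension "
                f"{self.values.shape[0]}"
            )
        if self.values.size and (not np.all(np.isfinite(self.values)) or self.values.min() < 0):
            raise ConfidenceFormatError("PAE entries must be finite and >= 0")

    @property
    def n_tokens(self) -> int:
        return self.values.shape[0]

    def token_index(self) -> dict[tuple[str, int], int]:
        """Map (chain_id, residue_index) -> matrix index, polymer tokens only."""
        out: dict[tuple[str, int], int] = {}
        for i, tok in enumerate(self.token_map):
            if tok.is_polymer:
                key = (tok.chain_id, tok.residue_index)
                if key in out:
                    raise ConfidenceFormatError(f"duplicate polymer token {key}")
                out[key] = i
        return out


@dataclass
class ConfidenceBundle:
    """PAE matrix plus the optional whole-model confidence scalars."""

    pae: PaeMatrix
    ptm: Optional[float] = None
    iptm: Optional[float] = None

    def __post_init__(self) -> None:
        for name, val in (("ptm", self.ptm), ("iptm", self.iptm)):
            if val is not None and not (0.0 <= val <= 1.0):
                raise ConfidenceFormatError(f"{name} must lie in [0, 1], got {val}")


def read_confidence(path: str | Path) -> ConfidenceBundle:
    """Read a confidence JSON document (see docs/confidence_format.md)."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfidenceFormatError(f"cannot read {path}: {exc}") from exc
    if "pae" not in doc:
        raise ConfidenceFormatError(f"{path}: missing 'pae' array")
    values = np.asarray(doc["pae"], dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ConfidenceFormatError(
            f"{path}: 'pae' must be a square 2-D array, got shape {values.shape}"
        )
    chain_ids = doc.get("token_chain_ids")
    res_ids = doc.get("token_res_ids")
    if chain_ids is None or res_ids is None:
        raise ConfidenceFormatError(f"{path}: missing token_chain_ids/token_res_ids")
    if len(chain_ids) != len(res_ids):
        raise ConfidenceFormatError(f"{path}: token id lists differ in length")
    is_poly = doc.get("token_is_polymer", [True] * len(chain_ids))
    tokens = [
        Token(chain_id=str(c), residue_index=int(r), is_polymer=bool(p))
        for c, r, p in zip(chain_ids, res_ids, is_poly)
    ]
    pae = PaeMatrix(values=values, token_map=tokens)
    return ConfidenceBundle(pae=pae, ptm=doc.get("ptm"), iptm=doc.get("iptm"))


def write_confidence(bundle: ConfidenceBundle, path: str | Path) -> None:
    doc: dict = {
        "pae": bundle.pae.values.tolist(),
        "token_chain_ids": [t.chain_id for t in bundle.pae.token_map],
        "token_res_ids": [t.residue_index for t in bundle.pae.token_map],
        "token_is_polymer": [t.is_polymer for t in bundle.pae.token_map],
    }
    if bundle.ptm is not None:
        doc["ptm"] = bundle.ptm
    if bundle.iptm is not None:
        doc["iptm"] = bundle.iptm
    Path(path).write_text(json.dumps(doc))


def validate_token_coverage(pae: PaeMatrix, structure: ComplexStructure) -> None:
    """Check that the token map covers every polymer residue exactly once.

    Raises TokenMappingError naming the first uncovered residue.
    """
    index = pae.token_index()
    for key in structure.iter_polymer_residues():
        if key not in index:
            raise TokenMappingError(
                f"polymer residue {key[0]}/{key[1]} has no PAE token"
            )


# ---------------------------------------------------------------------------
# job specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolymerEntry:
    chain_id: str
    kind: str  # protein | dna | rna
    sequence: str
    unpaired_msa: Optional[str] = None
    paired_msa: Optional[str] = None
    templates: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.kind not in POLYMER_KINDS:
            raise JobSpecError(f"unknown polymer kind {self.kind!r}")
        if not self.sequence:
            raise JobSpecError(f"polymer {self.chain_id}: empty sequence")


@dataclass(frozen=True)
class LigandEntry:
    """A ligand component; count copies, one chain id per copy."""

    chain_ids: tuple[str, ...]
    ccd_codes: Optional[tuple[str, ...]] = None
    smiles: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.chain_ids) < 1:
            raise JobSpecError("ligand must have count >= 1 (at least one chain id)")
        if (self.ccd_codes is None) == (self.smiles is None):
            raise JobSpecError("ligand needs exactly one of ccd_codes or smiles")

    @property
    def count(self) -> int:
        return len(self.chain_ids)


@dataclass(frozen=True)
class IonEntry:
    chain_ids: tuple[str, ...]
    ccd_codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.chain_ids) < 1:
            raise JobSpecError("ion must have count >= 1 (at least one chain id)")
        if not self.ccd_codes:
            raise JobSpecError("ion needs a CCD/element code")

    @property
    def count(self) -> int:
        return len(self.chain_ids)


@dataclass(frozen=True)
class JobSpec:
    """A predictor job definition: sequences plus optional ligand/ion entries."""

    job_name: str
    polymers: tuple[PolymerEntry, ...]
    ligands: tuple[LigandEntry, ...] = ()
    ions: tuple[IonEntry, ...] = ()
    seed: int = 1

    def __post_init__(self) -> None:
        ids: list[str] = [p.chain_id for p in self.polymers]
        for entry in (*self.ligands, *self.ions):
            ids.extend(entry.chain_ids)
        dupes = {c for c in ids if ids.count(c) > 1}
        if dupes:
            raise JobSpecError(f"duplicate chain ids: {sorted(dupes)}")
        if not self.polymers:
            raise JobSpecError("a job needs at least one polymer sequence")


def _ids_to_json(chain_ids: tuple[str, ...]):
    return chain_ids[0] if len(chain_ids) == 1 else list(chain_ids)


def _ids_from_json(raw) -> tuple[str, ...]:
    if isinstance(raw, str):
        return (raw,)
    if isinstance(raw, list) and raw:
        return tuple(str(c) for c in raw)
    raise JobSpecError(f"invalid chain id field: {raw!r}")


def read_jobspec(path: str | Path) -> JobSpec:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise JobSpecError(f"cannot read {path}: {exc}") from exc
    return jobspec_from_dict(doc)


def jobspec_from_dict(doc: dict) -> JobSpec:
    if "name" not in doc or "sequences" not in doc:
        raise JobSpecError("job document needs 'name' and 'sequences'")
    polymers: list[PolymerEntry] = []
    ligands: list[LigandEntry] = []
    ions: list[IonEntry] = []
    for entry in doc["sequences"]:
        if len(entry) != 1:
            raise JobSpecError(f"each sequences item must have one key, got {list(entry)}")
        (key, body), = entry.items()
        if key in POLYMER_KINDS:
            polymers.append(
                PolymerEntry(
                    chain_id=body["id"],
                    kind=key,
                    sequence=body.get("sequence", ""),
                    unpaired_msa=body.get("unpairedMsa"),
                    paired_msa=body.get("pairedMsa"),
                    templates=tuple(body["templates"]) if body.get("templates") is not None else None,
                )
            )
        elif key == "ligand":
            ligands.append(
                LigandEntry(
                    chain_ids=_ids_from_json(body["id"]),
                    ccd_codes=tuple(body["ccdCodes"]) if "ccdCodes" in body else None,
                    smiles=body.get("smiles"),
                )
            )
        elif key == "ion":
            ions.append(
                IonEntry(
                    chain_ids=_ids_from_json(body["id"]),
                    ccd_codes=tuple(body["ccdCodes"]),
                )
            )
        else:
            raise JobSpecError(f"unknown sequences entry kind {key!r}")
    seeds = doc.get("modelSeeds", [1])
    if not seeds:
        raise JobSpecError("modelSeeds must be non-empty")
    return JobSpec(
        job_name=doc["name"],
        polymers=tuple(polymers),
        ligands=tuple(ligands),
        ions=tuple(ions),
        seed=int(seeds[0]),
    )


def jobspec_to_dict(spec: JobSpec) -> dict:
    sequences: list[dict] = []
    for p in spec.polymers:
        body: dict = {"id": p.chain_id, "sequence": p.sequence}
        if p.unpaired_msa is not None:
            body["unpairedMsa"] = p.unpaired_msa
        if p.paired_msa is not None:
            body["pairedMsa"] = p.paired_msa
        if p.templates is not None:
            body["templates"] = list(p.templates)
        sequences.append({p.kind: body})
    for lig in spec.ligands:
        body = {"id": _ids_to_json(lig.chain_ids)}
        if lig.ccd_codes is not None:
            body["ccdCodes"] = list(lig.ccd_codes)
        else:
            body["smiles"] = lig.smiles
        sequences.append({"ligand": body})
    for ion in spec.ions:
        sequences.append(
            {"ion": {"id": _ids_to_json(ion.chain_ids), "ccdCodes": list(ion.ccd_codes)}}
        )
    return {"name": spec.job_name, "modelSeeds": [spec.seed], "sequences": sequences}


def write_jobspec(spec: JobSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(jobspec_to_dict(spec), indent=1))
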