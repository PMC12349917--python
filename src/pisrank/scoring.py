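"""Interface-confidence scores and clash-aware ranking for one model.

Two scores are computed from the predicted-aligned-error (PAE) matrix,
both restricted to the interfacial residue set I:

* the predicted interface TM-score,

      piTM = max_{i in I} (1/|I|) * sum_{j in I} 1 / (1 + (<e_ij>/d0(|I|))^2)

  where <e_ij> is the expected error (Å) of residue j's position when
  the prediction is aligned on residue i, and the outer maximum picks
  the best aligning residue;

* the predicted interface-similarity score, a per-chain decomposition
  of piTM summed over the C polymer chains,

      pIS = sum_{p=1..C} (1/|I|) * max_{i in I \\ I_p} sum_{j in I_p}
                1 / (1 + (<e_ij>/d0(|I|))^2)

  where I_p is the interface subset on chain p. Each chain's term
  aligns on a residue *outside* that chain, so the score reflects
  cross-chain placement confidence. Both scores reach a maximum of 1
  for a perfectly confident (all-zero) PAE.

The normalisation distance d0 follows the interface TM-score
convention, piecewise in the interface size:

      d0(|I|) = 1.24 * (|I| - 15)^(1/3) - 1.8   for |I| >= 22
                0.02 * |I|                       for |I| <  22

Models are ranked by pIS minus a clash penalty large enough that any
clashing model ranks below any clash-free one; a model with an empty
interface cannot be scored by pIS and falls back to its pTM scalar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .config import RunConfig
from .errors import ScoringError, TokenMappingError
from .interface import InterfaceSet, find_interface
from .model_io import ComplexStructure, ConfidenceBundle, PaeMatrix

__all__ = [
    "ScoreReport",
    "d0",
    "pitm",
    "pis",
    "detect_clashes",
    "ranking_score",
    "native_style_ranking",
    "score_model",
]


def d0(interface_size: int) -> float:
    """Size-dependent TM-score normalisation distance in Å.

    Piecewise in the interface size |I|: the classic cube-root law for
    |I| >= 22 and a linear ramp through the origin below. Discontinuous
    at the branch point by definition; strictly positive on both
    branches.
    """
    if interface_size <= 0:
        raise ValueError(f"interface size must be positive, got {interface_size}")
    if interface_size >= 22:
        return 1.24 * (interface_size - 15) ** (1.0 / 3.0) - 1.8
    return 0.02 * interface_size


def _interface_token_indices(
    pae: PaeMatrix, interface: InterfaceSet
) -> dict[tuple[str, int], int]:
    index = pae.token_index()
    out: dict[tuple[str, int], int] = {}
    for res in interface.residues:
        if res not in index:
            raise TokenMappingError(
                f"interface residue {res[0]}/{res[1]} has no PAE token"
            )
        out[res] = index[res]
    return out


def _tm_terms(pae: PaeMatrix, idx: np.ndarray, norm: float) -> np.ndarray:
    sub = pae.values[np.ix_(idx, idx)]
    return 1.0 / (1.0 + (sub / norm) ** 2)


def pitm(pae: PaeMatrix, interface: InterfaceSet) -> float:
    """Predicted interface TM-score of one model; in (0, 1]."""
    if interface.size < 1:
        raise ScoringError("piTM is undefined for an empty interface")
    mapping = _interface_token_indices(pae, interface)
    idx = np.array([mapping[r] for r in interface.residues], dtype=int)
    terms = _tm_terms(pae, idx, d0(interface.size))
    return float(terms.sum(axis=1).max() / interface.size)


def pis(pae: PaeMatrix, interface: InterfaceSet) -> float:
    """Predicted interface-similarity score of one model; in [0, 1].

    Chains with an empty interface subset contribute 0, as do chains
    whose complement I \\ I_p is empty (a chain that owns the entire
    interface has no cross-chain residue to align on).
    """
    if interface.size < 1:
        raise ScoringError("pIS is undefined for an empty interface")
    mapping = _interface_token_indices(pae, interface)
    idx = np.array([mapping[r] for r in interface.residues], dtype=int)
    terms = _tm_terms(pae, idx, d0(interface.size))
    chains = np.array([r[0] for r in interface.residues])
    total = 0.0
    for chain in interface.by_chain:
        in_p = chains == chain
        rows = ~in_p
        if not in_p.any() or not rows.any():
            continue
        chain_sums = terms[np.ix_(rows, in_p)].sum(axis=1)
        total += float(chain_sums.max()) / interface.size
    return total


def detect_clashes(
    structure: ComplexStructure,
    clash_distance: float = 1.1,
    count_threshold: int = 100,
    fraction_threshold: float = 0.5,
) -> tuple[bool, int]:
    """Count steric clashes between heavy atoms of distinct polymer chains.

    An atom pair clashes when its distance is strictly below
    ``clash_distance``. The model is flagged as clashing when the total
    pair count exceeds ``count_threshold``, or when for some chain pair
    the count exceeds ``fraction_threshold`` of the smaller chain's
    heavy-atom count — i.e. when two chains substantially overlap.
    """
    if clash_distance <= 0:
        raise ValueError("clash_distance must be positive")
    atoms = [a for a in structure.atoms if a.is_polymer and not a.is_hydrogen]
    if len(atoms) < 2:
        return False, 0
    coords = np.array([a.xyz for a in atoms])
    tree = cKDTree(coords)
    chain_sizes: dict[str, int] = {}
    for a in atoms:
        chain_sizes[a.chain_id] = chain_sizes.get(a.chain_id, 0) + 1
    pair_counts: dict[tuple[str, str], int] = {}
    total = 0
    for i, j in tree.query_pairs(clash_distance):
        ci, cj = atoms[i].chain_id, atoms[j].chain_id
        if ci == cj:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d >= clash_distance:  # query_pairs is inclusive; clash is strict
            continue
        key = (ci, cj) if ci <= cj else (cj, ci)
        pair_counts[key] = pair_counts.get(key, 0) + 1
        total += 1
    has_clash = total > count_threshold
    for (ci, cj), count in pair_counts.items():
        smaller = min(chain_sizes[ci], chain_sizes[cj])
        if count > fraction_threshold * smaller:
            has_clash = True
    return has_clash, total


@dataclass
class ScoreReport:
    """Scores, clash status and final ranking score for one model."""

    model_id: str
    pitm: float
    pis: float
    interface_size: int
    has_clash: bool
    clash_pair_count: int
    ranking_score: float
    fallback_used: bool = False

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "pitm": self.pitm,
            "pis": self.pis,
            "interface_size": self.interface_size,
            "has_clash": self.has_clash,
            "clash_pair_count": self.clash_pair_count,
            "ranking_score": self.ranking_score,
            "fallback_used": self.fallback_used,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    TSV_HEADER = (
        "model_id\tpitm\tpis\tinterface_size\thas_clash\t"
        "clash_pair_count\tranking_score\tfallback_used"
    )

    def to_tsv_row(self) -> str:
        return (
            f"{self.model_id}\t{self.pitm:.6f}\t{self.pis:.6f}\t"
            f"{self.interface_size}\t{int(self.has_clash)}\t"
            f"{self.clash_pair_count}\t{self.ranking_score:.6f}\t"
            f"{int(self.fallback_used)}"
        )


def ranking_score(
    pis_value: Optional[float],
    has_clash: bool,
    penalty: float = 100.0,
    ptm: Optional[float] = None,
) -> tuple[float, bool]:
    """Final ranking score and whether the pTM fallback was used.

    ``pis_value=None`` signals an empty interface; the model is then
    ranked by its pTM scalar (still clash-penalised). With pIS <= 1 and
    a penalty of 100, any clashing model scores below any clash-free
    one.
    """
    if pis_value is None:
        if ptm is None:
            raise ScoringError(
                "model has no interface residues and no pTM scalar to fall back on"
            )
        base, fallback = ptm, True
    else:
        base, fallback = pis_value, False
    return base - (penalty if has_clash else 0.0), fallback


def native_style_ranking(
    iptm: float, ptm: float, has_clash: bool, penalty: float = 100.0
) -> float:
    """AlphaFold-style composite 0.8·ipTM + 0.2·pTM with clash penalty.

    Provided for comparison only; the toolkit's own ranking is pIS-based.
    """
    return 0.8 * iptm + 0.2 * ptm - (penalty if has_clash else 0.0)


def score_model(
    structure: ComplexStructure,
    bundle: ConfidenceBundle,
    config: RunConfig = RunConfig(),
) -> ScoreReport:
    """Full per-model scoring pipeline: interface → piTM/pIS → clash → rank."""
    interface = find_interface(
        structure,
        cutoff=config.interface_cutoff,
        protein_only=config.protein_only,
    )
    has_clash, n_clash = detect_clashes(
        structure,
        clash_distance=config.clash_distance,
        count_threshold=config.clash_count_threshold,
        fraction_threshold=config.clash_fraction_threshold,
    )
    if interface.size > 0:
        pitm_val = pitm(bundle.pae, interface)
        pis_val = pis(bundle.pae, interface)
        score, fallback = ranking_score(pis_val, has_clash, config.penalty)
    else:
        pitm_val = 0.0
        pis_val = 0.0
        score, fallback = ranking_score(None, has_clash, config.penalty, ptm=bundle.ptm)
    return ScoreReport(
        model_id=structure.model_id,
        pitm=pitm_val,
        pis=pis_val,
        interface_size=interface.size,
        has_clash=has_clash,
        clash_pair_count=n_clash,
        ranking_score=score,
        fallback_used=fallback,
    )
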