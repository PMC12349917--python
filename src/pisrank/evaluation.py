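"""Evaluation of predicted complexes against reference structures.

Implements the standard DockQ composite of fnat (fraction of native
5 Å heavy-atom residue contacts recovered), iRMS (backbone RMSD over
the 10 Å reference interface zone after interface superposition) and
LRMS (ligand-chain backbone RMSD after receptor superposition):

    DockQ = ( fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2) ) / 3

Scores are banded into the four conventional quality regions —
incorrect [0, 0.23), acceptable [0.23, 0.49), medium [0.49, 0.80) and
high [0.80, 1.00] — and paired score sets are compared with a
one-tailed Wilcoxon signed-rank test (exact null distribution for
small samples, normal approximation with continuity and tie
corrections otherwise).

Multi-chain complexes are evaluated per contacting reference chain
pair and combined as the interface-size-weighted mean of the per-pair
DockQ values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.stats import norm, rankdata

from .errors import AlignmentError, EvaluationError
from .model_io import AtomRecord, ComplexStructure

__all__ = [
    "SuperposeResult",
    "DockQResult",
    "BANDS",
    "band_of",
    "superpose",
    "dockq",
    "band_counts",
    "map_chains",
    "WilcoxonResult",
    "paired_wilcoxon_one_tailed",
]

FNAT_CUTOFF = 5.0  # Å, native-contact definition
INTERFACE_ZONE_CUTOFF = 10.0  # Å, iRMS interface-residue zone
IRMS_SCALE = 1.5  # Å
LRMS_SCALE = 8.5  # Å
BACKBONE_ATOMS = ("N", "CA", "C", "O")

BANDS = ("incorrect", "acceptable", "medium", "high")
_BAND_EDGES = (0.23, 0.49, 0.80)


def band_of(dockq_value: float) -> str:
    """Quality band of a DockQ value; bins are left-closed, the last closed."""
    if dockq_value < _BAND_EDGES[0]:
        return "incorrect"
    if dockq_value < _BAND_EDGES[1]:
        return "acceptable"
    if dockq_value < _BAND_EDGES[2]:
        return "medium"
    return "high"


# ---------------------------------------------------------------------------
# rigid superposition
# ---------------------------------------------------------------------------


@dataclass
class SuperposeResult:
    rotation: np.ndarray  # 3×3 proper rotation
    translation: np.ndarray  # 3-vector; transform is x -> R x + t
    rmsd: float
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, target: np.ndarray) -> SuperposeResult:
    """Least-squares rigid superposition of matched coordinate sets.

    Returns the proper rotation R and translation t minimising
    ||R·mobile + t − target|| and the resulting RMSD. Collinear inputs
    leave the rotation under-determined; the result is flagged
    degenerate but the RMSD is still valid.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise AlignmentError(
            f"coordinate sets differ in shape: {mobile.shape} vs {target.shape}"
        )
    if mobile.shape[0] < 3:
        raise AlignmentError("superposition needs at least 3 matched points")
    mob_mean = mobile.mean(axis=0)
    tgt_mean = target.mean(axis=0)
    mob_c = mobile - mob_mean
    tgt_c = target - tgt_mean
    # collinear (rank-1) point sets admit no unique optimal rotation
    degenerate = (
        np.linalg.matrix_rank(mob_c, tol=1e-8) < 2
        or np.linalg.matrix_rank(tgt_c, tol=1e-8) < 2
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot, rssd = Rotation.align_vectors(tgt_c, mob_c)
    R = rot.as_matrix()
    t = tgt_mean - R @ mob_mean
    rmsd = float(rssd) / math.sqrt(mobile.shape[0])
    return SuperposeResult(rotation=R, translation=t, rmsd=rmsd, degenerate=degenerate)


# ---------------------------------------------------------------------------
# DockQ
# ---------------------------------------------------------------------------


def _heavy_by_chain(structure: ComplexStructure) -> dict[str, list[AtomRecord]]:
    out: dict[str, list[AtomRecord]] = {}
    for a in structure.atoms:
        if a.is_polymer and not a.is_hydrogen:
            out.setdefault(a.chain_id, []).append(a)
    return out


def _residue_contacts(
    atoms_a: list[AtomRecord], atoms_b: list[AtomRecord], cutoff: float
) -> set[tuple[int, int]]:
    """Residue-index pairs (a_res, b_res) with any heavy-atom pair <= cutoff."""
    if not atoms_a or not atoms_b:
        return set()
    tree_b = cKDTree(np.array([a.xyz for a in atoms_b]))
    coords_a = np.array([a.xyz for a in atoms_a])
    contacts: set[tuple[int, int]] = set()
    for ia, neighbours in enumerate(tree_b.query_ball_point(coords_a, cutoff)):
        for ib in neighbours:
            contacts.add((atoms_a[ia].residue_index, atoms_b[ib].residue_index))
    return contacts


def _backbone_coords(
    atoms: list[AtomRecord], residues: Optional[set[int]] = None
) -> dict[tuple[int, str], np.ndarray]:
    """Backbone atom coordinates keyed by (residue_index, atom_name)."""
    out = {}
    for a in atoms:
        if residues is not None and a.residue_index not in residues:
            continue
        if a.atom_name in BACKBONE_ATOMS:
            out[(a.residue_index, a.atom_name)] = np.array(a.xyz)
    if not out:  # structures without canonical backbone names: use all heavy atoms
        for a in atoms:
            if residues is not None and a.residue_index not in residues:
                continue
            out[(a.residue_index, a.atom_name)] = np.array(a.xyz)
    return out


def _matched(
    model_map: dict, ref_map: dict
) -> tuple[np.ndarray, np.ndarray]:
    keys = sorted(set(model_map) & set(ref_map))
    if not keys:
        return np.zeros((0, 3)), np.zeros((0, 3))
    return (
        np.array([model_map[k] for k in keys]),
        np.array([ref_map[k] for k in keys]),
    )


@dataclass
class DockQResult:
    """DockQ decomposition and quality band for one model/reference pair."""

    fnat: float
    irms: float
    lrms: float
    dockq: float
    band: str
    model_id: str = ""

    TSV_HEADER = "model_id\tdockq\tfnat\tirms\tlrms\tband"

    def to_tsv_row(self) -> str:
        return (
            f"{self.model_id}\t{self.dockq:.4f}\t{self.fnat:.4f}\t"
            f"{self.irms:.3f}\t{self.lrms:.3f}\t{self.band}"
        )


def _dockq_formula(fnat: float, irms: float, lrms: float) -> float:
    return (
        fnat
        + 1.0 / (1.0 + (irms / IRMS_SCALE) ** 2)
        + 1.0 / (1.0 + (lrms / LRMS_SCALE) ** 2)
    ) / 3.0


def _pair_dockq(
    model_chains: dict[str, list[AtomRecord]],
    ref_chains: dict[str, list[AtomRecord]],
    mc_rec: str,
    mc_lig: str,
    rc_rec: str,
    rc_lig: str,
) -> Optional[tuple[DockQResult, int]]:
    """DockQ for one receptor/ligand chain pair; None when the reference
    pair has no contacts. Returns (result, interface size) for weighting."""
    ref_rec, ref_lig = ref_chains[rc_rec], ref_chains[rc_lig]
    mod_rec, mod_lig = model_chains[mc_rec], model_chains[mc_lig]

    native = _residue_contacts(ref_rec, ref_lig, FNAT_CUTOFF)
    if not native:
        return None
    model_contacts = _residue_contacts(mod_rec, mod_lig, FNAT_CUTOFF)
    fnat = len(native & model_contacts) / len(native)

    # iRMS: backbone of the 10 Å reference interface zone
    zone = _residue_contacts(ref_rec, ref_lig, INTERFACE_ZONE_CUTOFF)
    zone_rec = {r for r, _ in zone}
    zone_lig = {l for _, l in zone}
    ref_bb = {
        **{(rc_rec, k): v for k, v in _backbone_coords(ref_rec, zone_rec).items()},
        **{(rc_lig, k): v for k, v in _backbone_coords(ref_lig, zone_lig).items()},
    }
    mod_bb = {
        **{(rc_rec, k): v for k, v in _backbone_coords(mod_rec, zone_rec).items()},
        **{(rc_lig, k): v for k, v in _backbone_coords(mod_lig, zone_lig).items()},
    }
    mod_xyz, ref_xyz = _matched(mod_bb, ref_bb)
    if mod_xyz.shape[0] < 3:
        raise EvaluationError(
            f"chain pair {rc_rec}/{rc_lig}: fewer than 3 matched interface atoms"
        )
    irms = superpose(mod_xyz, ref_xyz).rmsd

    # LRMS: superpose on the receptor, measure the ligand chain
    mod_rec_xyz, ref_rec_xyz = _matched(
        _backbone_coords(mod_rec), _backbone_coords(ref_rec)
    )
    if mod_rec_xyz.shape[0] < 3:
        raise EvaluationError(f"receptor chain {rc_rec}: too few matched atoms")
    sup = superpose(mod_rec_xyz, ref_rec_xyz)
    mod_lig_xyz, ref_lig_xyz = _matched(
        _backbone_coords(mod_lig), _backbone_coords(ref_lig)
    )
    if mod_lig_xyz.shape[0] == 0:
        raise EvaluationError(f"ligand chain {rc_lig}: no matched atoms")
    moved = sup.apply(mod_lig_xyz)
    lrms = float(np.sqrt(np.mean(np.sum((moved - ref_lig_xyz) ** 2, axis=1))))

    score = _dockq_formula(fnat, irms, lrms)
    result = DockQResult(fnat=fnat, irms=irms, lrms=lrms, dockq=score, band=band_of(score))
    interface_size = len(zone_rec) + len(zone_lig)
    return result, interface_size


def _chain_signature(atoms: list[AtomRecord]) -> tuple:
    residues: dict[int, str] = {}
    for a in atoms:
        residues.setdefault(a.residue_index, a.residue_name)
    return tuple(residues[i] for i in sorted(residues))


def map_chains(
    model: ComplexStructure, reference: ComplexStructure
) -> dict[str, str]:
    """Find a model→reference chain pairing.

    Chains are grouped by residue signature (sequence of residue
    names); within each group all bijections are tried (exhaustively
    for up to 6 chains per group, greedily by contact overlap beyond
    that) and the mapping recovering the most reference contacts wins.
    Identical chain id sets short-circuit to the identity mapping.
    """
    model_chains = _heavy_by_chain(model)
    ref_chains = _heavy_by_chain(reference)
    if set(model_chains) == set(ref_chains):
        return {c: c for c in model_chains}

    mod_by_sig: dict[tuple, list[str]] = {}
    for c, atoms in model_chains.items():
        mod_by_sig.setdefault(_chain_signature(atoms), []).append(c)
    ref_by_sig: dict[tuple, list[str]] = {}
    for c, atoms in ref_chains.items():
        ref_by_sig.setdefault(_chain_signature(atoms), []).append(c)

    unmappable = [
        c
        for sig, chains in mod_by_sig.items()
        for c in chains
        if len(ref_by_sig.get(sig, [])) != len(chains)
    ]
    if unmappable:
        raise EvaluationError(f"unmappable model chains: {sorted(unmappable)}")

    best_map: dict[str, str] = {}
    for sig, mod_group in mod_by_sig.items():
        ref_group = ref_by_sig[sig]
        if len(mod_group) == 1:
            best_map[mod_group[0]] = ref_group[0]
        elif len(mod_group) <= 6:
            best_perm, best_score = None, -1.0
            for perm in itertools.permutations(ref_group):
                candidate = dict(zip(mod_group, perm))
                score = _mapping_score(model_chains, ref_chains, candidate)
                if score > best_score:
                    best_perm, best_score = candidate, score
            best_map.update(best_perm)
        else:  # greedy by contact overlap
            remaining = list(ref_group)
            for mc in mod_group:
                scored = [
                    (_mapping_score(model_chains, ref_chains, {mc: rc}), rc)
                    for rc in remaining
                ]
                scored.sort(reverse=True)
                chosen = scored[0][1]
                remaining.remove(chosen)
                best_map[mc] = chosen
    return best_map


def _mapping_score(model_chains, ref_chains, candidate: dict[str, str]) -> float:
    """Fraction of reference contacts recovered under a partial chain map."""
    total = recovered = 0
    items = list(candidate.items())
    for (mc1, rc1), (mc2, rc2) in itertools.combinations(items, 2):
        native = _residue_contacts(ref_chains[rc1], ref_chains[rc2], FNAT_CUTOFF)
        if not native:
            continue
        model = _residue_contacts(model_chains[mc1], model_chains[mc2], FNAT_CUTOFF)
        total += len(native)
        recovered += len(native & model)
    return recovered / total if total else 0.0


def dockq(
    model: ComplexStructure,
    reference: ComplexStructure,
    chain_map: Optional[dict[str, str]] = None,
) -> DockQResult:
    """DockQ of a model against its reference.

    For a two-chain complex this is the standard receptor/ligand DockQ
    (the larger chain is the receptor). Complexes with more chains are
    scored per contacting reference chain pair and combined as the
    interface-size-weighted mean; fnat/iRMS/LRMS are reported as the
    same weighted means of the per-pair values.
    """
    if chain_map is None:
        chain_map = map_chains(model, reference)
    model_chains = _heavy_by_chain(model)
    ref_chains = _heavy_by_chain(reference)
    bad = [c for c in chain_map if c not in model_chains] + [
        r for r in chain_map.values() if r not in ref_chains
    ]
    if bad or len(set(chain_map.values())) != len(chain_map):
        raise EvaluationError(f"invalid chain map (unknown or repeated chains): {chain_map}")

    inverse = {r: m for m, r in chain_map.items()}
    results: list[tuple[DockQResult, int]] = []
    for rc1, rc2 in itertools.combinations(sorted(inverse), 2):
        n1 = len({a.residue_index for a in ref_chains[rc1]})
        n2 = len({a.residue_index for a in ref_chains[rc2]})
        rc_rec, rc_lig = (rc1, rc2) if n1 >= n2 else (rc2, rc1)
        pair = _pair_dockq(
            model_chains,
            ref_chains,
            inverse[rc_rec],
            inverse[rc_lig],
            rc_rec,
            rc_lig,
        )
        if pair is not None:
            results.append(pair)
    if not results:
        raise EvaluationError("reference has no inter-chain contacts to evaluate")
    weights = np.array([w for _, w in results], dtype=float)
    weights /= weights.sum()
    fnat = float(sum(w * r.fnat for (r, _), w in zip(results, weights)))
    irms = float(sum(w * r.irms for (r, _), w in zip(results, weights)))
    lrms = float(sum(w * r.lrms for (r, _), w in zip(results, weights)))
    score = float(sum(w * r.dockq for (r, _), w in zip(results, weights)))
    return DockQResult(
        fnat=fnat,
        irms=irms,
        lrms=lrms,
        dockq=score,
        band=band_of(score),
        model_id=model.model_id,
    )


def band_counts(results: Sequence[DockQResult]) -> dict[str, int]:
    """Number of results falling in each of the four quality bands."""
    counts = {b: 0 for b in BANDS}
    for r in results:
        counts[r.band] += 1
    return counts


# ---------------------------------------------------------------------------
# paired one-tailed Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_nonzero: int
    degenerate: bool = False  # all paired differences were zero


EXACT_LIMIT = 25  # exact null distribution up to this many nonzero pairs


def _exact_sf(doubled_ranks: np.ndarray, doubled_w: int) -> float:
    """P(W+ >= w) by dynamic programming over all 2^n sign assignments.

    Ranks are doubled so tie-averaged half-integer ranks become exact
    integers; the distribution of W+ under the null (each difference
    equally likely positive or negative) is the convolution of
    independent {0, r_i} contributions.
    """
    max_sum = int(doubled_ranks.sum())
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: max_sum + 1 - r]
        counts = counts + shifted
    total = counts.sum()  # == 2^n
    return float(counts[doubled_w:].sum() / total)


def paired_wilcoxon_one_tailed(
    a: Sequence[float], b: Sequence[float]
) -> WilcoxonResult:
    """One-tailed paired Wilcoxon signed-rank test of "a tends to exceed b".

    Zero differences are discarded; ties among |differences| receive
    averaged ranks. The p-value is exact (full enumeration of the sign
    null via dynamic programming) for up to 25 nonzero pairs, and a
    normal approximation with continuity and tie corrections beyond.
    All differences zero is a degenerate comparison, reported with
    p = 1 and flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AlignmentError("paired score lists must be 1-D and equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_nonzero=0, degenerate=True)
    ranks = rankdata(np.abs(d))  # tie-averaged
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT:
        doubled = np.rint(2 * ranks).astype(int)
        p = _exact_sf(doubled, int(round(2 * w_plus)))
    else:
        mean = n * (n + 1) / 4.0
        tie_sizes = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
            ((tie_sizes**3 - tie_sizes) / 48.0).sum()
        )
        z = (w_plus - mean - 0.5) / math.sqrt(var)
        p = float(norm.sf(z))
    return WilcoxonResult(statistic=w_plus, p_value=p, n_nonzero=n)
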