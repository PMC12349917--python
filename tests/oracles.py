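"""Independent brute-force reference implementations used only by tests.

These deliberately use naive loops/enumeration and share no code with
the production implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import rankdata


def naive_d0(n: int) -> float:
    return 1.24 * (n - 15) ** (1 / 3) - 1.8 if n >= 22 else 0.02 * n


def naive_pitm(values, token_index, residues) -> float:
    """Triple-loop interface TM-score: max over aligning residue i."""
    n = len(residues)
    norm = naive_d0(n)
    best = -math.inf
    for i in residues:
        total = 0.0
        for j in residues:
            e = values[token_index[i]][token_index[j]]
            total += 1.0 / (1.0 + (e / norm) ** 2)
        best = max(best, total / n)
    return best


def naive_pis(values, token_index, residues, by_chain) -> float:
    """Per-chain decomposition: each chain's term aligns outside the chain."""
    n = len(residues)
    norm = naive_d0(n)
    total = 0.0
    for chain, members in by_chain.items():
        outside = [r for r in residues if r[0] != chain]
        if not members or not outside:
            continue
        best = -math.inf
        for i in outside:
            s = 0.0
            for j in members:
                e = values[token_index[i]][token_index[j]]
                s += 1.0 / (1.0 + (e / norm) ** 2)
            best = max(best, s)
        total += best / n
    return total


def allpairs_interface(structure, cutoff: float) -> set:
    """O(n^2) scan over all heavy polymer atom pairs across chains."""
    atoms = [a for a in structure.atoms if a.is_polymer and not a.is_hydrogen]
    members = set()
    for a, b in itertools.combinations(atoms, 2):
        if a.chain_id == b.chain_id:
            continue
        d = math.dist(a.xyz, b.xyz)
        if d <= cutoff:
            members.add((a.chain_id, a.residue_index))
            members.add((b.chain_id, b.residue_index))
    return members


def allpairs_clash_count(structure, clash_distance: float) -> int:
    atoms = [a for a in structure.atoms if a.is_polymer and not a.is_hydrogen]
    count = 0
    for a, b in itertools.combinations(atoms, 2):
        if a.chain_id != b.chain_id and math.dist(a.xyz, b.xyz) < clash_distance:
            count += 1
    return count


def enumerate_wilcoxon_p(diffs) -> tuple[float, float]:
    """Exact one-tailed signed-rank p by enumerating all 2^n sign patterns.

    Returns (W+ of the observed differences, P(W+ >= observed)).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    observed = float(ranks[d > 0].sum())
    at_least = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if w >= observed - 1e-12:
            at_least += 1
    return observed, at_least / 2**n
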