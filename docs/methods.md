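# Methods

This note records what `pisrank` computes, the parameters it uses and
why, the scope of the synthetic data generator, numerical choices, and
known limitations. Notation: a complex has chains p = 1..C; ⟨e_ij⟩ is
the predicted aligned error of residue j under alignment on residue i.

## 1. Interface definition

A polymer residue is **interfacial** if any of its heavy (non-hydrogen)
atoms lies within `interface_cutoff` of a heavy atom belonging to a
different polymer chain. The boundary is inclusive (distance exactly
equal to the cutoff counts). Ligands and ions never create interface
residues: they are excluded both as sources and as partners, so a
protein residue touching only a ligand is not interfacial. With
`protein_only=True`, chains that contain no CA atoms (nucleic acids,
in practice) are excluded as well.

*Default cutoff 4.5 Å* — the conventional heavy-atom contact distance
of the interface-TM-score lineage of metrics; exposed in `RunConfig`
rather than hard-coded.

Implementation: one `scipy.spatial.cKDTree` over all heavy atoms,
`query_pairs(r=cutoff)` with the inclusive boundary checked explicitly;
verified against an all-pairs O(n²) scan in the tests.

## 2. Confidence scores

Let I be the interface residue set, I_p its restriction to chain p,
and n = |I|. Each polymer residue corresponds to one PAE token (the
token map in the confidence file is authoritative; a structure residue
with no token is an error, not a silent skip).

**d0 normalisation** (TM-score family, re-based on interface size):

    d0(n) = 1.24·(n − 15)^(1/3) − 1.8   for n ≥ 22
    d0(n) = 0.02·n                       for n < 22

The function is implemented exactly as printed, including the jump
discontinuity at n = 22 (d0(21) = 0.42, d0(22) ≈ 0.575). We do not
smooth it: downstream consumers expect the published form.

**piTM** scans alignment frames i over the whole interface:

    piTM = max_{i∈I} (1/n) Σ_{j∈I} 1 / (1 + (⟨e_ij⟩/d0(n))²)

The inner sum includes the self term j = i, so piTM ≥ 1/n > 0. The
source formulation indexes the inner sum by an otherwise-undefined set
J; we take J = I, which makes piTM a strict interface-restriction of
the pTM construction and gives piTM = 1 exactly when the PAE vanishes
on I×I.

**pIS** scores each chain's interface patch from the best frame
*outside* that chain:

    pIS = Σ_{p=1}^{C} (1/n) max_{i∈I∖I_p} Σ_{j∈I_p} 1 / (1 + (⟨e_ij⟩/d0(n))²)

Since the I_p partition I, pIS ∈ [0, 1] and equals 1 iff every
cross-chain frame is perfectly confident about every other chain's
interface residues. If I∖I_p is empty for some chain (cannot happen
when I comes from `find_interface`, which only ever produces residues
with a cross-chain partner) the chain contributes zero.

PAE matrices are used asymmetrically: ⟨e_ij⟩ is read as row i
("aligned on"), column j ("error of"), matching the predictor's
convention. Both scores are evaluated with vectorised submatrix
operations on the term matrix 1/(1+(e/d0)²) and are tested to 1e−12
against naive triple-loop oracles.

## 3. Clash detection and ranking

Heavy-atom pairs on different polymer chains at distance strictly
below `clash_distance` (default 1.1 Å) count as clashes. A model
`has_clash` if the total count exceeds `clash_count_threshold`
(default 100), or if for some chain pair the count exceeds
`clash_fraction_threshold` (default 0.5) times the heavy-atom count of
the smaller chain of the pair. These constants follow the convention
of the AlphaFold-style ranking pipelines; they are deliberate
conventions, not fitted values, and all are configurable.

The **ranking score** is

    R = pIS − P·[has_clash],          P = 100 by default,

so any clash-free model outranks any clashing one regardless of pIS.
When the interface is empty (pIS undefined) the model falls back to
the global pTM scalar, and the report flags `fallback_used` so
consumers can tell the two regimes apart; fallback with no pTM
available is an error. Ties in R break by piTM, then model id, making
ranking deterministic. A `native_style_ranking` helper
(0.8·ipTM + 0.2·pTM − P·[has_clash]) is provided for comparison with
predictor-default ordering.

## 4. Dual-branch selection and job transforms

For jobs containing ligands or ions, two prediction branches are
compared: the original job ("with") and a stripped one ("without").
`strip_ligands_ions` removes all ligand and ion entries and suffixes
the job name with `_apo` (once — the transform is idempotent);
`strip_paired_msa` blanks each polymer's paired MSA while keeping
unpaired MSAs and templates. The transforms commute and touch nothing
else.

`decide_branch` takes the best-ranked model of each branch (by R) and
chooses the branch with the higher ranking score — i.e. the comparison
is clash-penalised, not raw pIS, so a branch whose best model clashes
cannot win on confidence alone. Exact ties go to "with" (keeping the
user's declared inputs is the conservative default). The decision
records both scores and the margin.

`audit_decisions` cross-tabulates recorded decisions against reference
DockQ values at a series of margin thresholds t: a pair qualifies when
|DockQ_with − DockQ_without| ≥ t, and the audit reports how often the
chosen branch was the truly better one, plus the mean absolute DockQ
gain among qualifying cases (None when nothing qualifies).

## 5. Evaluation (DockQ)

For a model/reference chain pair with receptor = larger chain:

* **fnat** — fraction of reference interface contacts (heavy-atom
  pairs ≤ 5 Å across the pair) preserved in the model;
* **iRMS** — backbone (N, CA, C, O) RMSD over the reference 10 Å
  interface zone after superposing on that zone;
* **LRMS** — ligand-chain backbone RMSD after superposing on the
  receptor;
* **DockQ** = (fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²)) / 3.

Chains without backbone atoms fall back to all heavy atoms.
Superposition is Kabsch via `scipy.spatial.transform.Rotation.align_vectors`
(RMSD = rssd/√n); coordinate sets of rank < 2 are flagged degenerate.

Quality bands are left-closed: incorrect [0, 0.23), acceptable
[0.23, 0.49), medium [0.49, 0.80), high [0.80, 1.00]. For multi-chain
complexes the reported DockQ is the mean over contacting reference
chain pairs weighted by interface-zone residue count, so large
interfaces dominate, matching the intuition that a complex is as good
as its load-bearing interfaces. Chain correspondence defaults to
identity when the id sets match; otherwise chains are grouped by
signature (length/composition) and matched exhaustively within small
groups (≤ 6) or greedily beyond.

## 6. Paired one-tailed Wilcoxon signed-rank test

Used to compare paired per-target DockQ (or score) samples, testing
H1: sample A > sample B. Zero differences are dropped; ties among
|differences| receive averaged ranks. For n ≤ 25 retained pairs the
null distribution is computed **exactly** by dynamic-programming
convolution over doubled ranks (doubling makes tie-averaged ranks
integral, so the DP stays exact — this is why we do not use scipy's
exact mode, which refuses ties). Beyond 25 pairs a normal
approximation is used with mean n(n+1)/4, tie-corrected variance
n(n+1)(2n+1)/24 − Σ(t³−t)/48, and a 0.5 continuity correction. The
all-zero-difference case returns p = 1 with a `degenerate` flag rather
than an error. `scipy.stats.wilcoxon` is used in the tests as an
independent cross-check of both branches, and the exact branch is
additionally checked against full 2ⁿ sign-flip enumeration.

## 7. Synthetic fixture generator

All test data is generated, text-only, and deterministic per seed.
Chains are straight four-atom-per-residue strands (N, CA, C, O;
pitch 4.5 Å along x, small z zig-zag) stacked along y so that the
minimum inter-chain heavy-atom distance is *exactly* the configured
gap — the default 4.4 Å sits just inside the 4.5 Å cutoff and makes
every residue of adjacent chains interfacial. PAE modes: `ZeroPae`
(identically 0), `UniformPae(lo, hi)` (i.i.d. uniform, zero diagonal),
`PlantedPae(interface_err, core_err)` (confident within chains,
configurable cross-chain error). Decoys rotate the last chain about z
through its centroid and translate it along +y, giving a controllable
quality ladder. Fixture bundles carry ptm/ipTM scalars so that
interface-free decoys remain rankable via the fallback.

These geometries are idealisations: passing tests demonstrates
correctness of the *computations* (score algebra, interface logic,
superposition, test statistics) on controlled inputs, not predictive
performance on real complexes. Problem sizes exercised: 2–4 chains,
2–60 residues per chain, interfaces up to ~60 residues, Wilcoxon
samples up to a few hundred pairs.

## 8. Numerical choices and limitations

* Scores are computed in float64; oracle agreement is asserted to
  1e−12 absolute. Superposition accuracy is limited by
  `align_vectors` to ~1e−7, so geometric assertions use 1e−6.
* The first model of a multi-model file is used; altlocs resolve to
  the highest-occupancy conformer; residues are re-indexed 1..k per
  chain in file order.
* One PAE token per polymer residue is assumed (standard-residue
  tokenisation); modified residues tokenised per-atom are out of
  scope.
* Chain mapping beyond 6 interchangeable chains per signature group is
  greedy, not exhaustive, and may be suboptimal for highly symmetric
  assemblies.
* `has_clash` thresholds and the penalty P are conventions with no
  fitted basis; results at other settings are governed by the same
  code paths but are not characterised here.
* No empirical performance claims (e.g. benchmark DockQ distributions
  on real targets) are made anywhere in this repository; everything
  asserted is computed by the shipped code on generated inputs.
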