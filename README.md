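# pisrank

Interface-confidence scoring, clash-aware model ranking and DockQ
evaluation for predicted biomolecular complexes.

Structure predictors of the AlphaFold family emit, alongside each
candidate complex structure, an N×N **predicted aligned error** (PAE)
matrix: entry ⟨e_ij⟩ estimates the positional error (Å) of residue *j*
when the prediction is aligned on residue *i*. The default whole-chain
confidence scalars (pTM/ipTM) average over entire chains, diluting the
signal that matters most for complexes — whether the *interfaces* are
right. `pisrank` implements the interface-restricted alternative and
the downstream machinery built around it, for people who run such
predictors and need to pick the best model out of many, decide whether
ligand/ion inputs helped or hurt, and benchmark the results.

## The scores

Let *I* be the set of interfacial residues (any heavy atom within
4.5 Å of a heavy atom on another polymer chain), partitioned per chain
into the sets *I_p*. The **predicted interface TM-score** is

    piTM = max_{i∈I} (1/|I|) Σ_{j∈I} 1 / (1 + (⟨e_ij⟩ / d0(|I|))²)

with the size-dependent normalisation

    d0(|I|) = 1.24·(|I|−15)^⅓ − 1.8   if |I| ≥ 22
            = 0.02·|I|                 if |I| < 22

The **predicted interface-similarity score** decomposes piTM per
chain, aligning each chain's interface residues on a residue *outside*
that chain:

    pIS = Σ_{p=1..C} (1/|I|) max_{i∈I∖I_p} Σ_{j∈I_p} 1 / (1 + (⟨e_ij⟩ / d0(|I|))²)

Both scores live in [0, 1] and reach 1 exactly under perfect
confidence (PAE ≡ 0). Models are ranked by pIS minus a large clash
penalty, so a model with substantially overlapping chains can never
outrank a clash-free one.

Around the scores, the toolkit provides:

* mmCIF/PDB structure IO, confidence-JSON and job-specification IO
  (`pisrank.model_io`, structures via gemmi);
* interface detection with a brute-force-verified spatial index
  (`pisrank.interface`);
* the dual-branch ligand decision — rerun the predictor with ligands
  and ions stripped, keep whichever branch's best model scores higher —
  plus the job transforms that prepare the second branch
  (`pisrank.selection`);
* DockQ evaluation against references with the standard quality bands
  (incorrect < 0.23 ≤ acceptable < 0.49 ≤ medium < 0.80 ≤ high) and a
  paired one-tailed Wilcoxon signed-rank comparison, exact for small
  samples (`pisrank.evaluation`);
* a deterministic synthetic-fixture generator (`pisrank.fixtures`) and
  a CLI (`pisrank score|rank|decide|prep|eval|simulate`).

## Worked example

Generate a synthetic dimer whose PAE is confident within chains but
uncertain across them ("planted" mode), and score it:

```sh
$ pisrank simulate demo --seed 7 --pae-mode planted
$ pisrank score demo/model.cif demo/confidence.json
{"model_id": "model", "pitm": 0.11670140868401002, "pis": 0.00042004193397792106,
 "interface_size": 10, "has_clash": false, "clash_pair_count": 0,
 "ranking_score": 0.00042004193397792106, "fallback_used": false}
```

The ten interface residues (five per chain) give d0 = 0.2 Å, so the
planted ~10 Å cross-chain errors crush the pIS to nearly zero: this
model's interface placement is not to be trusted, and in a ranked set
it would fall below any model whose cross-chain errors are small. With
a perfectly confident (all-zero) PAE the same geometry scores
`"pis": 1.0`. To prepare the ligand-free second prediction branch from
an existing job document:

```sh
$ pisrank prep demo/job.json --strip-paired-msa --strip-ligands -o demo/job_apo.json
```

which blanks every polymer's paired MSA, drops all ligand/ion entries
and suffixes the job name with `_apo`, leaving sequences, unpaired
MSAs and templates untouched for feature reuse.

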