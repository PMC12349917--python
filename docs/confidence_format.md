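# Input JSON dialects

## Confidence file

`read_confidence` / `write_confidence` use a single JSON object:

```json
{
  "pae": [[0.0, 3.1], [2.9, 0.0]],
  "token_chain_ids": ["A", "B"],
  "token_res_ids": [1, 1],
  "token_is_polymer": [true, true],
  "ptm": 0.8,
  "iptm": 0.75
}
```

| key | required | meaning |
| --- | --- | --- |
| `pae` | yes | square N×N matrix of non-negative finite floats, in Å. Entry `[i][j]` is the predicted error of token j when aligned on token i (rows = alignment frame). Asymmetry is expected and preserved. |
| `token_chain_ids` | yes | length-N list; chain id of each token, same order as the matrix axes. |
| `token_res_ids` | yes | length-N list of 1-based residue indices within the chain. |
| `token_is_polymer` | no | length-N booleans; defaults to all true. Non-polymer tokens (ligands, ions) are carried but never enter interface scoring. |
| `ptm` / `iptm` | no | global scalars in [0, 1]. `ptm` is the empty-interface ranking fallback. |

Validation: the matrix must be square and match the token-list
lengths; negative or non-finite entries, out-of-range scalars, or
duplicate (chain, residue) polymer tokens raise
`ConfidenceFormatError`. `validate_token_coverage` additionally checks
that every polymer residue of a structure has a token
(`TokenMappingError` names the first missing residue as `chain/index`).

Exactly one token per polymer residue is assumed; per-atom
tokenisation of modified residues is not supported.

## Job specification file

`read_jobspec` / `write_jobspec` use the AlphaFold 3 input dialect
(subset):

```json
{
  "name": "job1",
  "modelSeeds": [1],
  "sequences": [
    {"protein": {"id": "A", "sequence": "GAAAA",
                 "unpairedMsa": ">query\nGAAAA\n", "pairedMsa": ">query\nGAAAA\n",
                 "templates": []}},
    {"ligand": {"id": ["L1", "L2"], "ccdCodes": ["HEM"]}},
    {"ion": {"id": "Z", "ccdCodes": ["MG"]}}
  ]
}
```

* Polymer kinds: `protein`, `dna`, `rna`. MSA/template fields are
  optional and round-trip unchanged.
* `ligand`/`ion` entries take `ccdCodes` (list) or `smiles`
  (exclusive); `id` may be a string or a list of strings — the list
  length is the copy count (there is no separate count field in this
  dialect).
* Chain ids must be unique across the whole document; the first entry
  of `modelSeeds` is exposed as `JobSpec.seed`.

Malformed documents raise `JobSpecError` with the offending key.
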