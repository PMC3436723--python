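# nplikeness

Natural-product-likeness scoring of small molecules.

Natural products — small molecules made by living organisms — occupy a
distinctive region of chemical space: sp3-rich, oxygen-rich, stereocentre-dense
scaffolds, quite unlike the flat halogenated aromatics that dominate synthetic
screening collections. *NP-likeness* quantifies how natural-product-like a
molecule is, which makes it useful for ranking compound libraries, picking
leads that mimic metabolites, and filtering candidate structures in
computer-assisted structure elucidation.

The score is fragment-based and fully interpretable. Every heavy atom of a
molecule is described by a **circular atom signature**: a canonical string for
the subgraph within a fixed bond radius (*height*, default 2) of that atom.
Given a natural-product corpus and a synthetic-molecule corpus, each fragment
*i* contributes a log-ratio of document frequencies

```
fragment_i = ln( (NP_i + α) / (SM_i + α) · SM_t / NP_t )
```

where `NP_i` / `SM_i` count the corpus molecules containing the fragment,
`NP_t` / `SM_t` are the corpus sizes, and `α` (default 1) is a pseudo-count
that keeps fragments seen in only one corpus finite. A query molecule's score
is the sum of its per-atom fragment contributions divided by its number of
atoms *N*:

```
score = ( Σ_i fragment_i ) / N
```

Positive means natural-product-like, negative means synthetic-like; on typical
corpora scores span roughly −3 to +3. Because the model is just a pair of
fragment-frequency tables, the *reason* for any score can be read off directly
— and the highest-scoring fragments can be decoded back into structures for
use in fragment-based design.

## Workflow

The `nplikeness` command chains five stages; every intermediate is a plain
text file (SDF, SMILES, or tab-separated tables), so stages can be cached and
re-run independently.

1. **curate** — tag each molecule with a UUID, strip disconnected fragments
   below 6 heavy atoms (counter-ions, solvates), discard molecules containing
   elements outside C, H, N, O, P, S, F, Cl, Br, I, As, Se, B, and remove
   glycosidically bound sugars so the score reflects the aglycone scaffold.
   Fragments split from one parent keep its UUID and are scored as one
   molecule.
2. **sign** — write one atom signature per heavy atom, tagged by UUID.
3. **train** — build the paired document-frequency indexes from a
   natural-product and a synthetic signature file.
4. **score** — score query signature files; optionally decode the top-*k*
   fragments to an SDF with their scores.
5. **plot** — overlay kernel-density estimates of score sets as a PDF.

## Worked example

Using the built-in seeded fixture generator (NP-like vs synthetic-like demo
corpora — see `docs/methods.md` for what these emulate):

```console
$ nplikeness fixtures --seed 42 --n-np 200 --n-sm 200 -o fix
wrote 200 NP-like, 200 synthetic-like and 6 edge-case molecules to fix
$ nplikeness curate -i fix/np.smi -o np_kept.sdf --uuid-seed 1
kept 200 molecule(s) (200 fragment record(s)), discarded 0
$ nplikeness sign -i np_kept.sdf -o np_sigs.tsv --height 2
wrote 3046 signature(s) for 200 molecule(s)
$ # ... same for sm.smi ...
$ nplikeness train --np np_sigs.tsv --sm sm_sigs.tsv -o model.npl
trained on 200 NP / 200 SM molecules (421 / 326 fragments)
$ nplikeness score -m model.npl -q np_sigs.tsv -o np_scores.tsv \
      --fragments-out frags.sdf --top-k 10
scored 200 molecule(s)
wrote 10 fragment structure(s)
$ head -3 np_scores.tsv
cd613e30-d8f1-4adf-91b7-584a2265b1f5	2.471828
1e2feb89-414c-443c-9027-c4d1c386bbc4	3.253100
78e51061-7311-48a3-82ce-6f447ed4d57b	3.498747
$ head -3 sm_scores.tsv
d95bafc8-f2a4-427b-9cf4-bb99f4bea973	-2.377741
5c6e4337-15ba-4bdd-9772-19d30e7a269f	-3.751443
cf1822ff-bc68-4778-ab49-1044d5e34124	-2.539881
$ nplikeness plot -s natural=np_scores.tsv -s synthetic=sm_scores.tsv -o density.pdf
wrote density plot for 2 set(s) to density.pdf
```

The NP-like molecules score strongly positive, the synthetic-like ones
strongly negative: the two density curves barely overlap. The same pipeline
is available as a library (`nplikeness.curate`, `sign_batch`, `train`,
`score_molecules`, …); signature files look like

```
cd613e30-d8f1-4adf-91b7-584a2265b1f5	[C](-[O](-[C]))
cd613e30-d8f1-4adf-91b7-584a2265b1f5	[O](-[C]-[C](-[C]))
```

with the signature grammar documented in `docs/methods.md`.

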