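# sutura

Cranial **suture contact coding**, **phenetic similarity**, and
**morphological parsimony** for turtle-skull comparative studies.

CT imaging makes it possible to see not just *which* skull bones touch,
but *how*: the spatial relation of the two bones in cross section
(parallel `p`, overlapping `o` / underlying `u`, clasping `c` /
clasped-by `cb`, vertically transverse `t`) and the depth of the suture
on an ordinal four-step scale (smooth `s`, faintly `if`, moderately `im`,
strongly `is` interfingering).  This package implements that coding
scheme and the analyses built on it, for workers comparing skull
osteology across fossil and living taxa:

* **Contact tables** — typed records of bone-pair contacts (present /
  absent / unknown, with anterior-to-posterior segment lists), a long-TSV
  interchange format, canonicalization of the direction-dependent codes
  (`A o B` ⇔ `B u A`), and validation.
* **Phenetic similarity** — for two taxa, the percentage of comparable
  bone pairs whose contacts are similar.  Segments are similar when the
  spatial relation matches and the suture depth differs by **less than
  two** ordinal categories: `S(A,B) = round(100 · n_sim / n_comp)`.
  Every unstated rule (denominator, unknown depths, multi-segment
  contacts, excluded bones) is an explicit `SimilarityPolicy` field.
* **Synthetic data** — contact tables evolved on random trees by Poisson
  gain/loss, relation-switch and ±1 depth-step events, plus an Mk-like
  simulator of discrete character matrices; both seeded and
  byte-reproducible.
* **Matrix assembly** — NEXUS/TNT I/O; insertion of newly defined
  characters at stated positions with automatic renumbering; a
  ten-entry recoding patch for *Desmatochelys lowii* guarded by the
  expected previous states; ordered (morphocline) flags for the built-in
  37-character list; taxon deactivation.
* **Parsimony** — tree length with unordered (Fitch) and ordered
  (Sankoff, cost `|i−j|`) characters, missing/gap and polymorphic cells;
  `CI = Σmᵢ/L` and `RI = (Σgᵢ−L)/(Σgᵢ−Σmᵢ)`; exhaustive enumeration for
  small problems; random-addition + TBR heuristic search honouring a
  backbone constraint; strict consensus; taxon pruning.

The packaged study fixture (`sutura.study_fixture()`) is a row-by-row
transcription of the published contact observations for the Cretaceous
protostegid *Desmatochelys lowii* (KUVP 1200) and three living turtles
(*Eretmochelys imbricata*, *Dermochelys coriacea*, *Chelydra
serpentina*); the fossil's suture depths are largely `?` because matrix
and crushing obscure them.

## Worked example

```sh
python examples/similarity_from_fixture.py
```

prints (abbreviated):

```
Similarity (%), nasal contacts excluded:
                         Desm  Eret  Derm  Chel
Desmatochelys_lowii       -     18    18    21
Eretmochelys_imbricata    18    -     9     11
Dermochelys_coriacea      18    9     -     18
Chelydra_serpentina       21    11    18    -

Comparable bone pairs per taxon pair (the denominators):
  Desmatochelys_lowii    vs Eretmochelys_imbrica     7/38
  ...
```

Each cell is the share of bone pairs scored in both taxa whose contacts
are similar under the default policy; the counts file shows the exact
numerators and denominators behind every percentage, so any cell can be
audited against the fixture rows.  Because this fixture is transcribed
from narrative descriptions rather than the study's own coding tables,
its absolute percentages are lower than the published ones — the prose
records far more segment-level detail (and occasional internal
disagreement) than tabulated codes do; see `docs/methods.md` for the
analysis.

Other examples: `examples/simulate_contact_evolution.py` (similarity
decays with tree path length), `examples/assemble_matrix.py` (the
154 × 263 matrix build with renumbering and the guarded recoding patch),
`examples/parsimony_search.py` (constrained search, consensus, CI/RI).

A thin CLI mirrors the library:

```sh
sutura similarity --contacts table.tsv --out results/
sutura simulate --taxa 8 --pairs 50 --seed 42 --out tips.tsv --tree tree.nwk
sutura matrix --in base.nex --add-table3 --recode-dlowii --ordered-builtin --out final.tnt
sutura pscore --matrix final.tnt --tree tree.nwk
sutura psearch --matrix final.tnt --reps 100 --seed 1 --constraint backbone.nwk --out mpts.nwk
```

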