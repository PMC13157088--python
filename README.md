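# redoxpair

Screen protein structures for proximal cysteine pairs and score their
likelihood of forming **redox-active disulphides** — reversible S–S bonds
whose formation and reduction switch protein conformation or function.

Redox-regulated disulphides are hard to find experimentally: they are
transient, often substoichiometric, and invisible to most chemoproteomic
screens because a thiol locked in a disulphide cannot be engaged by an
electrophilic probe. `redoxpair` is aimed at structural biologists and
covalent-drug hunters who want to triage candidate cysteine pairs directly
from deposited structures: it finds every pair of cysteine Sγ atoms within
10 Å, characterises each pair with five structural descriptors, and ranks
pairs with a trainable composite score.

## The score

For candidate pair *k* with descriptors *x<sub>ik</sub>*:

* Sγ–Sγ distance (Å),
* % buried (complement of relative solvent accessibility, Shrake–Rupley
  SASA against a Gly-X-Gly reference state, averaged over the two
  cysteines),
* total half-sphere exposure (neighbouring residues by Cα within 12 Å,
  split about the Cα→Cβ plane, summed over the pair),
* minimum predicted thiol pK<sub>a</sub> (pluggable PROPKA3-style engine or
  a deterministic lookup table),
* mean crystallographic B-factor over the pair's heavy atoms,

each descriptor receives a Spearman correlation *r<sub>i</sub>* with the
class label of a training set of known redox-active (positive) and inert
(negative) pairs. Descriptors with pairwise |ρ| ≥ 0.80 are grouped; within a
group, weights *w<sub>i</sub>* are proportional to descriptor variance and
sum to 1 (ungrouped descriptors have *w<sub>i</sub>* = 1). The raw score

&nbsp;&nbsp;&nbsp;&nbsp;*S<sub>k</sub>* = Σ<sub>i</sub> *w<sub>i</sub> r<sub>i</sub> x<sub>ik</sub>*

is min–max normalised over the scored set to a 0–100 **redox score**:

&nbsp;&nbsp;&nbsp;&nbsp;RedoxScore<sub>k</sub> = 100 · (*S<sub>k</sub>* − *S*<sub>min</sub>) / (*S*<sub>max</sub> − *S*<sub>min</sub>).

Pairs observed in several structures are de-duplicated onto canonical
(UniProt-style) residue numbering — assigned by exact flanking-window
matching against reference sequences — keeping the structure with the
shortest thiol separation. Chemoproteomic ligandability tables
(accession + canonical residue + compounds) can be joined onto the scored
pairs to ask which predicted redox switches are already covalently
druggable.

## Worked example

```python
import redoxpair as rp
from redoxpair import fixtures

# a synthetic interchain cystine: two chains, SSBOND record, S-S at 2.05 A
s = fixtures.make_disulphide_structure()
(pair,) = rp.scan_pairs(s)
print(pair.sg_distance, pair.topology, pair.disulphide_bound)
# 2.05 intermolecular True

# fit the score on a synthetic labelled training library (20 pos / 20 neg)
train = fixtures.make_training_set(effect_profile="strong", seed=1)["training"]
feats = list(rp.DESCRIPTOR_NAMES)
model = rp.fit_score_model(train[feats + ["label"]])
print(model.r)     # {'sg_distance': -0.77, 'pct_buried': -0.87,
                   #  'hse_total': -0.83, 'min_pka': -0.87, 'avg_b': 0.81}
print(model.groups)  # [['sg_distance'], ['pct_buried', 'hse_total'],
                     #  ['min_pka'], ['avg_b']]
scored = rp.score_dataset(model, train[feats])
```

The fitted correlations recover the generating directions — positives have
shorter thiol separations, lower burial/exposure counts, lower minimum
pK<sub>a</sub> and higher B-factors — and % buried groups with HSE total
(|ρ| ≥ 0.8), sharing one variance-weighted slot. On this training set the
redox score separates the classes completely: positives span 61.8–100.0,
negatives 0.0–36.4.

The same pipeline runs from the shell:

```sh
redoxpair fixtures --outdir demo --seed 7          # synthetic inputs
redoxpair scan demo/structures -o demo/pairs.tsv
redoxpair map demo/pairs.tsv --refs demo/references.fasta -o demo/canonical.tsv
redoxpair descriptors demo/canonical.tsv --structures demo/structures \
    --pka-table demo/pka_table.tsv -o demo/descriptors.tsv
redoxpair fit demo/training.tsv -o demo/model.json
redoxpair score demo/descriptors.tsv --model demo/model.json -o demo/scored.tsv
redoxpair annotate demo/scored.tsv --ligandability demo/ligandability.tsv \
    --model demo/model.json -o demo/annotated.tsv
redoxpair evaluate --training demo/training.tsv --annotated demo/annotated.tsv \
    -o demo/stats.tsv
```

With network access, `rp.fetch_structure("2IW2")` pulls the human prolidase
(PEPD) homodimer whose interchain C58–C158 pair is a characterised
redox-regulated disulphide with a predicted thiol pK<sub>a</sub> near 5.

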