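# Methods

## Problem and model

Reversible disulphides form between cysteine thiols that are already close
in the folded structure. The package screens deposited structures for every
unordered pair of cysteine Sγ atoms strictly closer than a threshold
(default 10 Å), and summarises each pair with five descriptors chosen to
track the physical prerequisites of redox-dependent bond formation:
geometric proximity (Sγ–Sγ distance), solvent accessibility (% buried and
half-sphere exposure — a buried, tightly packed pair has little room for
the conformational change a redox switch requires), thiol reactivity
(minimum predicted pK<sub>a</sub>: a low pK<sub>a</sub> thiolate is the
oxidation-susceptible species at physiological pH), and conformational
heterogeneity (crystallographic B-factor: a mixed population of bonded and
unbonded states inflates apparent displacement).

The composite is a weighted rank-correlation score. On a labelled training
set (positive = pair with demonstrated redox-dependent disulphide,
negative = pair in the same protein class unable to form one), each
descriptor *x<sub>i</sub>* gets a tie-corrected Spearman correlation
*r<sub>i</sub>* with the 0/1 label. Descriptors whose pairwise |ρ| reaches
0.80 are grouped (connected components of the correlation graph); within a
group weights are variance-proportional and sum to one, so a group of
redundant burial measures contributes like a single descriptor; singletons
have weight 1. The raw score S<sub>k</sub> = Σ w<sub>i</sub> r<sub>i</sub>
x<sub>ik</sub> is min–max normalised over the scored candidate set to a
0–100 percentage, then those bounds are frozen for incremental scoring
(out-of-range later pairs clamp to 0/100).

## Numerical and design choices

* **Descriptor pre-scaling.** Raw descriptor units differ by orders of
  magnitude (Å vs % vs Å²); applying variance-proportional weights to raw
  values would let the B-factor column dominate. Descriptors are therefore
  min–max scaled to [0, 1] on their training ranges before correlation,
  weighting and summation. Spearman correlations are unchanged by this
  monotone map; the choice is recorded in the persisted model and a raw
  mode is available (`scale_descriptors=False`).
* **Duplicate-robust weights.** Within a group, columns that are identical
  after scaling share one variance slot, split equally. This makes the raw
  score exactly invariant to duplicating any descriptor column — without
  it, a duplicated column would double-claim its group's weight.
* **Missingness.** Missing descriptor values (unresolved atoms, pKa engine
  failure) are median-imputed with audit flags, never silently zeroed or
  dropped; constant columns get r = 0 and are flagged.
* **Screen thresholds.** Strict `<` at the 10 Å screen. A pair counts as
  disulphide-bound when its Sγ separation is ≤ 2.5 Å (covalent S–S ≈
  2.05 Å plus slack) or a declared SSBOND/struct_conn record names it.
* **Half-sphere exposure.** Cβ-based: neighbours are Cα atoms of all other
  polymer residues strictly within 12 Å of the site's Cα; the dividing
  plane passes through Cα perpendicular to Cα→Cβ, with the standard
  −120° rotation pseudo-Cβ for residues lacking one; a neighbour exactly in
  the plane counts "down". Pair aggregation: HSE counts are summed over the
  two cysteines, % buried is averaged, B is averaged over all heavy atoms
  of both residues (alternatives are a config choice).
* **% buried.** Shrake–Rupley SASA (probe 1.4 Å, 960-point deterministic
  Fibonacci sphere, element-based radii) of the cysteine's heavy atoms in
  full structure context, divided by the Gly-Cys-Gly theoretical maximum
  ASA of 167 Å² (Tien et al. 2013); burial is the clamped complement.
* **pK<sub>a</sub> is a provider, not an algorithm.** The descriptor layer
  accepts any object with `predict(structure) -> {(chain, resnum, icode):
  pKa}`. A PROPKA3 adapter is included (optional dependency); a
  deterministic table-backed provider serves offline runs and tests.
  Provider crashes become missing values with a logged warning.
* **Structure reading policies.** First model only for NMR ensembles;
  highest-occupancy alternate location per atom name (ties → first altloc
  identifier); hydrogens dropped; HETATM retained but excluded from
  polymer-derived quantities. Chemically modified cysteines (CSO, CME,
  OCS, …) and selenocysteine are detected and flagged but excluded from
  pairing by default — the screen concerns free thiols. Asymmetric-unit
  coordinates only; no symmetry-mate expansion.
* **Canonical numbering.** Exact flanking-window matching with 'X'
  (unresolved) as a wildcard, escalating half-widths 10 → 15 → 20 until
  exactly one reference position matches; terminal wildcards may overhang
  the reference ends. Zero or multiple matches at every width leave the
  site unmapped — ambiguity is surfaced, not guessed. A full aligner is
  deliberately avoided: exact matching is deterministic and sufficient at
  these window lengths. De-duplication keeps the record with the shortest
  thiol separation (ties → lexicographically smallest structure id).
* **Group statistics.** Welch's unequal-variance t-test for
  positive-vs-negative descriptor comparisons; Mann–Whitney U (normal
  approximation, tie-corrected, no continuity correction) for
  ligandability comparisons.

## Synthetic data: what it emulates and what it does not

The fixture generator builds idealised poly-Ala/Gly scaffolds (Cα spacing
3.8 Å) in which Sγ–Sγ separations are set exactly, burial is imposed with
occluding dummy-atom shells, and B-factors follow a per-residue plan. It
emulates the *measurable geometry* a crystal structure presents — distances,
neighbour counts, accessibility, declared disulphide records — not protein
energetics: there is no Ramachandran realism, no side-chain packing, no
crystallographic noise model. Passing tests therefore demonstrate that the
descriptors and the score are computed correctly and behave as specified,
not that the score's biological discrimination on real structures is
reproduced here.

The labelled training generator draws the five descriptors from
class-conditional normal distributions. Defaults (negative → positive
means): distance 7.0 → 3.8 Å (σ ≈ 1.2), % buried 75 → 42 (σ 10), HSE total
54 → 36 (σ 9), minimum pK<sub>a</sub> 9.3 → 5.8 (σ 1.0), mean B 25 → 48
(σ 8). These place positives where characterised redox switches sit — near
bonding distance, partially exposed, thiolate-favouring pK<sub>a</sub>
around 5–6, elevated mobility — while negatives resemble ordinary buried
structural cysteines. % buried and HSE total share a latent burial factor
(ρ ≈ 0.9), so the grouping step reproducibly merges them, as the two
accessibility measures do on real data. Profiles: `strong` (full shift,
cleanly separable), `moderate` (half shift), `null` (no shift, for
calibration checks). Default training size is 20 positives / 20 negatives.

The ligandability population generator mixes a disulphide-bound
subpopulation (Sγ–Sγ ≈ 2.05 Å, never ligandable — a bonded thiol cannot be
alkylated by a chemoproteomic probe) with free pairs whose ligandability is
independent of distance. This reproduces, as a testable workflow, the
analysis in which ligandable pairs appear to sit farther apart than
non-ligandable ones until disulphide-bound pairs are removed, after which
the association vanishes.

## Problem sizes

Tests and the acceptance script use deliberately small inputs: random
50-cysteine clouds for oracle equivalence (20 seeds), 40-example training
tables, 100 replicate fits for direction recovery, 8 candidate structures
for the end-to-end chain, and a 400-pair population for the ligandability
analysis. The complete suite and the acceptance script each run in seconds
on one CPU.

## Known limitations

* The PROPKA3 adapter and the RCSB fetcher require, respectively, an
  installed `propka` and network access; offline runs use table-backed
  pKa values and local files.
* Biological assemblies, symmetry mates, anisotropic B-factors and
  isoform-level accession reconciliation are out of scope.
* S<sub>min</sub>/S<sub>max</sub> and the descriptor grouping are computed
  on the set actually supplied (training at fit time, candidate set at
  first scoring); with few or degenerate candidates the 0–100 span is
  exact by construction but can be volatile.
* The paired descriptor aggregation (sum of HSE, mean of burial and B) is
  one defensible convention among several; all three are configurable.
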