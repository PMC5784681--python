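# contactfold

Contact-driven ab initio protein structure modelling at coarse-grained
(Cα/Cβ) resolution. Given a protein sequence, a list of predicted
residue–residue contacts (CASP RR format) and a predicted 3-state
secondary structure, `contactfold` explores fold space by folding the
chain against nested subsets of the contact list, then selects five
representative models by contact-satisfaction filtering and TM-score
clustering.

Intended users: structural bioinformaticians who have contact
predictions in hand and want ranked tertiary models quickly, without a
fragment library or a molecular-dynamics engine; and method developers
who need a self-contained, deterministic pipeline to experiment with
contact-energy functions and model-selection strategies (a synthetic
target generator means no external data is required).

## Method

**Energy.** Each predicted contact (i, j) becomes a soft-square distance
restraint on the Cβ–Cβ distance R:

```
E(R) = min(ceil, w) · { Δ²            , R <  d + d₊ + r_sw
                      { a + b / Δ²    , R ≥  d + d₊ + r_sw

Δ(R) = R − (d + d₊)    if R ≥ d + d₊
     = (d − d₋) − R    if R < d − d₋
     = 0               otherwise
```

with d = 3.6 Å, d₋ = 0.1 Å, d₊ = 4.4 Å (zero-error well 3.5–8.0 Å),
switching width r_sw = 1.8 Å, exponents 2, ceil = 1000, w = 1. The
constants a and b are fixed at run time by value and slope continuity at
Δ = r_sw (for the defaults a = 2·r_sw² = 6.48, b = −r_sw⁴ = −10.4976),
so the square error tapers to a bounded constant: grossly violated
restraints stop dominating the gradient instead of tearing the model
apart. Secondary structure adds Cα restraints (helix i→i+4 at
6.2 ± 0.3 Å, strand i→i+2 at 6.7 ± 0.4 Å); chain connectivity and
sterics are harmonic Cα terms.

**Exploration.** 40 contact subsets (the top x·L contacts by confidence,
x = 0.1 … 4.0) are each folded 20 times by simulated annealing with
interleaved gradient sweeps; the 5 lowest contact-energy models per
subset are pooled (200 models). An optional second stage drops contacts
violated in the first-stage model and refolds.

**Selection.** Models are ranked by the fraction of the top ⌈L/5⌉
long-range (|i−j| ≥ 24) contacts realized below 8 Å; the best 50 are
clustered (average linkage on 1 − TM-score) into five clusters; the
cluster medoids, re-ranked by satisfaction, are the final predictions.

## Worked example

Generate a synthetic 48-residue three-helix-bundle target and model it
(short annealing schedule; a few minutes):

```
printf 'n_steps: 300\nsweep_iters: 12\nn_blocks: 10\n' > cfg.yaml
contactfold fixture --out target/
contactfold fold --fasta target/seq.fasta --rr target/contacts.rr \
    --ss target/ss.txt --out models/ --seed 1 --config cfg.yaml
```

Output:

```
fixture written to target (L=48, 68 contacts)
model1: satisfaction=1.000 e_contact=0.28 (subset x=3.9)
model2: satisfaction=1.000 e_contact=0.98 (subset x=2.8)
model3: satisfaction=0.900 e_contact=0.16 (subset x=1.1)
model4: satisfaction=0.900 e_contact=0.23 (subset x=1.1)
model5: satisfaction=0.900 e_contact=0.28 (subset x=1.4)
```

`satisfaction` is the fraction of the top ⌈L/5⌉ = 10 long-range
predicted contacts realized below 8 Å Cβ–Cβ in that model (1.000 = all
ten); `e_contact` is the model's soft-square contact energy against its
own subset's restraints (0 means every restraint sits inside its
zero-error well); `subset x` records which top-x·L contact subset the
model was folded from. `models/` holds `model1.pdb` … `model5.pdb` and
`report.tsv` with one row per candidate in the 200-model pool.

The same machinery is available as a library:

```python
from contactfold import FixtureSpec, make_native, true_contacts, tm_score
spec = FixtureSpec()                       # 3×14-residue helix bundle, L=48
native, ss = make_native(spec)
contacts = true_contacts(native)           # Cβ–Cβ ≤ 8 Å, |i−j| ≥ 6
```

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end to end on the synthetic target: it generates
the fixture inputs, runs the full 40-subset × 20-model exploration with
a short annealing schedule, applies the satisfaction filter and TM-score
clustering, writes the five ranked models under `results/models/` and
the results JSON to the given path.

## Limitations

Models are two-bead coarse-grained chains, not all-atom structures; no
beta-sheet hydrogen-bond geometry, no fragment assembly, no multi-chain
or multi-domain handling. See `docs/methods.md` for the model
assumptions, parameter defaults and numerical choices.
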