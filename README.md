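# hknot

Prediction of H-type pseudoknots in RNA sequences.

An H-type pseudoknot is two crossing helical stems. `hknot` finds the two
crossing *core* base pairs with a small context-free grammar parsed by an
Earley engine (an independent brute-force enumerator is provided and must
agree bit-for-bit), grows each core pair outward into a stem by stacking
contiguous complementary pairs ("decoration"), scores every candidate with
a linear pseudoknot energy `g = beta1 + beta2*Bp + beta3*Up`, and returns
the structure with the maximum number of base pairs, breaking ties by
minimum energy. Output is extended dot-bracket notation with `[ ]` for the
first stem and `( )` for the crossing stem.

## CLI

```bash
# predict one pseudoknot per FASTA record
hknot predict --input seqs.fasta --engine bruteforce --max-gap 2 \
    --workers 4 --csv-out candidates.csv

# score predictions against reference structures
hknot evaluate --pred pred.txt --ref ref.txt --bins "30,40,50"

# seeded synthetic sequences with one planted pseudoknot + ground truth
hknot generate --n 100 --seed 7 --out synth.fasta --structures-out synth.structs
```

`predict` reads FASTA (lowercase and `T` are normalised with a warning)
and writes three-line records: header, sequence, dot-bracket. `evaluate`
accepts those records or a CSV with `seq_id,sequence,dot_bracket` columns
and reports per-base PPV/recall/F1/MCC plus core-stem exact matches under
one-position slippage, overall and per length bin. Options can also come
from a YAML config (`--config`); CLI flags win over the file, the file
wins over built-in defaults (`beta1=9.6`, `beta2=beta3=0.1`).

## Library

```python
from hknot import RnaSequence, predict

pred = predict(RnaSequence("ex", "CCAUCGCCUGAUUUGAGGA"))
pred.dot_bracket   # '..[[[.(((]]]...))).'
pred.candidate     # core stems (5,10) and (9,16)
```

Modules: `grammar` (the parameterised rule table), `earley` (chart parser
+ derivation extraction), `detect` (grammar / brute-force / parallel
candidate enumeration), `decorate` (stem extension, wobble optional),
`energy_select` (scoring and hybrid selection), `metrics` (confusion
counts, PPV/recall/F1/MCC, slippage matching, dataset reports), `io_cli`
(formats, config, synthetic fixture generator, CLI).

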