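# taulogp

Tautomer-aware prediction of the octanol–water partition coefficient
(log P), built as a tested library plus CLI:

- **dataset** — delimited-text / SDF I/O for molecular datasets, structure
  normalization (hypervalent nitro, N-oxide, azide rewrites), salt
  stripping with a counterion whitelist, tautomer-augmented variant tables
  (every variant labeled with the parent's macro log P), and group-aware
  train/valid/test splitting.
- **tautomers** — rule-based tautomer enumeration: a single proton-shift
  engine covering keto–enol, amide–imidic acid / lactam–lactim,
  imine–enamine, 1,3 shifts between ring nitrogens, and the nitroso–oxime
  shift extended through an aromatic ring (nitrosophenol ↔ quinone
  monoxime).
- **featurize** — heavy-atom graph featurization (fixed 27-column per-atom
  layout: element / degree / H-count one-hots, charge, aromaticity, ring,
  hybridization).
- **gcn** — a graph-convolutional regressor written directly on numpy
  (graph conv → batch norm → graph pool, twice; atom-sum gather; dense +
  batch norm + dropout; scaled-tanh output head), trained with Adam on MSE
  and fully deterministic under a seed.
- **speciation** — microstate enumeration, independent-site species
  fractions over pH, log D / macro log P mixing in log space, and
  pKa-window ionization classification.
- **curation** — single-model and ensemble outlier flags, duplicate
  detection (identical graph / tautomer pair / salt pair) via union-find
  closure, and rmse stratified by heavy-atom count.
- **synthetic** — seeded molecule generator with an atom-additive log P
  oracle whose tautomer-sensitive variant mixes per-tautomer micro values
  into a macro label, plus the two benchmark experiments (oracle recovery,
  mono-vs-augmented tautomer invariance).

## CLI

All commands are subcommands of `taulogp` (see `taulogp --help`); a flat
YAML config file can pre-set options (`--config`), explicit flags win.

```bash
taulogp simulate --n 2000 --seed 1 --noise 0.1 --out synth.csv
taulogp augment  --data synth.csv --out variants.csv
taulogp split    --data synth.csv --seed 1 --out split.csv
taulogp train    --data synth.csv --augment taut --epochs 30 --seed 1 \
                 --split-file split.csv --out model.npz
taulogp predict  --model model.npz --smiles "CC(C)=O"
taulogp evaluate --model model.npz --data synth.csv --bootstrap 1000
taulogp tautomers enumerate --smiles "O=Nc1ccc(O)cc1"
taulogp speciate --pka-acid 5.1 --pka-base 2.3 --ph-min 0 --ph-max 8 --step 0.25
taulogp logd     --logp 2,-2 --fractions 0.5,0.5
taulogp curate   --data synth.csv --predictions preds.tsv --min-tools 4 --out flags.csv
```

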