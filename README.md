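# caspcleave

Prediction of caspase cleavage sites in protein sequences.

Caspases are cysteine proteases central to apoptosis and inflammation that
cleave their substrates almost exclusively after aspartate residues
(P1 = D in Schechter–Berger nomenclature; the scissile bond lies between P1
and P1′).  Experimental substrate catalogues are incomplete, so ranking the
aspartates of a protein by cleavage likelihood is a practical way to guide
degradomics experiments.  `caspcleave` is for protease biologists and
bioinformaticians who want exactly that: a trainable, scriptable
cleavage-site scanner with motif search, variant (SNP) re-scoring and
ortholog conservation mapping.

## Method

Annotated cleavage sites are aligned on the scissile bond and their
8-residue P5…P3′ contexts counted into a background-normalized log2
position weight matrix

    PWM(i, j) = log2( (count(i, j) + c·b(i)) / ((n_j + c) · b(i)) )

with b(i) the amino-acid background, n_j the observations at position j and
c a background-proportional pseudocount (so Σ_i b(i)·2^PWM(i,j) = 1
exactly).  Each candidate window is encoded as its 8 per-position PWM
values plus per-residue secondary-structure (H/E/_) and disorder (./*)
labels, and classified by a random forest (1500 trees, unlimited depth)
trained against sliding-window negatives — the windows at offsets ±1 and ±2
from each verified P1, giving a 1:4 class ratio.  A site is called cleaved
when the positive-class probability is ≥ 0.5.  See `docs/methods.md` for
the full model description and its assumptions.

## Worked example

Everything runs on synthetic data out of the box.  Generate 40 proteins
carrying 150 planted caspase-like sites, build the training windows, train
a forest and scan:

```console
$ caspcleave synth --preset ratio --out-fasta demo.fasta --out-annotations demo_sites.tsv
wrote 40 proteins and 150 annotations

$ caspcleave build-dataset --fasta demo.fasta --annotations demo_sites.tsv --out demo_windows.tsv
150 positive and 600 negative windows (ratio 1:4.00)

$ caspcleave train --fasta demo.fasta --annotations demo_sites.tsv \
      --trees 300 --seed 1 --out demo_model.joblib
Caspase cleavage classifier
---------------------------
Classifier        random_forest
Trees / depth     300 / unlimited
Training windows  150 positive, 600 negative
PWM               150 aligned sites, pseudocount 1
Features          40 (8 PWM + 24 secondary-structure + 8 disorder)
Decision rule     cleavage 'yes' if P(cleaved) >= 0.5

$ caspcleave scan --model demo_model.joblib --fasta demo.fasta | head -5
protein_id  p1_position  window       score     class  ss        disorder
SYN0001     109          KDGKD-NAGIH  0.966667  yes    ________  ******..
SYN0001     42           LDHQD-TPTEQ  0.953333  yes    HHH_____  ********
SYN0001     149          LDYND-GIELK  0.946667  yes    _______H  ********
SYN0001     19           FKLAD-AGQAL  0.903333  yes    HHHHHHHH  ........
```

Each row is one candidate scissile bond: the P5-P5′ window with `-` at the
bond, the cleavage probability (here the fraction of the 300 trees voting
"cleaved"), the yes/no call at the 0.5 threshold, and the
secondary-structure and disorder context of P5…P3′.  Results are ranked by
score, so the planted sites (D at P1 in a DxxD-[AGST]-like context,
typically in disordered loops) surface at the top.

Other subcommands follow the same pattern:

```sh
caspcleave evaluate --fasta demo.fasta --annotations demo_sites.tsv --folds 10 --json
caspcleave motif    --fasta demo.fasta --motif "DEVD-A/G/S/T" --model demo_model.joblib
caspcleave variant  --model demo_model.joblib --fasta demo.fasta --variants snps.tsv
caspcleave conserve --substrate human.fasta --ortholog mouse.fasta --sites 299
```

`evaluate` reports pooled 10-fold cross-validation confusion counts with
accuracy, precision, specificity, Cohen's kappa, MCC, AUC and cost;
`variant` re-scores every cleavage-site aspartate whose P5…P3′ window
contains the substituted position; `conserve` maps sites through a BLOSUM62
global alignment and flags whether the aligned P1 is still acidic.

The same functionality is available as a library, organised as
model/results objects:

```python
from caspcleave import (CleavageModel, ModelConfig, build_training_set,
                        generate, SynthConfig, scan_protein)

records, sites = generate(SynthConfig(n_proteins=40, n_sites=150, seed=0))
ts = build_training_set(records, sites)
results = CleavageModel.from_training_data(records, ts, ModelConfig(seed=0)).fit()
print(results.summary())
hits = scan_protein(results, records[0])
```

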