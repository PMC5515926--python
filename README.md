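# mmptl

Knowledge-transfer learning for predicting matrix-metalloprotease (MMP)
substrate-cleavage sites.

Matrix metalloproteases degrade extracellular-matrix proteins by
hydrolyzing specific peptide bonds in their substrates. For several MMP
types only a few dozen experimentally verified cleavage sites exist —
too few to train a reliable site predictor in isolation. Because MMP
cleavage sites share sequence preferences (e.g. glycine enrichment at
P7, P4, P1, P3′ and P6′, proline at P3 and P5′, leucine at P1′, in
Schechter–Berger notation), feature knowledge learned from data-rich
proteases (the *source domain*) can be transferred to a data-poor
protease (the *target domain*).

`mmptl` is for computational biologists who want to train, evaluate or
dissect such transfer models on their own substrate data, and for
method developers who need a fully seeded, self-contained benchmark.

## Method

1. **Windows.** Each substrate is cut into 16-residue windows
   P8…P1|P1′…P8′, one per peptide bond; windows at annotated P1
   positions are positives. Sequences are first de-duplicated at 70%
   global identity and negatives are down-sampled to a 1:3
   positive:negative ratio, preferring solvent-buried P1 residues when
   an accessibility profile is available.
2. **Encoding.** Eight feature schemes — AAindex (1024), AAPair/AAC
   (20), Binary one-hot (336), BLOSUM62 (336), CHARGE-Hyd (9), CKSAAP
   (2400), DISOPRED disorder (16), PSSM (320) — give 4461 named
   features per window. For spacing *k*, CKSAAP counts residue pairs
   (i, i+k+1): a full 16-mer has N_Total = 15, 14, 13, 12, 11, 10 pairs
   at k = 0…5.
3. **Transfer.** mRMR (greedy MID: maximize I(f;y) − mean I(f;s) over
   selected s) ranks features. The top 50 on the pooled source domains
   are the *common knowledge*; the target's own top 100 are appended
   after them without duplicates. An ε-SVR (RBF kernel, c/γ by grid
   search under stratified 5-fold CV) is then trained on every prefix
   of that list, and the shortest prefix maximizing mean CV AUC defines
   the final model. A *baseline* skips the transfer step: plain top-100
   mRMR on the merged data of all proteases.
4. **Evaluation.** Sensitivity, specificity, accuracy, F-score, MCC and
   Mann–Whitney AUC; plus per-position cleavage entropy
   S_i = −Σ_a p_a(i) log₂ p_a(i) of the cleaved windows as a
   specificity profile.

A seeded synthetic generator plants these shared motifs (plus
domain-private ones) into background sequences at a controllable
strength, so the whole pipeline is testable end-to-end without any
external database or predictor.

## Worked example

```sh
$ mmptl simulate --seed 5 --strength 0.6 --out-dir scenario/
wrote scenario to scenario (substrates per domain: {'SRC1': 36, 'SRC2': 35,
'SRC3': 37, 'SRC4': 42, 'SRC5': 40, 'TGT': 35})

$ mmptl transfer --scenario-dir scenario/ --seed 5 --out report.json
transfer[TGT]: 101 features (50 common), CV AUC 0.999, accuracy 0.988, MCC 0.967
baseline[TGT]: CV AUC 0.993, accuracy 0.969, MCC 0.918

$ mmptl entropy --fasta scenario/TGT.fasta --annotations scenario/TGT.tsv \
      --name TGT --out entropy.tsv
TGT: 221 cleavage windows, average entropy 3.120 bits
```

The transfer model kept a 101-feature prefix of the candidate list, 50
of which are common knowledge extracted from the five source domains;
its cross-validated AUC of 0.999 means held-out cleavage windows are
ranked above non-cleavage windows almost perfectly at this motif
strength. The average cleavage entropy of 3.12 bits (maximum
log₂20 ≈ 4.32) reflects the planted positional preferences: conserved
motif positions pull the per-position entropy down.

The same workflow runs on real data: pass your own FASTA plus a
`substrate_id<TAB>p1_position` annotation TSV (1-based P1 positions)
through `mmptl.io_data.read_substrates`, with optional NetSurfP-style
accessibility, DISOPRED-style disorder and PSI-BLAST ASCII PSSM files
per substrate.

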