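# looplens

Positional RIP-qPCR analysis of the mRNA cap-to-tail closed loop, with a
mechanistic simulator for validating the estimator end to end.

## The problem

The closed-loop model of eukaryotic translation initiation holds that the
cap-binding factor eIF4E, the scaffold eIF4G and the poly(A)-binding protein
PAB1 bridge an mRNA's 5′ and 3′ ends into a loop. A direct in-vivo readout
is positional RIP-qPCR: crosslink cells, digest the lysate with a controlled
dose of RNase, pull down a tagged factor, and ask by qPCR *which parts* of a
transcript came along. Amplicons are tiled along each transcript (two near
the ends, several internal, each ≤75 bp), and each amplicon's IP/Input
ratio measures how strongly that region co-purifies with the factor.

A factor's own binding site (the *proximal* end: 5′ for eIF4E/eIF4G, 3′ for
PAB1) is always retained. The *distal* end co-purifies only through the
bridged complex of a looped molecule. The core statistic is therefore the
**closed-loop index**

```
index = E_distal / E_proximal
```

where `E` is the normalized end enrichment (the quantities written 4E:3′,
4E:5′, PAB:3′, PAB:5′). Because incomplete co-capture and fragmentation can
only lose distal signal, the index is a **lower bound** on the closed-loop
fraction of factor-engaged molecules.

`looplens` is aimed at anyone running or reviewing this kind of assay: it
implements the full pipeline (dilution-curve efficiency correction, reaction
QC, IP/Input enrichment, within- and cross-transcript normalization, the
index, replicate statistics, condition comparisons with multiple-testing
correction) and a generative simulator of the whole experiment — molecule
states, Poisson RNase fragmentation, anchor/co-capture/background retention,
and the qPCR read-out — with closed-form expectations for every amplicon,
so that estimator accuracy, the lower-bound property and test calibration
can all be checked against known truth.

## Worked example

Simulate a single SSC1-like transcript (2000 nt, cap-side closed-loop
fraction 0.35, weak PAB1-side co-capture) and analyze it in one command:

```sh
cat > demo.yaml <<'EOF'
simulate:
  transcripts:
    - {transcript_id: SSC1, length: 2000, closed_fraction: 0.35}
  factors: [eIF4E, eIF4G, PAB1]
  co_capture_eff: {eIF4E: 1.0, eIF4G: 1.0, PAB1: 0.163}
EOF
looplens all --config demo.yaml --seed 7 --out demo_run
cat demo_run/results/report.txt
```

```
looplens 0.1.0 — closed-loop analysis report

Closed-loop index per transcript (distal/proximal end enrichment;
lower bound on closed-loop prevalence among factor-bound molecules):

  factor=PAB1 condition=steady
    SSC1         index 0.070 ± 0.008 (n=3)

  factor=eIF4E condition=steady
    SSC1         index 0.377 ± 0.011 (n=3)

  factor=eIF4G condition=steady
    SSC1         index 0.369 ± 0.007 (n=3)

Positional profiles (mean normalized enrichment per region class):
  PAB1   steady   SSC1         fiveprime=0.32  internal=0.03  threeprime=4.60
  eIF4E  steady   SSC1         fiveprime=3.59  internal=0.02  threeprime=1.35
  eIF4G  steady   SSC1         fiveprime=3.60  internal=0.03  threeprime=1.33
```

Reading the output: both cap-factor pulldowns enrich both transcript ends
over the internal amplicons, and their index (~0.37 here) estimates the
simulated 35% closed fraction up to sampling and efficiency-fit noise. The
PAB1 pulldown dominates at the 3′ end with a selective but weak 5′ signal;
its index (~0.07) reflects the deliberately poor PAB1-side co-capture, which
is why the statistic is read as a lower bound. ±values are SEMs over the 3
biological replicates; `n=3` is the replicate count.

The same steps are available as library calls
(`looplens.generate_ct_dataset`, `looplens.analyze_tables`) and as separate
`simulate` / `analyze` / `report` subcommands working on plain CSV tables —
see `looplens/qpcr_io.py` for the column conventions of each file.

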