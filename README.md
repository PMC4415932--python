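# batmap

Water–fat MRI **cooling–reheating pipeline** for human brown adipose
tissue (BAT): digital phantom simulation of multi-echo
chemical-shift-encoded scans, proton-density fat-fraction (FF) and R2*
map reconstruction, segmentation of the cervical-supraclavicular fat
depot (suspected BAT, *sBAT*) and posterior subcutaneous fat (*SAT*),
rigid VOI transfer across scan states, and the paired nonparametric
statistics that decide whether a cold-induced FF decrease reflects
**lipid consumption** or **altered perfusion**.

It is written for imaging scientists who want to test the full
analysis chain of such an experiment — thresholds, erosion,
registration, test power, attribution logic — against synthetic data
with exact ground truth, since raw MRI from cohort studies of this
design is rarely shareable.

## The model

Each voxel's complex multi-echo gradient-echo signal is

```
s(TE_n) = (W + F·c_n) · exp(i·2π·ψ·TE_n) · exp(−R2*·TE_n),
c_n = Σ_p α_p · exp(i·2π·f_p·TE_n)
```

with water/fat amplitudes W, F, B0 off-resonance ψ (Hz), one shared
R2\* (s⁻¹) per voxel, and a nine-peak triglyceride fat spectrum
(α_p, f_p).  FF = F/(F+W), reported in percent; changes in percentage
points (pp).  Reconstruction is decoupled: a μ-regularised multi-scale
discrete search for ψ (iterated conditional modes with an exact
serpentine-chain initialisation at the coarsest scale, μ = 10 by
default), a 1D discrete R2\* search at fixed ψ, a joint Gauss–Newton
polish, and a final linear solve for W and F.

The three-scan protocol (Baseline → 3 h mild cold → Cold scan →
~15 min reheating → Reheated scan) separates mechanisms by time scale:
perfusion is rapidly regulated and reverses on reheating; lipid
content is slowly regulated and persists.  A persistent significant
sBAT-FF decrease is attributed to lipid consumption, a reversing one
to perfusion (Wilcoxon matched-pairs tests, exact null, α = 0.05).

See `docs/methods.md` for the full model, parameter defaults, and
numerical conventions.

## Worked example

Run the demo pipeline — simulate a nine-subject, three-state synthetic
cohort at the default study conditions (lipid-type sBAT effect
−1.94 ± 1.83 pp, SAT posture drift −0.79 ± 0.27 pp, SNR ≈ 50),
reconstruct all 27 scans, segment and transfer VOIs, and analyse:

```bash
batmap run --seed 1 --outdir demo/
```

prints `attribution: lipid` and writes, among others,
`demo/changes.csv`:

| voi | quantity | transition | mean_change | p_value | significant |
|---|---|---|---|---|---|
| sbat | ff | Cold−Baseline | −2.91 pp | 0.0039 | True |
| sbat | ff | Reheated−Baseline | −3.01 pp | 0.0039 | True |
| sbat | ff | Reheated−Cold | −0.10 pp | 0.055 | False |
| sat | ff | Cold−Baseline | −0.07 pp | 0.098 | False |
| sat | ff | Reheated−Cold | −0.70 pp | 0.0039 | True |

Reading: this cohort's sBAT-FF dropped significantly in the cold scan
and *stayed* low after reheating (no significant Cold→Reheated
rebound), so the change is attributed to lipid consumption rather than
perfusion.  SAT-FF was unaffected by cooling but fell between the Cold
and Reheated scans — the posture-related drift, which the two-scan
no-cooling control mode (`--procedure-study`, n = 8) reproduces without
any temperature change.  Per-state group means land at the generating
values (e.g. baseline sBAT-FF 81.7 ± 7.1 % for this seed's draws) in
`demo/states.csv`; the per-subject VOI means are in
`demo/measurements.csv` and the exact simulated truth in
`demo/truth_ledger.csv`.  The whole run takes well under a minute.

Individual stages are also exposed (`batmap simulate / recon /
segment / register / analyze`), each reading and writing NIfTI + CSV,
so external quantitative maps and masks can enter the chain at any
point.

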