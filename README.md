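# refstab

Selection and validation of reference (housekeeping) genes for RT-qPCR
normalization: candidate screening from RNA-seq, four independent
expression-stability statistics, a geometric-mean consensus ranking, and
efficiency-corrected relative quantification.

## The problem

Quantifying a transcript by RT-qPCR requires dividing out sample-to-sample
differences in RNA input, reverse-transcription yield and loading.  The
standard remedy is normalization against one or more *reference genes*
assumed to be stably expressed — but that assumption fails often enough
(especially under stress treatments) that reference genes must themselves be
validated for every experimental system.  `refstab` implements the complete
validation workflow on a quantification-cycle (Cq) table with a sample sheet
of treatment groups:

- **candidate screen** (`refstab.candidate_screen`): per-gene mean
  expression, coefficient of variation and dispersion (DPM) over an
  FPKM-scale expression matrix, with the conventional filters
  *annotated* ∧ *mean FPKM > 10* ∧ *DPM ≤ 0.3*.
- **geNorm** (`refstab.stability_suite.genorm_rank`): relative quantities
  `Q(g,s) = E_g^(min Cq_g − Cq(g,s))`; the stability value of gene *j* is
  `M_j = mean_k SD_s[log2(Q_j/Q_k)]`, computed stepwise while excluding the
  worst gene, plus the pairwise variation `V(n/n+1)` between normalization
  factors of the n and n+1 most stable genes (cutoff 0.15) to choose how
  many references are needed.
- **NormFinder** (`normfinder_stability`): a model-based decomposition of
  each gene's log2 variation into intra-group variance `σ²_ig` and
  shrunken inter-group deviations `d_ig`, combined into a stability value
  `SV_i = mean_g(|d̃_ig| + √(σ̂²_ig/n_g))`.
- **BestKeeper** (`bestkeeper_analyze`): descriptive statistics on raw Cq
  (SD as mean absolute deviation, CV%, min/max, geometric mean) and the
  Pearson correlation of each gene against the BestKeeper index (per-sample
  geometric mean Cq); genes with SD > 1 cycle are flagged unacceptable.
- **comparative ΔCt** (`deltact_rank`): `SD_s[Cq_j − Cq_k]` for every gene
  pair, averaged per gene.
- **consensus** (`refstab.consensus_rank`): per-method ranks aggregated by
  geometric mean — lower is more stable.
- **validation** (`refstab.normalization_validate`): normalization factors
  (geometric mean of reference quantities), efficiency-corrected fold
  changes versus a control group with Welch-t significance, and concordance
  against RNA-seq fold changes.
- **simulation** (`refstab.synthetic_data`): Cq experiments with known
  stable/unstable genes for end-to-end parameter-recovery studies.

A worked example dataset — nine candidate reference genes of the intertidal
red alga *Pyropia yezoensis* assayed under dehydration and temperature
stress — ships in `refstab.datasets`.

## Worked example

```python
from refstab import datasets, screen_candidates
from refstab.consensus_rank import comprehensive_rank

# transcriptome screen of the nine bundled candidates
result = screen_candidates(datasets.example_screen_table())
print(result.n_pass, "pass,", result.n_fail, "fail")
for r in result.records[:3]:
    print(f"{r.gene:8s} mean={r.mean_expression:8.1f} dpm={r.dpm:.3f} passes={r.passes}")

# consensus of the four published per-method rankings (dehydration panel)
consensus = comprehensive_rank(datasets.example_method_rankings("dehydration"))
print(" > ".join(consensus.final_order))
print(round(consensus.geomean_rank["CGS1"], 3), round(consensus.geomean_rank["UBC"], 3))
```

prints

```
6 pass, 3 fail
MAP      mean=   104.8 dpm=0.129 passes=True
ATPase   mean=    36.4 dpm=0.134 passes=True
CGS1     mean=   175.3 dpm=0.164 passes=True
CGS1 > UBC > FHP > PPK > MAP > EF1-a > eif4A > DPE2 > ATPase
1.414 2.0
```

Six screen candidates pass (the three conventional housekeeping genes fail
on dispersion), and the geometric-mean consensus of the four method
rankings puts *CGS1* (geomean rank 1.414) ahead of *UBC* (2.0) under
dehydration stress.

The same pipeline runs from the shell:

```sh
refstab simulate --genes 9 --groups 5 --replicates 3 --stable 3 --seed 17 --out sim/
refstab stability --cq sim/cq.tsv --samples sim/samples.tsv --efficiency sim/efficiency.tsv --out out/
refstab consensus --cq sim/cq.tsv --samples sim/samples.tsv --efficiency sim/efficiency.tsv --out out/
refstab normalize --cq sim/cq.tsv --samples sim/samples.tsv --targets variable_1 \
    --refs stable_1,stable_2 --control control --out out/
```

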