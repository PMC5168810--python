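# discut

Differential expression analysis by learning a discriminant boundary in a
multi-dimensional space of test statistics, with permutation-based FDR
control.

## The problem and the method

Every differential-expression test statistic — a moderated *t*, a rank-sum,
an NB Wald statistic — summarizes each feature's evidence under a particular
distributional assumption, and no single assumption fits every gene in a
real dataset. `discut` treats K such statistics as coordinates
s⁽¹⁾, …, s⁽ᴷ⁾ of each feature and learns a linear discriminant

    f(s) = Σₖ wₖ s⁽ᵏ⁾ − τ,    Σₖ |wₖ| = 1

that calls feature *i* differentially expressed when f(sᵢ) > 0. The weights
and cutoff are chosen to solve

    max |{i : f(sᵢ) > 0}|   subject to   FDR̂(f) < Ψ

where Ψ is a user-set FDR bound and FDR̂ is a Storey-style non-parametric
estimate built from label permutations:

    FDR̂_λ = #{dᵢ ≤ d_λ} · Ê_b(#{d*ᵢ,b > 0}) / ((1 − λ) · (r ∨ 1) · M)

with d*ᵢ,b the discriminant values recomputed on B permuted label
assignments, d_λ the λ-quantile of the pooled permutation values (λ = 0.5),
and r the number of calls. Up- and down-regulation are searched with
separate boundaries (wₖ ≥ 0 for up, wₖ ≤ 0 for down). After the grid search,
the cutoff τ of the winning weight vector is recalibrated on an independent
permutation set to remove selection bias.

The package also ships a realistic count simulator (per-gene NB or
zero-truncated Gaussian-mixture families, null genes constrained to
|log₂ FC| ≤ 4.5 σ_N, true DEFs spiked in with uniform 1.5–3.0× factors)
and an evaluation harness (true FDR, true-positive counts, false-discovery
curves, replicate aggregation).

It is intended for bioinformaticians analyzing two-condition RNA-seq,
methylation, or other feature-by-sample matrices who want more detections
than any single statistic yields at the same FDR target.

## Worked example

```sh
discut simulate --mode synthetic --M 2000 --N 12 --up 100 --down 100 \
    --seed 3 --out sim/
discut detect --counts sim/counts.tsv --labels sim/labels.tsv \
    --attributes voom_t,sam_ranksum,nb_wald --fdr 0.05 --direction both \
    --B 50 --B-calib 50 --seed 1 --out results.tsv
discut evaluate --results results.tsv --truth sim/truth.tsv --out report.json
```

The detect step prints the learned boundaries and the call count:

```
INFO:discut:up: w=[0.15 0.5  0.35] tau=10.06 calls=55 FDR_hat=0.04673
INFO:discut:down: w=[-0.7  -0.05 -0.25] tau=4.092 calls=64 FDR_hat=0.04383
119 features called; results in results.tsv
```

Here the up-regulation boundary leans on the rank-sum and NB Wald
statistics while the down-regulation boundary is dominated by the voom
moderated *t* — the two tails of the joint attribute distribution need not
look alike. The evaluate step scores the calls against the simulation
truth:

```
true FDR 0.0504 over 119 calls; report in report.json
```

113 of the 119 calls are true DEFs, so the realized false-discovery
proportion (0.050) sits at the requested Ψ = 0.05.

All statistics are oriented group-2 minus group-1, where group 2 is the
alphabetically larger condition label. The same API is available in
Python: `discut.detect(data, ["voom_t", "sam_ranksum", "nb_wald"],
SearchConfig(psi=0.05, seed=1))`.

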