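# mirella

Resource-aware ODE modelling of how miRNA-mediated downregulation of one
transgene redistributes shared post-transcriptional resources — ribosomes
and RNases — onto co-expressed genes in mammalian cells.

## The problem

In synthetic gene circuits, two "independent" co-expressed genes are
coupled through finite cellular resources (gene expression burden). When
an endogenous miRNA downregulates one transgene (the **miTarget**, e.g.
an mKate reporter carrying miR-31 target sites in its 5' or 3' UTR), a
co-expressed constitutive reporter (the **capacity monitor**, e.g. EGFP)
goes *up*. `mirella` is for circuit designers and modellers who want to
predict and dissect this indirect coupling: it quantifies two mechanisms,

1. **ribosome redistribution** — degrading target mRNA frees translation
   capacity for everything else, amplified when 5'UTR target sites make
   the miRNA-bound transcript translationally silent; and
2. **RNase queueing** — miRNA-committed transcripts monopolise a finite
   degradation machinery, slowing the decay of non-target mRNAs
   (biphasic decay above a threshold miRNA binding strength).

## The model

Two genes compete for a constant ribosome pool r_total through the free
ribosome level r = r_total / (1 + m_T/κ_T + σ·m_Q/κ_T + m_C/κ_C).
Free miRNA q binds the target mRNA (rate η⁺, the proxy for target-site
count), forming a complex degraded λ_TQ-fold faster; σ ∈ {0, 1} encodes
target-site location (0 = 5'UTR, silent complex; 1 = 3'UTR, translated
complex). The steady state is available in closed form via resource
demand coefficients

    ρ_T  = n_T α_T / (κ_T (β_T + α_Q η⁺ β_TQ / (β_Q (β_TQ + η⁻))))
    ρ_TQ = n_T α_T / (κ_T (β_TQ + β_T β_Q (β_TQ + η⁻) / (α_Q η⁺)))
    ρ_C  = n_C α_C / (κ_C β_C)

giving the shared-pool partition

    p̄_T = (γ_T/δ_T) · (ρ_T + σ ρ_TQ)/D · r_total,
    p̄_C = (γ_C/δ_C) · ρ_C/D · r_total,          D = 1 + ρ_T + σ ρ_TQ + ρ_C.

A second model variant gives the two genes a finite RNase pool: mRNAs
form degrading mRNA:RNase complexes (association β⁺, dissociation β⁻,
catalytic completion β_cat), and miRNA commitment boosts the target's
association constant while occupying the machinery longer per transcript.
Fitting ties the translation model to five-condition fold-change panels
(Control, 1TS/3TS × 3'/5'UTR) with the regularised loss
L(θ) = ‖y − ŷ(θ)‖² + λ‖θ‖² (λ = 0.001) minimised by differential
evolution. See `docs/methods.md` for the full account.

## Worked example

```python
from mirella import default_translation_params, steady_state

p = default_translation_params()           # shipped parameterisation
for eta, sigma in [(0.0, 1), (20.0, 1), (20.0, 0)]:
    ss = steady_state(p.replace(eta_plus=eta, sigma=sigma))
    print(eta, sigma, round(ss.p_T_bar, 1), round(ss.p_C_bar, 1), round(ss.r_bar, 2))
```

prints

```
0.0 1 45454.5 45454.5 90.91
20.0 1 41463.4 48780.5 97.56
20.0 0 40983.6 49180.3 98.36
```

— without miRNA regulation (η⁺ = 0) the two symmetric genes express
equally and only ~9% of ribosomes are free; at η⁺ = 20 nM⁻¹h⁻¹ the
target protein falls, the monitor rises and the free-ribosome pool
grows, all more strongly for 5'UTR sites (σ = 0) than 3'UTR (σ = 1).

The queueing effect, from the command line:

```bash
mirella decay --eta-values 0,4 --out decay_out
```

```
 eta_plus  n_phases  breakpoint_h  slope_phase1  slope_phase2  half_life_h
      0.0         1           NaN        -0.312           NaN         2.27
      4.0         2           3.0        -0.158        -0.306         3.77
```

— the endogenous transcript decays as a single exponential
(t½ ≈ 2.3 h) without miRNA activity, but under strong miRNA
regulation of the co-expressed target its decay is biphasic: nearly
stalled for ~3 h while target-derived complexes hold the RNase pool,
then accelerating once they clear, for a longer overall half-life.

Other subcommands: `mirella analytic`, `simulate`, `sweep`, `fit`,
`make-synthetic` (see `--help`); all write long-format CSVs plus a JSON
run manifest with the seed and config hash.

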