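# petiq — penalization strength in regularized PET reconstruction

`petiq` is a desk-scale simulation study of a question every PET site faces
when adopting Bayesian penalized-likelihood reconstruction: **how strong
should the penalty be?**  Block sequential regularized expectation
maximization (BSREM) runs the Poisson likelihood to effective convergence and
controls noise with a relative difference penalty (RDP) whose weight — the
penalization factor β — trades background noise against lesion recovery.
The package simulates a NEMA IEC image-quality phantom, reconstructs it with
OSEM and with BSREM across a β sweep, computes the standard phantom metrics,
and pairs this with the analysis of a packaged 45-lesion clinical SUVmax
table measured under the same six reconstructions (β = 100…500 and OSEM).

It is written for medical-physics and image-reconstruction researchers who
want a transparent, fully testable counterpart of a scanner-side β sweep.

## The model

Reconstruction maximizes the penalized Poisson likelihood

```
Φ(x) = L(x) − β·U(x),   L(x) = Σ_i [ y_i log (Ax)_i − (Ax)_i ]
```

where `A` is a slice-wise parallel-beam projector with Gaussian detector
blur, and `U` is the relative difference penalty

```
U(x) = Σ_j Σ_{k∈N_j} w_jk (x_j − x_k)² / (x_j + x_k + γ|x_j − x_k| + ε)
```

with inverse-distance neighbor weights `w_jk` and edge-preservation
parameter γ = 2.  Because the pairwise cost is normalized by the local
intensity sum, flat-region noise is penalized strongly while high-contrast
edges survive — which is why the optimal β depends on lesion size and
lesion-to-background ratio (LBR).

BSREM performs relaxed, subset-wise scaled gradient ascent on Φ (25
iterations, 12 subsets, nonnegativity by projection); with β = 0 and unit
relaxation each sub-step reduces exactly to the OSEM multiplicative update.
The OSEM comparator follows the routine protocol: 4 iterations, 24 subsets,
4.8 mm Gaussian post-filter.

Phantom metrics follow the NEMA read-out: contrast recovery
`CR = ((C_H/C_B) − 1)/(a_H/a_B − 1)`, recovery coefficient
`RC = measured/true`, background variability `BV = SD/mean` over sixty 10 mm
background ROIs, lung residual error `LE = lung/background`, contrast, SNR,
and the pairwise relative difference
`Δfeature(a−b)% = (feature_a − feature_b)/feature_a × 100`.

## Worked example

```python
from petiq.pipeline import beta_sweep

sweep = beta_sweep(lbr=4, seed=17)          # NEMA phantom, 2e5 counts/slice
m = sweep.metrics
for r in ("beta100", "beta300", "beta500", "OSEM"):
    print(r, round(m.recon_value(r, "BV_pct"), 1),
          round(m.sphere_value(r, 10.0, "CR"), 3))
print(m.compare("CR", "beta500", "beta100", 10.0).delta_pct)
```

prints (background variability %, contrast recovery of the 10 mm sphere):

```
beta100 31.2 0.77
beta300 25.0 0.67
beta500 20.8 0.59
OSEM 24.6 0.619
-30.6
```

Reading: raising β from 100 to 500 cuts background noise by a third while
costing the smallest sphere 31% of its contrast recovery; β = 300 sits at
OSEM's noise level with slightly better small-sphere recovery.  Across LBRs
the 10 mm ΔCR(500−100) shrinks from −46% (2:1) through −31% (4:1) to −15%
(8:1): the relative penalty hurts low-contrast small lesions most, which is
why the recommended β grows with lesion size and LBR.

The numbered drivers under `analysis/` run the full study and write tables
and figures under `results/`:

```
python analysis/01_build_phantom.py      # geometry checks, NIfTI export
python analysis/02_reconstruct_sweep.py  # sweeps at LBR 2:1, 4:1, 8:1
python analysis/03_phantom_metrics.py    # relative-difference tables, figures
python analysis/04_clinical_lesions.py   # 45-lesion table analysis
python analysis/05_stats.py              # RM-ANOVA + Bonferroni post hocs
```

There is also a thin CLI (`petiq simulate | recon | iq-analyze | run`) over
the same library calls.

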