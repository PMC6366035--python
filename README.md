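# mirimpact

Linear miRNA–mRNA perturbation modelling: predict stress-induced mRNA
log2 fold changes from miRNA binding-site structure and miRNA abundance,
estimate per-miRNA perturbation coefficients by least squares, and rank
miRNAs by their impact on global transcriptome change.

## The problem

After a cellular stress such as ionizing irradiation, mRNA levels shift
within the hour — before transcriptional programs can account for the
change. One candidate mechanism is perturbed miRNA-mediated repression:
damage to miRNAs or to their interactions re-weights how strongly each
miRNA silences its targets. `mirimpact` is for computational biologists
who want to quantify that hypothesis on expression data: given binding-site
counts, miRNA abundances and observed fold changes, it asks how much of
the transcriptome-wide change a linear re-weighting of miRNA repression
can explain, and which miRNAs carry that explanation.

## The model

The predicted log2 fold change of transcript *j* is

```
FC_j = Σ_i Δk_i · c'_ji · miRNA_i + b0        FC = A·Δk + b0·1,  A = C'·diag(miRNA)
```

where `c'_ji` is a weighted binding-site count combining several target
predictors (`c'_ji = Σ_k w_k c^k_ji`, default weights miranda/targetscan/
rnahybrid 0.3 each, in-repo text scan 0.1), `miRNA_i` the log2 abundance,
`Δk_i` the perturbation of miRNA *i*'s repression strength (positive:
repression weakened, targets rise) and `b0` a shared miRNA-independent
offset. With many more transcripts than miRNAs, `(Δk, b0)` are estimated
by ordinary least squares and scored by the Spearman correlation ρ between
predicted and observed fold changes. Validation machinery includes random
training/validation splits, three randomized-matrix null controls, a
single-predictor miRNA ranking with forward/reverse cumulative-inclusion
curves, a Gaussian-mixture expression noise filter, and structural feature
comparisons (Mann–Whitney U / t-tests). Every stage runs on synthetic data
generated by the package itself. See `docs/methods.md` for the full
statistical account.

## Worked example

```python
import numpy as np
from mirimpact import (
    make_dataset, build_design, fit_least_squares, rank_single_mirnas,
    cumulative_curve, randomization_control,
)

# synthetic study: 2000 transcripts x 100 miRNAs, 20 truly active,
# noise set so the model explains ~35% of fold-change variance
ds = make_dataset(n_mrna=2000, n_mirna=100, n_active=20, r_squared=0.35, seed=7)

design = build_design(ds.C_prime, ds.mirna_expr)       # A = C' diag(miRNA)
model = fit_least_squares(design, ds.fc_observed)      # (dk, b0) by least squares
print(f"training Spearman rho = {model.rho_train:.3f}")
print(f"intercept b0 = {model.b0:.3f}  (truth {ds.true_b0:.3f})")

ranking = rank_single_mirnas(ds.C_prime, ds.mirna_expr, ds.fc_observed)
print(ranking.table.head(5).to_string(index=False))
hits = len(set(ranking.top(20)) & set(ds.active_set))
print(f"planted actives in top 20: {hits}/20")

curve = cumulative_curve(ds.C_prime, ds.mirna_expr, ds.fc_observed, ranking, "forward")
print(f"forward curve plateau at n = {curve.plateau_n()} miRNAs")

null = randomization_control(ds.C_prime, ds.mirna_expr, ds.fc_observed,
                             "permute_after_fit", n_reps=200, seed=7)
print(f"permute-after-fit null: mean rho = {null.rho_dist.mean():+.4f}")
```

Output:

```
training Spearman rho = 0.556
intercept b0 = -0.034  (truth -0.044)
 rank mirna_id  rho_single  dk_single
    1  mir0075    0.266114  -0.019628
    2  mir0043    0.187229  -0.013628
    3  mir0058    0.166668   0.014371
    4  mir0005    0.164922   0.012963
    5  mir0085    0.152006  -0.019552
planted actives in top 20: 14/20
forward curve plateau at n = 58 miRNAs
permute-after-fit null: mean rho = -0.0009
```

Reading it: the fitted model ranks fold changes at ρ ≈ 0.56 while a
structureless (shuffled) target matrix carrying the same coefficients
ranks them at ρ ≈ 0 — the fit rests on the interaction structure, not on
the coefficient scale. The single-miRNA ranking recovers most of the
planted active miRNAs (weak ones with |Δk| near zero sit below the
ranking noise floor, ~1/√N_m), and the cumulative curve saturates once
the informative miRNAs are included. Note the top-ranked miRNAs mix
negative and positive Δk: the ranking refits each slope, so the score
measures explanatory power, not direction.

The same pipeline is scriptable from a shell: `mirimpact simulate`,
`build-matrix`, `filter-noise`, `fold-change`, `fit`, `validate`,
`randomize`, `rank`, `cumulative`, `features`, `classify-fit`
(see `mirimpact --help`).

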