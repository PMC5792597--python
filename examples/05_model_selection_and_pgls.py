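"""Which factors drive diversity?  Stepwise AIC, parsimony, and PGLS.

Per-species mitochondrial diversity is regressed on candidate factors:
bidirectional stepwise AIC picks a model, simpler models within ~5 AIC
units are preferred, and the chosen model is confirmed by phylogenetic
generalized least squares with Pagel's lambda estimated by restricted
maximum likelihood.
"""

import pandas as pd

import cetadiv as cd
from cetadiv.design import factor_frame

bundle = cd.simulate_study(cd.SimulationConfig(seed=7))
tree, factors = bundle["tree"], bundle["factors"]
frame = factor_frame(factors)  # population size already log10

pi = {e.species_id: e.value for e in cd.aggregate_pi(bundle["mtdna_regional"])}
response = pd.Series(pi, dtype=float)

pool = ["population_size", "latitudinal_range", "max_length",
        "generation_time", "habitat", "hemisphere", "social_structure"]
step = cd.stepwise_aic(response, pool, frame)
print("stepwise path (action, term, AIC):")
for action, term, aic in step.path:
    print(f"  {action:5s} {term or '-':20s} {aic:8.2f}")

sub = frame.loc[list(step.species_set)]
resp = response.loc[list(step.species_set)]
models = [cd.fit_linear_model(resp, (), sub), step.selected]
best = cd.parsimony_select(models)
print(f"\nselected terms: {list(best.terms)} "
      f"(AIC {best.aic:.2f}, n = {best.n})")

fit = cd.pgls_fit(tree, pi, frame, list(best.terms), structure="lambda")
print(f"\nPGLS (lambda = {fit.structure_param:.2f}) sequential F tests:")
for term in fit.term_F:
    print(f"  {term:20s} F = {fit.term_F[term]:7.2f}  p = {fit.term_p[term]:.4f}")
# lambda near 0 says phylogeny adds little once these factors are in the
# model; matrilineal social structure and range size carry the signal.
# When lambda-hat lands on the lower positive-definiteness bound the
# covariance is nearly singular along the grand mean and the intercept F
# becomes enormous -- read it as "boundary estimate", not as evidence.
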