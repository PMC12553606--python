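"""The three validation schemes and component-wise accuracy diagnostics.

Leave-one-country-out probes extrapolation to unseen environments;
leave-one-random-cluster-out probes prediction of new accessions with
relatives in training; leave-one-genetic-cluster-out probes prediction
across genetic distance.  Accuracy is the mean over folds of the Pearson
correlation between observed and predicted means in the held-out cells.
"""

from gxeblup import studies
import gxeblup as gx

panel = studies.build_panel(90, ["Norway", "Estonia", "Sweden", "Denmark"],
                            n_markers=500, seed=5)
y, idx, _ = gx.simulate_stage2(
    panel["design"], "TDM3", panel["G_A"], panel["E"], panel["G_D"],
    varcomp={"A": 0.30, "Env": 0.05, "AxEnv": 0.25, "D": 0.05, "DxEnv": 0.05,
             "residual": 0.30}, seed=5)
sub = idx[["accession", "environment", "country"]]
clusters = gx.genetic_clusters(panel["freq"], k=6)

terms = gx.stage2_terms(panel["G_A"], panel["E"], panel["G_D"], "M2")
schemes = {
    "leave-one-country-out": gx.make_country_folds(sub),
    "leave-one-random-cluster-out": gx.make_random_folds(sub, k=6, seed=5),
    "leave-one-genetic-cluster-out": gx.make_genetic_folds(sub, clusters),
}
for name, folds in schemes.items():
    cv = gx.run_cv(y, sub, terms, folds, model="M2")
    print(f"{name}: mean PA {cv.mean_accuracy:.3f} "
          f"(sd over {len(cv.per_fold)} folds {cv.sd_accuracy:.3f})")

print("\ncomponent-wise correlations, genetic-cluster scheme "
      "(which effect carries the predictive signal):")
cv = gx.run_cv(y, sub, terms, schemes["leave-one-genetic-cluster-out"],
               model="M2")
table = gx.component_correlations(cv)
print(table[["component", "mean", "sd"]].round(3).to_string(index=False))
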