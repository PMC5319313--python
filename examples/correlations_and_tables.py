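"""Effect-size posteriors for a correlation test and a 2x2 contingency table.

Correlations get an exact-likelihood posterior for rho under a stretched
beta prior (kappa = 1 is uniform on (-1, 1)) plus a default Bayes factor;
contingency tables get a Monte-Carlo posterior for Cramér's phi^2 from a
Dirichlet posterior over cell probabilities.
"""

import repbayes as rb

corr = rb.CorrelationSummary(r_obs=0.25, n=120)
post = rb.rho_posterior(corr, kappa=1.0)
bf = rb.bf_correlation(corr, kappa=1.0, side="positive")
print(f"rho   : median {post.median:.2f}, 95% CI [{post.ci_low:.2f}, {post.ci_high:.2f}]")
print(f"BF+0  = {bf:.2f}  ({rb.classify_evidence(bf).value} evidence)")

table = rb.ContingencyTable([[30, 10], [12, 28]])
phi2 = rb.phi2_posterior(table, alpha=1.0, seed=0)
print(
    f"phi^2 : median {phi2.median:.2f}, 95% CI [{phi2.ci_low:.2f}, {phi2.ci_high:.2f}]"
    "   (shared variance between the two binary variables)"
)
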