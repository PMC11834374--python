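"""Score bipartite network specialisation with H2' and a null model.

H2' rescales the Shannon entropy of the interaction table between the
extremes achievable with the observed marginals: 0 = species interact in
proportion to abundance, 1 = perfect partner specialisation.  The
standardised effect size (SES) compares the observed H2' with
fixed-marginal (Patefield) null tables.
"""

from symnet import (
    FilterConfig,
    SyntheticConfig,
    build_community_matrix,
    filter_observations,
    h2_ses,
    simulate_community,
)

cfg = SyntheticConfig(dominance=0.9, samples_per_species=40, seed=5)
table, _, _ = simulate_community(cfg)
web = build_community_matrix(
    filter_observations(table, FilterConfig(partner_kind="parasitoid")),
    "parasitoid",
)
print(
    f"aphid x parasitoid web: {len(web.focal_labels)} x "
    f"{len(web.partner_labels)}, {web.values.sum()} interactions"
)

res = h2_ses(web, n_null=1000, seed=0)
print(f"H2  = {res.H2:.4f} nats (bounds {res.H2min:.4f} .. {res.H2max:.4f})")
print(f"H2' = {res.h2prime:.4f}")
print(f"null H2' = {res.null_mean:.4f} +- {res.null_sd:.4f}  (n={res.n_null})")
print(f"SES = {res.ses:.1f}")
print(
    "\nWith 90% of attacks from one dominant parasitoid per aphid the web "
    "is far\nmore specialised than its null: SES tens of standard "
    "deviations above zero."
)
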