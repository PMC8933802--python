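"""Does the posted price reveal the hidden ward workload?

Two 20-day sessions: one where every ward prices linearly in its own
workload (a deliberate signal), one where prices are random and
workload-blind (no signal).  The association tables show Spearman rho ~ 1
per group in the first case and ~0 pooled in the second — pricing can carry
the ward's private workload state, but only if the pricing rule uses it.
"""

import tokenward as tw
from tokenward.analysis import association, extract_pairs
from tokenward.config import PolicySpec

linear = {w: PolicySpec(kind="workload_linear", params={"base": 5.0, "slope": 0.5}) for w in "ABC"}
blind = {w: PolicySpec(kind="random", params={"low": 1.0, "high": 9.0}) for w in "ABC"}

for label, policies in [("workload-linear pricing", linear), ("workload-blind pricing", blind)]:
    cfg = tw.default_scenario(n_days=20, seed=7, policies=policies)
    pairs = extract_pairs(tw.run_session(cfg).log)
    table = association(pairs, grouping="ward")
    print(f"\n=== {label} ({len(pairs)} price-workload pairs) ===")
    print(table.to_string(index=False))

print(
    "\nspearman_rho near 1 means higher workload reliably produced higher "
    "posted prices (the signal is recoverable by an outside observer); near "
    "0 means prices carried no workload information."
)
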