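"""Render the odds-ratio report: exponentiated posterior means, 95% credible
intervals, percentage effects and significance flags.

The report is gated: estimates print only when the convergence check passes.
"""

import hierlogit as hl

data, _ = hl.generate_dataset(hl.recovery_generator_config(n=400, seed=7))
draws = hl.run_chains(data, hl.PriorSpec(), hl.short_chain_config(seed=7))
conv = hl.check_convergence(draws)

rows = hl.odds_ratio_table(draws, level=0.95)
print(hl.render_report(rows, conv))
print("odds_ratio = exp(posterior mean of the slope); pct_effect = (OR-1)x100 is")
print("the percent change in the odds of intending to quit per unit covariate;")
print("'significant' means the 95% interval excludes an odds ratio of 1.")
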