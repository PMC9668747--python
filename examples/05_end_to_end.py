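"""One-call end-to-end run: synthesize -> process -> classify -> simulate
-> compare, then summarize from the persisted artefacts.

Uses a reduced problem size so the example finishes in seconds; the
defaults of RunConfig are the full study conditions.
"""

import plateaulearn as pl

config = pl.RunConfig(environment="A", seed=7, n_laps=30, n_cells=60,
                      n_chains=500, n_neurons=1000, n_ec3_axons_imaged=60,
                      out_dir="scratch_run")
run_dir = pl.run_end_to_end(config)
summary = pl.report_summary(run_dir)

print(f"artefacts in {run_dir}/ (session.h5, maps, records, manifest)")
for key, value in summary.items():
    print(f"  {key}: {value}")
# n_place_cells counts units passing the shuffle + reliability rule;
# recruited_fraction is the plateau-model calibration result;
# peak_shift_median_cm < 0 is the backward-shift plasticity signature.
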