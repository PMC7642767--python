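"""Estimate a genome size from simulated flow-cytometry events.

Simulates a co-preparation of a large-genome grasshopper sample
(true 1C = 9.64 pg) with the Locusta migratoria male internal standard
(1C = 6.20 pg), then recovers the sample's 1C value from the ratio of
the fitted 2C peak positions.
"""

from cvalkit import fcm, synth

cfg = synth.FcmSimConfig(true_1c=9.64, standard_1c=6.20, cv_sample=2.0,
                         cv_standard=2.0, n_events=20000,
                         debris_fraction=0.05, tetraploid_fraction=0.10,
                         seed=1)
table = synth.simulate_fcm_events(cfg)
est = fcm.estimate_from_events(table, expected_sample_range=(8, 12))

print(f"true 1C          : {cfg.true_1c:.2f} pg")
print(f"estimated 1C     : {est.one_c:.3f} pg ({est.genome_mb:,.0f} Mb)")
print(f"sample peak CV   : {est.sample_peak.cv:.2f} %")
print(f"standard peak CV : {est.standard_peak.cv:.2f} %")
print(f"QC (CV < 5%)     : {'pass' if est.qc_pass else 'FAIL'}")
# The estimate lands within ~0.5% of the simulated truth; both peak CVs
# sit near the simulated 2%, well inside the 5% QC gate.
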