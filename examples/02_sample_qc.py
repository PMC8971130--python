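"""Per-sample quality control on simulated QC metrics.

Computes the three cfRNA quality metrics (RNA degradation as 3'-bias,
DNA contamination as intron:exon ratio, reads assigned) and applies the
pooled 95th-percentile exclusion rule.
"""

from cfrna import qc, simulate

design = simulate.SimulationDesign(
    cohorts={"discovery": (30, 15)}, qc_outlier_fraction=0.04, seed=2
)
table, exon_fixture = simulate.simulate_qc_tables(design)

records = [
    qc.QCRecord(r["sample_id"], r["degradation_fraction"],
                int(r["reads_assigned"]), r["intron_exon_ratio"])
    for _, r in table.iterrows()
]
flagged = qc.flag_outliers(records, percentile=95.0)
frame = qc.records_to_frame(flagged)
print(frame.head())
n_out = int(frame["outlier"].sum())
print(f"{n_out} / {len(frame)} samples flagged as low-quality outliers")
# A flagged sample sits at or above the empirical 95th-percentile bound of
# degradation or contamination (or has no reads) and is excluded downstream.

deg = qc.degradation_fraction(exon_fixture)
print(f"degradation fraction of the exon-level fixture: {deg:.3f}")
# = share of detected genes whose reads all sit in the 3'-most exon.
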