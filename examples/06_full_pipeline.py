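"""The whole analysis in one call: simulate -> QC -> metrics -> RSCU ->
PCA/PERMANOVA -> skews -> ENC-GC3/neutrality -> CAI -> coadaptation.

Writes a deterministic output bundle (tidy CSVs, JSON fits, plots, run log,
config snapshot) under ./scratch/example_run and prints the plain-text
report.
"""

from mitocodon import CohortSpec, PipelineConfig, run_pipeline, write_report

config = PipelineConfig(
    cohort=CohortSpec(n_species=12, orders=("O1", "O2", "O3"), seed=12345),
    outdir="scratch/example_run",
    permutations=999,      # 10_000 for production runs
    bootstrap_B=1000,      # 10_000 for production runs
    seed=12345,
)
bundle = run_pipeline(config)
print(write_report(bundle))
print("outputs in", bundle.outdir)
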