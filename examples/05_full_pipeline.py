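"""One-call end-to-end run: simulate -> traits -> scans -> QTL -> report.

Runs the whole pipeline on a scaled synthetic study and prints the run
summary.  The run directory holds every stage artifact: the serialized
study, the trait matrix, thresholds, the QTL table, colocalization
groups and a manifest of checksums that makes the run reproducible.
"""

from microqtl import RunConfig, report, run_pipeline

cfg = RunConfig(
    output_dir="scratch/example_run",
    simulation=dict(
        n_individuals=300,
        n_chromosomes=5,
        markers_per_chromosome=15,
        n_asvs=80,
    ),
    n_perm=300,   # scaled down; use more for production thresholds
    seed=1,
)
run_dir = run_pipeline(cfg)
print(report(run_dir))
print(f"\nartifacts in: {run_dir}")
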