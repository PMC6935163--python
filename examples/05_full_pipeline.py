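"""The full evaluation pipeline on one synthetic study.

Simulates a two-series population with pedigree-recording errors, corrects the
pedigree from SNPs, evaluates every trait under both pedigree variants with
ABLUP and GBLUP, cross-validates predictive ability, and prints the two
report tables (genetic parameters and selection efficiency).
"""

import warnings

from pinegs import PipelineConfig, SimulationConfig, run_pipeline
from pinegs.simulate import SeriesConfig

warnings.simplefilter("ignore")

cfg = PipelineConfig(
    sim=SimulationConfig(
        series=(
            SeriesConfig("S1", 20, 80, "single_pair", ("A", "B")),
            SeriesConfig("S2", 12, 80, "factorial", ("B", "C")),
        ),
        n_unrelated=20,
        n_markers=600,
        pedigree_error_rate=0.5,
        genotype_error_rate=0.05,
        missing_rate=0.08,
    ),
    cv_k=5,
    cv_reps=2,
    panel_size=300,
    seed=2024,
)
report = run_pipeline(cfg)

print("parentage:", report.parentage_summary)
print(f"status number of the phenotyped group: {report.status_number:.2f}\n")
print("genetic parameters (trait x pedigree x model):")
print(report.genetic_params.round(3).to_string(index=False))
print("\nselection efficiency (trait x pedigree):")
print(report.efficiency.round(3).to_string(index=False))
print(
    "\nWith half the records corrupted, the corrected pedigree gives higher\n"
    "cross-validated predictive ability: its full-data EBV reference is no\n"
    "longer polluted by wrong parent assignments. The %VA split between the\n"
    "marker and residual-polygenic terms is only weakly identified at this\n"
    "scale (see docs/methods.md) and should be read with care."
)
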