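"""SNP-based pedigree correction by trio exclusion.

Simulates a factorial crossing trial whose documented pedigree carries 50%
recording errors, selects an informative parentage panel, scores every
candidate parent pair per progeny by Mendelian exclusions, and corrects the
pedigree. The confirmed fraction should sit near 1 - error rate, and nearly
every progeny should get its true parents back.
"""

import warnings

import numpy as np
import pandas as pd

from pinegs import SimulationConfig, assign_parentage, correct_pedigree, select_panel, simulate_dataset
from pinegs.simulate import SeriesConfig

warnings.simplefilter("ignore")

cfg = SimulationConfig(
    series=(SeriesConfig("POP", 24, 120, "factorial", ("A",)),),
    n_unrelated=0,
    n_markers=400,
    maf_bounds=(0.1, 0.5),
    pedigree_error_rate=0.5,
    genotype_error_rate=0.05,
    missing_rate=0.08,
    seed=7,
)
data = simulate_dataset(cfg)
geno, documented, true_ped = data["genotypes"], data["ped_documented"], data["ped_true"]

panel = select_panel(geno, maf_range=(0.3, 0.5), hwe_alpha=0.01, max_markers=300)
print(f"panel: {len(panel.markers)} SNPs retained (removed per criterion: {panel.removed})")

candidates = [i for i, (s, d) in documented.parents.items() if s == "0"]
assignments = [
    assign_parentage(prog, candidates, geno, panel, documented)
    for prog, (s, d) in documented.parents.items()
    if s != "0"
]
corrected, summary = correct_pedigree(documented, assignments)
print(f"trios confirmed: {summary['pct_confirmed']:.1f}%  "
      f"(true error rate injected: {100 * cfg.pedigree_error_rate:.0f}%)")
print(f"parent slots re-assigned: {summary['pct_parents_reassigned']:.1f}%")

recovered = np.mean([
    corrected.parents[p] in ((s, d), (d, s))
    for p, (s, d) in true_ped.parents.items() if s != "0"
])
print(f"progeny assigned their true parent pair: {100 * recovered:.1f}%")
print(
    "\nThe confirmed fraction mirrors the share of records that were correct\n"
    "to begin with; recovery near 100% shows the exclusion counts identify\n"
    "the true trio despite genotyping error and missing calls."
)
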