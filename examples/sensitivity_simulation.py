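"""Sensitivity/specificity benchmark with injected heterogeneity.

A homogeneous cohort is split into control (N1) and test (N2) halves; N2 is
divided into hidden subtypes N21/N22 (here 50/50). Fold changes drawn from
{1.2, 1.5, 1.8, 2.0, 3.0} are injected into 10% of genes in N21 and an
independent 10% in N22. Benchmark subnetworks of 7 correlated genes are
built per ground-truth category and both scoring modes are run; the
fraction of each category reported significant estimates sensitivity
(G1/G2/G12) and the false-positive rate (G0).

A short 5-iteration run at reduced scale; the printed medians are noisy but
show the characteristic pattern.
"""

from spsnet import run_sensitivity_experiment
from spsnet.simulation import summarize_sensitivity

table = run_sensitivity_experiment(
    n_genes=4000, n_samples=240, alpha=0.5, iterations=5, seed=1,
)
summary = summarize_sensitivity(table)
print(summary.to_string(index=False))
print(
    "\nReading the table: G1/G2 rows are subnetworks perturbed in one hidden"
    "\nsubtype only, G12 in both, G0 in neither. The subpopulation-sensitive"
    "\nmode (spsnet) recovers far more single-subtype subnetworks than the"
    "\nwhole-phenotype mode (pfsnet), while both keep the G0 fraction near 0."
)
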