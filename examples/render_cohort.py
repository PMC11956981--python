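"""Render a synthetic graded cohort and quantify its phenotypes.

Generates H&E-like patches whose tumor-nucleus size, nucleolus count and
vasculature density are controlled by a grade parameter, then runs the
phenotype detectors on the rendered images and prints per-grade means.
"""

from deltamarch.phenotypes import phenotype_table
from deltamarch.synthetic_tissue import make_cohort

patches, metadata = make_cohort(n_per_grade=25, seed=0)
print(f"rendered {len(patches)} patches across grades {sorted(map(int, metadata.grade.unique()))}")

table = phenotype_table(patches)
summary = table.groupby("grade")[
    ["mean_tumor_nuclear_area", "mean_other_nuclear_area",
     "nucleoli_per_tumor_nucleus", "vasc_fraction"]
].mean().round(2)
print(summary.to_string())
print(
    "\nTumor nuclear area and nucleoli counts rise with grade while the "
    "vasculature fraction falls; non-tumor nuclear area stays flat - the "
    "grade rules the downstream analyses must recover."
)
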