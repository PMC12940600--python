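"""End-to-end run plus the four-axis sensitivity suite.

Executes every stage (simulate, QC, descriptives, decomposition, forest,
HIA) into an output directory, then re-runs the analysis across the
robustness axes (completeness threshold, seasonal strata, outlier
exclusion, extended meteorology) and prints the shift in each pollutant's
meteorology share.
"""

import tempfile
import warnings

from aqpd import RunConfig, run_full_analysis, sensitivity_suite

warnings.filterwarnings("ignore")

with tempfile.TemporaryDirectory() as out:
    bundle = run_full_analysis(RunConfig(seed=123, outdir=out))
    print(f"bundle written to {out} (config hash {bundle.manifest['config_hash']})")
    print(bundle.decomposition[["pollutant", "n", "r2", "pct_meteo", "pct_covid", "p"]]
          .to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print("\nsensitivity: change in %meteo versus the base run")
grid = sensitivity_suite(RunConfig(seed=123))
for name, res in grid.items():
    if name == "base":
        continue
    if "skipped" in res:
        print(f"  {name}: skipped ({res['skipped']})")
    else:
        moves = ", ".join(f"{k} {v:+.1f}" for k, v in res["delta"].items())
        print(f"  {name}: {moves}")
print(
    "\nSmall shifts mean the meteorology/phase attribution is robust to "
    "that processing choice; seasonal strata shift more because each "
    "stratum sees only part of the phase calendar."
)
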