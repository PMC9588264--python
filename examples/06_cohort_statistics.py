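"""A miniature cohort run with permutation tests and boxplot statistics.

Runs the full pipeline on a few jittered phantoms (3-mm grid for speed),
then tests each paired scenario difference with a sign-flip permutation
test and summarizes gamma passing ratios as boxplot statistics. The full
study configuration is the default PipelineConfig (20 cases, 2-mm grid).
"""

from spacerdose import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_cases=4, master_seed=1, grid_preset="reduced", n_perm=1000)
report = run_pipeline(cfg)

print("mean gamma passing ratio over the cohort:")
pr = report.pr_table.query("roi == 'ALL'")
print(pr.groupby(["pair", "criteria"])["PR"].mean().unstack().round(4).to_string())

print("\nEUD differences vs ground truth (cGy), permutation p-values:")
perm = report.permutation_tests
sub = perm[(perm.metric == "EUD") & (perm.roi.isin(["ctv", "nvb", "rectum", "bladder"]))]
print(sub[["pair", "roi", "mean_diff_cGy", "p_value"]].to_string(index=False))

print("\nThe NVB carries the largest EUD error of the OARs because it sits "
      "in the lateral beam corridor directly behind the spacer; small "
      "p-values mean the paired difference is systematic across cases.")
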