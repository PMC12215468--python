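"""A small end-to-end phantom study: simulate, compare, test equivalence.

Two synthetic subjects x four knee bones with no systematic offset and
0.1 mm surface noise: the per-bone means should scatter near zero and the
TOST decision at the +-0.15 mm margin should come out TRUE, mirroring how
the pipeline is used on real paired scans.  Writes colorized distance
meshes and CSV/JSON tables to ./phantom_study_out.
"""

from bonequiv import StudyConfig, run_study

config = StudyConfig(n_subjects=2, delta=0.0, sigma_noise=0.1, seed=7, out_dir="phantom_study_out")
report = run_study(config)

print(report.pair_rows[["subject", "bone", "mean_mm", "std_mm", "n_vertices"]].to_string(index=False))
print("\nTOST on the per-bone means:")
print(report.equivalence.to_string(index=False))
print(f"\nfailures: {len(report.failures)}; artifacts in {config.out_dir}/")
print("equivalent=True: modality A's bone models match B's within +-0.15 mm on average")
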