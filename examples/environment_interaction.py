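"""Environment-dependent selection: the frequency-by-environment interaction.

Selection strength can be hooked per design cell: here selection operates in
three of the four cells but is absent where HI starts common in the
heterogeneous environment. Group-wise bootstrap means recover the pattern.
"""

from nfds import ExperimentDesign, generate_experiment, group_means, response_matrix
from nfds.freqs import build_line_records

true_s = {
    (0.2, "homogeneous"): 0.25,
    (0.8, "homogeneous"): 0.25,
    (0.2, "heterogeneous"): 0.25,
    (0.8, "heterogeneous"): 0.0,
}
design = ExperimentDesign(seed=21, true_s=true_s, census=10_000, read_depth_per_snp=50_000)
_, counts, design_table = generate_experiment(design)

lines = build_line_records(counts, design_table)
data = response_matrix(lines, kind="s_I")
groups = group_means(data, n_boot=9999, seed=22)

print("cell (start_freq, environment)   mean S_I   95% CI          true s")
for (sf, env), g in sorted(groups.items()):
    tag = "   <- null cell" if true_s[(sf, env)] == 0 else ""
    print(f"({sf}, {env:<13})        {g.estimate:+.3f}    "
          f"[{g.lower:+.3f}, {g.upper:+.3f}]  {true_s[(sf, env)]}{tag}")

print("\nOnly the cell simulated without selection has a CI containing zero;")
print("this is the pattern a significant SF x E interaction points at.")
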