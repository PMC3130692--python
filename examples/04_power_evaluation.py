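"""Power and cluster-recovery accuracy of the scan test across risk ratios.

Each simulated dataset is tested against its own permutation critical value.
At cluster risk ratio 1 the rejection rate is the empirical type I error;
above 1 it is the standard power.  Joint power demands exact recovery of the
planted cluster; sensitivity/specificity grade partial recovery of the most
likely cluster.  (Desk-scale settings keep this to about a minute.)
"""

from pathscan import choose_cluster_window, evaluate_crr_grid, generate_random_pathway
from pathscan.evaluation import reports_to_frame

graph = generate_random_pathway(300, 2, seed=42)
cluster = choose_cluster_window(graph, target_size=30)

reports = evaluate_crr_grid(
    graph, cluster.members, crr_grid=[1.0, 2.0, 3.0, 4.0, 5.0],
    n_datasets=100, n_cases=200, n_controls=200, p=5e-3, prevalence=0.01,
    R=4, B=199, alpha=0.05, seed=11)

print(reports_to_frame(reports).to_string(index=False))
print("-> the CRR=1 row's rejection_rate is the type I error (nominal 0.05);")
print("   power and sensitivity climb with CRR while specificity stays high")
print("   because the detected window rarely strays far from the cluster.")
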