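"""Elbow thresholding and overlapping link communities for the ED at night.

Sweeping the shared-shift threshold from 2 to 20 removes spurious one-off
edges quickly, then stalls; the elbow of the LOWESS-smoothed removal curve
is the operating threshold.  The pruned network's edges are clustered
(weighted Tanimoto similarity + WPGMA) and the dendrogram is cut at maximum
partition density, yielding communities that may share nodes.
"""

from carenet import (
    GeneratorConfig,
    build_collaboration_network,
    collect_gaps,
    detect_link_communities,
    generate_study,
    prepare_master_log,
    segment_shifts,
    select_break_interval,
    select_threshold,
    split_sublogs,
)

study = generate_study(GeneratorConfig(seed=1))
master, _ = prepare_master_log(study.records, study.encounters, study.adt, study.roster)
segmented, _ = segment_shifts(master, select_break_interval(collect_gaps(master)).chosen_interval)
sub = split_sublogs(segmented).sublogs[("ED", "night")]

net = build_collaboration_network(sub, ("ED", "night"))
pruned, curve = select_threshold(net)
print(f"ED night: {net.n_edges} edges, elbow threshold = {curve.elbow}, "
      f"{pruned.n_edges} edges retained")

result = detect_link_communities(pruned)
print(f"partition density at cut: {result.partition_density_value:.3f}")
print(f"communities: {len(result.communities)}")
for c in result.communities:
    print(f"  community {c.community_id}: {sorted(c.nodes)}")
print("roles in every community:", result.roles_in_all_communities())
# The hub roles bridging all communities are the care coordinators; their
# pie fractions show how their edges distribute across the teams:
for role in result.roles_in_all_communities():
    print(f"  {role} pie:", {k: round(v, 2) for k, v in sorted(result.pie_fractions[role].items())})
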