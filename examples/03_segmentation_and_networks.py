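"""Natural-break segmentation and the working-closely-together networks.

Consecutive-event gaps within each (encounter, shift) are pooled; a 2-class
natural-breaks optimization over a 30-120 minute grid picks the break
interval; shifts are partitioned into segments at gaps >= that interval.
Each (location, shift type) sublog then yields a weighted role-role network:
weight = (shifts where the pair shared a segment) / (shifts where both were
involved with the patient).
"""

from carenet import (
    GeneratorConfig,
    build_collaboration_network,
    collect_gaps,
    generate_study,
    prepare_master_log,
    segment_shifts,
    select_break_interval,
    split_sublogs,
)

study = generate_study(GeneratorConfig(n_encounters=200, locations=("ED",), seed=7))
master, _ = prepare_master_log(study.records, study.encounters, study.adt, study.roster)

sample = collect_gaps(master)
selection = select_break_interval(sample)
print(f"gaps pooled      : {len(sample)}")
print(f"chosen interval  : {selection.chosen_interval} min "
      f"(GVF = {selection.gvf_by_candidate.max():.4f})")

segmented, segments = segment_shifts(master, selection.chosen_interval)
print(f"segments         : {len(segments)}")

split = split_sublogs(segmented)
for key, sub in split.sublogs.items():
    if sub.empty:
        continue
    net = build_collaboration_network(sub, key)
    print(f"\n{key[0]} {key[1]}: {net.n_nodes_connected} connected roles, "
          f"{net.n_edges} edges from {net.n_events} events")
    top = net.edge_frame().nlargest(3, "co_segment_shifts")
    print(top.to_string(index=False))
# weight 1.0 means the pair co-segmented in every shift they shared; low
# co_segment_shifts counts are candidates for threshold pruning.
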