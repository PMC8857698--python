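import pytest

import carenet as cn


@pytest.fixture(scope="session")
def default_study():
    """Full-size synthetic study under the default study conditions."""
    return cn.generate_study(cn.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_master(default_study):
    master, exclusions = cn.prepare_master_log(
        default_study.records,
        default_study.encounters,
        default_study.adt,
        default_study.roster,
    )
    return master, exclusions


@pytest.fixture(scope="session")
def default_run(default_study, default_master):
    """Segmentation -> networks -> thresholds -> communities for every sublog."""
    master, _ = default_master
    selection = cn.select_break_interval(cn.collect_gaps(master))
    segmented, segments = cn.segment_shifts(master, selection.chosen_interval)
    split = cn.split_sublogs(segmented)
    sublogs = {}
    for key, sub in split.sublogs.items():
        net = cn.build_collaboration_network(sub, key)
        pruned, curve = cn.select_threshold(net)
        communities = cn.detect_link_communities(pruned) if pruned.n_edges else None
        sublogs[key] = {
            "sublog": sub,
            "network": net,
            "pruned": pruned,
            "curve": curve,
            "communities": communities,
        }
    return {
        "study": default_study,
        "master": master,
        "selection": selection,
        "segmented": segmented,
        "segments": segments,
        "sublogs": sublogs,
    }
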