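import pytest

from mapanchor.anchoring import assign_scaffolds, detect_chimeras
from mapanchor.linkage_map import LinkageMap, build_bins
from mapanchor.synthetic_data import (
    SimulationConfig,
    evaluate_recovery,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 2-chromosome noiseless dataset with planted chimeras
    (elevated fusion/inversion rates so every failure mode is present)."""
    return generate_dataset(
        SimulationConfig(
            seed=7,
            n_chromosomes=2,
            chromosome_length_bp=400_000,
            p_invert=0.25,
            p_chimera=0.3,
        )
    )


def run_anchoring(dataset, max_intra_lg_gap_cm=20.0, cm_precision=2):
    """Run the map-binning and anchoring stages on a synthetic dataset."""
    lmap = LinkageMap(dataset.markers)
    bins = build_bins(lmap, cm_precision=cm_precision)
    anchors = assign_scaffolds(dataset.placements, bins, lmap)
    reports = {}
    for a in anchors:
        rep = detect_chimeras(a, max_intra_lg_gap_cm)
        if rep is not None:
            reports[a.scaffold_id] = rep
    return lmap, bins, anchors, reports


def score(dataset, **kwargs):
    _, _, anchors, reports = run_anchoring(dataset, **kwargs)
    return evaluate_recovery(anchors, reports, dataset)
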