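"""pmoA amplicon filtering cascade on reads with planted defects.

Generates 2,000 reads from synthetic pmoA-like ORFs with planted
stop-codon, frameshift, and low-quality defects, runs the quality-window,
frame/stop, and length filters, checks the rejections against the planted
truth, and assigns taxonomy to a sample of surviving reads. Writes
results/filter_report.json.
"""

import json
from pathlib import Path

from peatmox import ReferenceDB, assign_taxonomy, quality_window_filter
from peatmox.community import frame_stop_filter, length_window_filter
from peatmox.simulate import gen_amplicons, gen_reference_orfs

SEED = 20163
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    refs = gen_reference_orfs(5, seed=SEED)
    reads, truth = gen_amplicons(
        refs, 2000,
        {"stop_codon": 0.05, "frameshift": 0.05, "low_quality_window": 0.10},
        seed=SEED + 1,
    )
    quality = quality_window_filter(reads)
    survivors, frame_fail, length_fail = [], 0, 0
    for read in quality.kept:
        if not frame_stop_filter(read.nucleotides)[0]:
            frame_fail += 1
        elif not length_window_filter(read.nucleotides, "mb661R"):
            length_fail += 1
        else:
            survivors.append(read)

    planted = truth["defect"].value_counts().to_dict()
    matches_truth = (
        quality.n_rejected == planted.get("low_quality_window", 0)
        and frame_fail == planted.get("stop_codon", 0) + planted.get("frameshift", 0)
        and len(survivors) == planted.get("clean", 0)
    )
    report = {
        "n_reads": len(reads),
        "planted": planted,
        "quality_rejected": quality.n_rejected,
        "frame_or_stop_rejected": frame_fail,
        "length_rejected_after_frame": length_fail,
        "survivors": len(survivors),
        "partition_matches_planted_truth": matches_truth,
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "filter_report.json").write_text(json.dumps(report, indent=2))

    db = ReferenceDB(refs)
    print(json.dumps(report, indent=2))
    print("taxonomy of the first five surviving reads:")
    for read in survivors[:5]:
        a = assign_taxonomy(read.nucleotides, db)
        print(f"  {read.id}: {a.taxonomy} ({a.percent_identity:.1f}% identity)")


if __name__ == "__main__":
    main()
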