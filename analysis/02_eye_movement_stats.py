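"""Eye-movement analysis of the default dataset.

Reads the scanpaths written by 01_generate_dataset.py (regenerating them if
absent), applies the 80 ms / 3 SD exclusions, computes FFD/GD/TVT on the
target words, and runs the log-transformed one-way repeated-measures ANOVA
plus the two planned semantic-violation contrasts. Writes results/em/.
"""

import sys
import warnings
from pathlib import Path

from frsp.io import RunConfig, read_fixation_table, write_json
from frsp.pipeline import (
    em_condition_means,
    run_em_analysis,
    scanpaths_to_frames,
    simulate_dataset,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    import pandas as pd

    cfg = RunConfig()
    dataset = ROOT / "dataset"
    if (dataset / "scanpaths.tsv").exists():
        fixations = read_fixation_table(dataset / "scanpaths.tsv")
        trial_table = pd.read_csv(dataset / "trials.tsv", sep="\t")
    else:
        corpus, trials = simulate_dataset(cfg, SEED)
        fixations, trial_table = scanpaths_to_frames(corpus, trials)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_em_analysis(fixations, trial_table)

    out = ROOT / "em"
    write_json(out / "em_stats.json", {"seed": SEED, **result})

    excl = result["exclusions"]
    print(f"exclusions: {excl['n_below_80ms']} below 80 ms, "
          f"{excl['n_above_3sd']} above 3 SD "
          f"({100 * excl['fraction_removed']:.2f}% of "
          f"{excl['n_fixations_total']} fixations)")
    print("raw target-word condition means (ms):")
    for measure, conds in em_condition_means(result).items():
        print("  " + measure + ":  " +
              "  ".join(f"{c}={v:.1f}" for c, v in sorted(conds.items())))
    for measure in ("FFD", "GD", "TVT"):
        for name, t in result["measures"][measure]["paired_t"].items():
            print(f"  {measure} {name}: t({t['df']}) = {t['t']:.2f}, p = {t['p']:.4g}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
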